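"""Held-out evaluation: per-cell rank correlation and the nearest-neighbor
baseline.

Predicted expression is scored against the measured profile one cell at a
time with Spearman correlation (rank-based, so any monotone rescaling of
either side is immaterial). The baseline predicts each test cell's
expression as that of the Euclidean-nearest training cell in surface-
protein space; the paired one-sided Wilcoxon signed-rank test compares
the two methods' per-cell scores.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import rankdata, wilcoxon

log = logging.getLogger(__name__)


def spearman_per_cell(Y_pred: pd.DataFrame, Y_true: pd.DataFrame) -> pd.Series:
    """Spearman rho between predicted and measured expression for every
    cell (column), with average-rank tie handling.

    Columns with zero variance on either side yield NaN (logged) and are
    excluded from downstream means by the callers.
    """
    Pv = np.asarray(Y_pred, float)
    Tv = np.asarray(Y_true, float)
    if Pv.shape != Tv.shape:
        raise ValueError(f"shape mismatch: {Pv.shape} vs {Tv.shape}")
    rp = rankdata(Pv, axis=0)
    rt = rankdata(Tv, axis=0)
    rp = rp - rp.mean(axis=0)
    rt = rt - rt.mean(axis=0)
    denom = np.sqrt((rp**2).sum(axis=0) * (rt**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(denom > 0, (rp * rt).sum(axis=0) / denom, np.nan)
    n_nan = int(np.isnan(rho).sum())
    if n_nan:
        log.info("spearman_per_cell: %d constant columns scored as NaN", n_nan)
    index = Y_true.columns if isinstance(Y_true, pd.DataFrame) else range(len(rho))
    return pd.Series(rho, index=index, name="rho")


def nearest_neighbor_baseline(
    P_train: pd.DataFrame, Y_train: pd.DataFrame, P_test: pd.DataFrame
) -> pd.DataFrame:
    """Predict each test cell's expression as the expression of its
    Euclidean-nearest training cell in protein space (ties broken toward
    the lowest training-cell index)."""
    Ptr = np.asarray(P_train, float)
    Pte = np.asarray(P_test, float)
    Ytr = np.asarray(Y_train, float)
    if Ptr.shape[0] == 0:
        raise ValueError("nearest_neighbor_baseline needs at least one training cell")
    if Ytr.shape[1] != Ptr.shape[0]:
        raise ValueError(
            f"Y_train has {Ytr.shape[1]} cells but P_train has {Ptr.shape[0]}"
        )
    idx = cdist(Pte, Ptr).argmin(axis=1)  # argmin returns the first (lowest) index
    pred = Ytr[:, idx]
    genes = Y_train.index if isinstance(Y_train, pd.DataFrame) else range(pred.shape[0])
    cells = P_test.index if isinstance(P_test, pd.DataFrame) else range(pred.shape[1])
    return pd.DataFrame(pred, index=genes, columns=cells)


def compare_methods(scores_a: pd.Series, scores_b: pd.Series) -> tuple[float, float]:
    """One-sided Wilcoxon signed-rank test that method a outperforms b on
    paired per-cell scores.

    Pairs are matched by cell barcode; NaN pairs and zero differences are
    dropped (Wilcoxon convention). Exact distribution for small n without
    ties, normal approximation with continuity correction otherwise.
    """
    a, b = scores_a.align(scores_b, join="inner")
    mask = ~(a.isna() | b.isna())
    a, b = a[mask], b[mask]
    if len(a) < 6:
        raise ValueError(f"need at least 6 paired scores, got {len(a)}")
    d = a.to_numpy() - b.to_numpy()
    if np.all(d == 0):
        warnings.warn("all paired differences are zero; p = 1", UserWarning)
        return 0.0, 1.0
    res = wilcoxon(d, alternative="greater", zero_method="wilcox",
                   correction=True, method="auto")
    return float(res.statistic), float(res.pvalue)
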