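"""Activity mappings through the trained interaction matrix and their
permutation-based significance.

Two linear mappings read out the trained model: TF activities per cell,
``A = W P^T`` (TFs x cells), and projected surface-protein activities,
``A = Y^T D W`` (cells x proteins). Significance of TF activities is
assessed against an empirical null built by permuting the gene labels of
Y (breaking the gene correspondence between expression and the regulon
prior), retraining the model on each permutation with the same
hyperparameters, and recording the null activities.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .affinity import InteractionMatrix, _fit, _ids, _values, build_reduced_system


def _as_W(W) -> tuple[np.ndarray, list | None, list | None]:
    if isinstance(W, InteractionMatrix):
        return W.values, W.tf_ids, W.protein_ids
    if isinstance(W, pd.DataFrame):
        return W.to_numpy(float), list(W.index), list(W.columns)
    return np.asarray(W, float), None, None


def infer_tf_activity(W, P, zscore: bool = False) -> pd.DataFrame:
    """TF activities A = W P^T (TFs x cells).

    With ``zscore=True`` each TF row is standardized across cells (display
    convention for dot plots / heatmaps); raw activities are used for
    significance testing.
    """
    Wv, tf_ids, prot_ids = _as_W(W)
    if prot_ids is not None and isinstance(P, pd.DataFrame):
        missing = [p for p in prot_ids if p not in P.columns]
        if missing:
            raise ValueError(f"protein ids missing from P: {missing}")
        P = P[prot_ids]
    Pv = _values(P)
    if Pv.shape[1] != Wv.shape[1]:
        raise ValueError(f"W has {Wv.shape[1]} proteins but P has {Pv.shape[1]}")
    A = Wv @ Pv.T
    if zscore:
        mu = A.mean(axis=1, keepdims=True)
        sd = A.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        A = (A - mu) / sd
    df = pd.DataFrame(
        A,
        index=tf_ids if tf_ids is not None else range(A.shape[0]),
        columns=_ids(P, 0) if _ids(P, 0) is not None else range(A.shape[1]),
    )
    df.attrs["kind"] = "tf_activity"
    df.attrs["zscored"] = bool(zscore)
    return df


def infer_protein_activity(Y, D, W) -> pd.DataFrame:
    """Projected surface-protein activities A = Y^T D W (cells x proteins)."""
    Wv, tf_ids, prot_ids = _as_W(W)
    if tf_ids is not None and isinstance(D, pd.DataFrame):
        missing = [t for t in tf_ids if t not in D.columns]
        if missing:
            raise ValueError(f"TF ids missing from D: {missing}")
        D = D[tf_ids]
    if isinstance(Y, pd.DataFrame) and isinstance(D, pd.DataFrame):
        missing = [g for g in Y.index if g not in D.index]
        if missing:
            raise ValueError(f"genes missing from D: {missing[:5]}")
        D = D.loc[list(Y.index)]
    Yv, Dv = _values(Y), _values(D)
    if Yv.shape[0] != Dv.shape[0]:
        raise ValueError(f"Y has {Yv.shape[0]} genes but D has {Dv.shape[0]}")
    A = Yv.T @ Dv @ Wv
    df = pd.DataFrame(
        A,
        index=_ids(Y, 1) if _ids(Y, 1) is not None else range(A.shape[0]),
        columns=prot_ids if prot_ids is not None else range(A.shape[1]),
    )
    df.attrs["kind"] = "protein_activity"
    return df


@dataclasses.dataclass
class NullModel:
    """Empirical null TF-activity samples from gene-label permutations.

    ``samples`` has shape (n_perm, TFs, cells); entry ``samples[r]`` is the
    activity matrix of a model retrained on the r-th permuted expression
    matrix with the observed hyperparameters.
    """

    samples: np.ndarray
    tf_ids: list | None
    cell_barcodes: list | None
    n_perm: int
    seed: int
    lambda1: float
    lambda2: float
    perm_axis: str


def build_null_model(
    Y,
    D,
    P,
    n_perm: int = 200,
    seed: int = 0,
    lambda1: float = 0.0,
    lambda2: float = 1e-3,
    var_retained: float | None = 0.95,
    perm_axis: str = "genes",
    permutations: list[np.ndarray] | None = None,
    tol: float = 1e-8,
    max_iter: int = 100_000,
) -> NullModel:
    """Retrain the model on permuted expression matrices and record the
    null TF activities.

    ``perm_axis="genes"`` permutes the gene labels (rows) of Y, severing
    the Y-D gene correspondence that drives TF-activity inference while
    preserving every cell's expression distribution and column norms;
    ``"cells"`` permutes cell columns instead. ``permutations`` may inject
    explicit permutations (e.g. the identity) for debugging.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if perm_axis not in ("genes", "cells"):
        raise ValueError("perm_axis must be 'genes' or 'cells'")
    Yv, Dv, Pv = _values(Y), _values(D), _values(P)
    N, M = Yv.shape
    Q = Dv.shape[1]
    rng = np.random.default_rng(seed)
    if permutations is not None:
        n_perm = len(permutations)
    samples = np.empty((n_perm, Q, M))
    for r in range(n_perm):
        if permutations is not None:
            perm = np.asarray(permutations[r])
        else:
            perm = rng.permutation(N if perm_axis == "genes" else M)
        Yp = Yv[perm, :] if perm_axis == "genes" else Yv[:, perm]
        try:
            sys = build_reduced_system(Yp, Dv, Pv, var_retained)
            W_r = _fit(sys, lambda1, lambda2, tol, max_iter)
        except Exception as err:  # noqa: BLE001 - annotate which permutation failed
            raise RuntimeError(f"null model fit failed at permutation {r}") from err
        samples[r] = W_r.values @ Pv.T
    return NullModel(
        samples,
        _ids(D, 1),
        _ids(P, 0),
        n_perm,
        seed,
        float(lambda1),
        float(lambda2),
        perm_axis,
    )


@dataclasses.dataclass
class SignificanceReport:
    """Per-(TF, cell) empirical significance against the permutation null.

    ``p_value`` is the two-tailed empirical p with the +1 correction,
    ``p_adjusted`` the Bonferroni correction across TFs within each cell,
    ``q_value`` the BH-FDR analogue (reported as an extra column only),
    ``direction`` +1 where the observed activity sits in the high tail,
    -1 in the low tail, and ``frequency`` the per-TF fraction of cells
    passing the adjusted threshold (per cell type when labels are given).
    """

    p_value: pd.DataFrame
    p_adjusted: pd.DataFrame
    q_value: pd.DataFrame
    significant: pd.DataFrame
    direction: pd.DataFrame
    frequency: pd.Series | pd.DataFrame
    alpha: float

    def to_table(self) -> pd.DataFrame:
        """Long-format (tf, cell, p, p_adj, q, direction, significant)."""
        rows = []
        for tf in self.p_value.index:
            for cell in self.p_value.columns:
                rows.append(
                    dict(
                        tf=tf,
                        cell=cell,
                        p=self.p_value.at[tf, cell],
                        p_adj=self.p_adjusted.at[tf, cell],
                        q=self.q_value.at[tf, cell],
                        direction=int(self.direction.at[tf, cell]),
                        significant=bool(self.significant.at[tf, cell]),
                    )
                )
        return pd.DataFrame(rows)


def score_significance(
    A, null: NullModel, alpha: float = 0.15, labels: pd.Series | None = None
) -> SignificanceReport:
    """Empirical two-tailed p-values of observed activities against the null.

    Per (TF, cell): each tail probability is (b + 1)/(n_perm + 1) where b
    counts null samples at least as extreme, and p = min(1, 2 * min(tails))
    so p can never be zero. Bonferroni multiplies by the number of TFs
    within each cell; calls are significant at adjusted p < ``alpha``.
    """
    Av = _values(A)
    Q, M = Av.shape
    R = null.samples.shape[0]
    if null.samples.shape[1:] != (Q, M):
        raise ValueError(
            f"null model shape {null.samples.shape[1:]} does not match activities {(Q, M)}"
        )
    min_adj = min(1.0, Q * 2.0 / (R + 1))
    if min_adj >= alpha:
        warnings.warn(
            f"minimum attainable adjusted p is {min_adj:.3g} >= alpha={alpha}; "
            "no call can be significant (increase n_perm)",
            UserWarning,
        )
    b_hi = (null.samples >= Av[None]).sum(axis=0)
    b_lo = (null.samples <= Av[None]).sum(axis=0)
    p_hi = (b_hi + 1) / (R + 1)
    p_lo = (b_lo + 1) / (R + 1)
    p = np.minimum(1.0, 2.0 * np.minimum(p_hi, p_lo))
    p_adj = np.minimum(1.0, Q * p)
    q = np.empty_like(p)
    for j in range(M):  # BH across TFs within each cell
        q[:, j] = multipletests(p[:, j], method="fdr_bh")[1]
    tf_index = A.index if isinstance(A, pd.DataFrame) else (
        null.tf_ids if null.tf_ids is not None else range(Q)
    )
    cell_index = A.columns if isinstance(A, pd.DataFrame) else (
        null.cell_barcodes if null.cell_barcodes is not None else range(M)
    )
    as_df = lambda x: pd.DataFrame(x, index=tf_index, columns=cell_index)  # noqa: E731
    sig = as_df(p_adj < alpha)
    direction = as_df(np.where(p_hi <= p_lo, 1, -1))
    if labels is not None:
        labels = pd.Series(labels).reindex(cell_index)
        freq = sig.T.groupby(labels).mean().T  # TFs x cell types
    else:
        freq = sig.mean(axis=1)
        freq.name = "frequency"
    return SignificanceReport(
        as_df(p), as_df(p_adj), as_df(q), sig, direction, freq, alpha
    )
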