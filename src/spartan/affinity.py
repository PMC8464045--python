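"""Regularized bilinear (affinity) regression D W P^T ~ Y.

The model explains a genes x cells expression matrix Y as the interaction
of two attribute matrices: a binary genes x TFs regulon prior D and a
cells x proteins surface-protein matrix P. The learned TFs x proteins
interaction matrix W couples surface-receptor levels to TF regulons.

Vectorizing turns the bilinear fit into ordinary regression,

    D W P^T ~ Y   <=>   (P (x) D) vec(W) ~ vec(Y),

and left-multiplying by Y^T compresses the system from N*M to M*M
equations without changing the unknowns:

    (P (x) Y^T D) vec(W) ~ vec(Y^T Y).

We minimize, over the compressed design A = P (x) G with G = Y^T D and
b = vec(Y^T Y),

    f(W) = 1/2 ||b - A vec(W)||^2 + lambda2/2 ||W||_F^2 + lambda1 ||W||_1,

whose lambda1 = 0 limit is the ridge solution (A^T A + lambda2 I)^{-1} A^T b.
P may optionally be replaced by a rank-k SVD truncation before training;
W is always reported in the original protein coordinates.

The scikit-learn style estimator :class:`AffinityRegression` wraps the
functional surface (:func:`build_reduced_system`, :func:`solve_ridge_reduced`,
:func:`solve_elastic_net`, :func:`cross_validate`, :func:`predict_expression`).
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numba
import numpy as np
import pandas as pd
from scipy.linalg import eigh, svd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.model_selection import KFold

DEFAULT_GRID: list[tuple[float, float]] = [
    (l1, l2)
    for l1 in (1e-4, 1e-3, 1e-2, 1e-1, 1.0)
    for l2 in (1e-4, 1e-3, 1e-2, 1e-1, 1.0)
]


def _values(x) -> np.ndarray:
    return np.asarray(x.to_numpy() if hasattr(x, "to_numpy") else x, dtype=float)


def _ids(x, axis: int):
    if isinstance(x, pd.DataFrame):
        return list(x.columns if axis == 1 else x.index)
    return None


@dataclasses.dataclass
class ReducedSystem:
    """The Y^T-compressed training system.

    ``G = Y^T D`` (cells x TFs), ``B = Y^T Y`` (cells x cells),
    ``P_red = P V_k`` the SVD-reduced protein matrix (``V_k`` is None when
    no reduction is applied, in which case ``P_red`` is P itself).
    """

    G: np.ndarray
    B: np.ndarray
    P_red: np.ndarray
    V_k: np.ndarray | None
    singular_values: np.ndarray | None
    tf_ids: list[str] | None = None
    protein_ids: list[str] | None = None
    cell_barcodes: list[str] | None = None

    @property
    def rank(self) -> int | None:
        return None if self.V_k is None else self.V_k.shape[1]

    @property
    def n_proteins(self) -> int:
        return self.P_red.shape[1] if self.V_k is None else self.V_k.shape[0]

    def design_protein_matrix(self) -> np.ndarray:
        """The (possibly rank-truncated) protein matrix in ORIGINAL
        protein coordinates."""
        if self.V_k is None:
            return self.P_red
        return self.P_red @ self.V_k.T


@dataclasses.dataclass
class InteractionMatrix:
    """Learned TFs x proteins interaction weights with fit metadata."""

    values: np.ndarray
    tf_ids: list[str] | None
    protein_ids: list[str] | None
    lambda1: float
    lambda2: float
    svd_rank: int | None
    n_iter: int = 0
    converged: bool = True
    objective_path: list[float] = dataclasses.field(default_factory=list)

    @property
    def sparsity(self) -> float:
        """Fraction of exactly-zero entries."""
        return float(np.mean(self.values == 0.0))

    def to_frame(self) -> pd.DataFrame:
        q, s = self.values.shape
        return pd.DataFrame(
            self.values,
            index=self.tf_ids if self.tf_ids is not None else range(q),
            columns=self.protein_ids if self.protein_ids is not None else range(s),
        )


def build_reduced_system(Y, D, P, var_retained: float | None = 0.95) -> ReducedSystem:
    """Compress the bilinear problem: G = Y^T D, B = Y^T Y, and optionally
    reduce P by SVD keeping the smallest rank whose cumulative squared
    singular values reach ``var_retained`` (1.0 keeps the full rank; None
    skips the SVD entirely).
    """
    Yv, Dv, Pv = _values(Y), _values(D), _values(P)
    if Yv.shape[0] != Dv.shape[0]:
        raise ValueError(f"Y has {Yv.shape[0]} genes but D has {Dv.shape[0]}")
    if Yv.shape[1] != Pv.shape[0]:
        raise ValueError(f"Y has {Yv.shape[1]} cells but P has {Pv.shape[0]}")
    G = Yv.T @ Dv
    B = Yv.T @ Yv
    if var_retained is None:
        return ReducedSystem(
            G, B, Pv, None, None,
            tf_ids=_ids(D, 1), protein_ids=_ids(P, 1), cell_barcodes=_ids(P, 0),
        )
    U, s, Vt = svd(Pv, full_matrices=False)
    tol = max(Pv.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    r = int(np.sum(s > tol))
    if r == 0:
        raise ValueError("protein matrix has rank 0")
    if var_retained >= 1.0:
        k = r
    else:
        frac = np.cumsum(s[:r] ** 2) / np.sum(s[:r] ** 2)
        k = int(np.searchsorted(frac, var_retained) + 1)
    return ReducedSystem(
        G, B, U[:, :k] * s[:k], Vt[:k].T, s.copy(),
        tf_ids=_ids(D, 1), protein_ids=_ids(P, 1), cell_barcodes=_ids(P, 0),
    )


def _gram(sys: ReducedSystem) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gram blocks of the compressed design in original protein coordinates:
    Gg = G^T G, Pg = Pt^T Pt, C = G^T B Pt with Pt the design protein matrix."""
    Pt = sys.design_protein_matrix()
    Gg = sys.G.T @ sys.G
    Pg = Pt.T @ Pt
    C = sys.G.T @ sys.B @ Pt
    return Gg, Pg, C


def solve_ridge_reduced(sys: ReducedSystem, lambda2: float) -> InteractionMatrix:
    """Closed-form ridge solution of the compressed system.

    Exploits the Kronecker structure: with eigendecompositions
    Gg = Ug diag(a) Ug^T and Pg = Vp diag(t) Vp^T the solution is
    W = Ug [ (Ug^T C Vp)_{ij} / (a_i t_j + lambda2) ] Vp^T. When P was
    SVD-reduced the solve runs in reduced coordinates and W is rotated back
    by V_k^T, which is exactly the original-coordinate solution because the
    orthogonal complement of V_k carries no signal.
    """
    if sys.V_k is None:
        Pd = sys.P_red
    else:
        Pd = sys.P_red  # reduced coordinates; rotate back at the end
    Gg = sys.G.T @ sys.G
    Pg = Pd.T @ Pd
    C = sys.G.T @ sys.B @ Pd
    a, Ug = eigh(Gg)
    t, Vp = eigh(Pg)
    denom = np.multiply.outer(a, t) + lambda2
    scale = max(a.max(initial=0.0) * t.max(initial=0.0), 1.0)
    if np.min(denom) <= scale * 1e-14:
        raise np.linalg.LinAlgError(
            "compressed normal equations are singular; use lambda2 > 0"
        )
    core = Ug @ ((Ug.T @ C @ Vp) / denom) @ Vp.T
    W = core if sys.V_k is None else core @ sys.V_k.T
    return InteractionMatrix(
        W, sys.tf_ids, sys.protein_ids, 0.0, float(lambda2), sys.rank
    )


def _objective(W, Gg, Pg, C, bb, lambda1, lambda2) -> float:
    quad = Gg @ W @ Pg
    return (
        0.5 * bb
        - float(np.sum(W * C))
        + 0.5 * float(np.sum(W * quad))
        + 0.5 * lambda2 * float(np.sum(W * W))
        + lambda1 * float(np.sum(np.abs(W)))
    )


@numba.njit(cache=True)
def _cd_kernel(Gg, Pg, C, bb, lambda1, lambda2, tol, max_iter, W):  # pragma: no cover
    """Cyclic coordinate descent over the entries of W with Gram blocks
    Gg = G^T G and Pg = Pt^T Pt. ``R`` tracks C - Gg W Pg so each update
    costs O(Q*S). Stops when the max KKT violation falls below
    ``tol * max(1, ||C||_inf)``."""
    Q, S = C.shape
    R = C - Gg @ W @ Pg
    scale = max(1.0, np.abs(C).max())
    obj_path = np.empty(max_iter + 1)
    obj_path[0] = (
        0.5 * bb - np.sum(W * C) + 0.5 * np.sum(W * (Gg @ W @ Pg))
        + 0.5 * lambda2 * np.sum(W * W) + lambda1 * np.sum(np.abs(W))
    )
    n_iter = 0
    converged = False
    for it in range(1, max_iter + 1):
        n_iter = it
        max_step = 0.0
        w_scale = 0.0
        for q in range(Q):
            for s in range(S):
                a0 = Gg[q, q] * Pg[s, s]
                denom = a0 + lambda2
                if denom <= 0.0:
                    continue
                z = R[q, s] + a0 * W[q, s]
                if z > lambda1:
                    w_new = (z - lambda1) / denom
                elif z < -lambda1:
                    w_new = (z + lambda1) / denom
                else:
                    w_new = 0.0
                d = w_new - W[q, s]
                if d != 0.0:
                    W[q, s] = w_new
                    for i in range(Q):
                        gi = Gg[i, q] * d
                        for j in range(S):
                            R[i, j] -= gi * Pg[s, j]
                if abs(d) > max_step:
                    max_step = abs(d)
                if abs(W[q, s]) > w_scale:
                    w_scale = abs(W[q, s])
        if it % 100 == 0:  # kill drift from incremental residual updates
            R = C - Gg @ W @ Pg
        kkt = 0.0
        for q in range(Q):
            for s in range(S):
                g = -R[q, s] + lambda2 * W[q, s]
                if W[q, s] > 0.0:
                    v = abs(g + lambda1)
                elif W[q, s] < 0.0:
                    v = abs(g - lambda1)
                else:
                    v = abs(R[q, s]) - lambda1
                    if v < 0.0:
                        v = 0.0
                if v > kkt:
                    kkt = v
        obj_path[it] = (
            0.5 * bb - np.sum(W * C) + 0.5 * np.sum(W * (Gg @ W @ Pg))
            + 0.5 * lambda2 * np.sum(W * W) + lambda1 * np.sum(np.abs(W))
        )
        # stagnation at floating-point resolution is a fixed point
        if kkt <= tol * scale or max_step <= 1e-15 * (1.0 + w_scale):
            converged = True
            break
    return W, n_iter, converged, obj_path[: n_iter + 1]


def lambda1_max(sys: ReducedSystem) -> float:
    """Smallest lambda1 that forces W = 0 exactly (||A^T b||_inf of the
    compressed system)."""
    _, _, C = _gram(sys)
    return float(np.max(np.abs(C)))


def solve_elastic_net(
    sys: ReducedSystem,
    lambda1: float,
    lambda2: float,
    tol: float = 1e-9,
    max_iter: int = 100_000,
    W0: np.ndarray | None = None,
) -> InteractionMatrix:
    """Cyclic coordinate descent for the compressed elastic-net objective.

    Operates on W in the original protein coordinates (so L1 zeros are
    zeros of W itself), with precomputed Gram blocks. Deterministic;
    iterates until the maximum KKT violation falls below
    ``tol * max(1, ||A^T b||_inf)``, which keeps the ``lambda1 = 0``
    solution within 1e-6 relative Frobenius error of the ridge closed
    form. ``W0`` warm-starts path computations.
    """
    if lambda1 < 0 or lambda2 < 0:
        raise ValueError("penalties must be non-negative")
    Gg, Pg, C = _gram(sys)
    bb = float(np.sum(sys.B * sys.B))
    W = np.zeros_like(C) if W0 is None else np.array(W0, dtype=float)
    W, n_iter, converged, path = _cd_kernel(
        np.ascontiguousarray(Gg), np.ascontiguousarray(Pg), np.ascontiguousarray(C),
        bb, float(lambda1), float(lambda2), float(tol), int(max_iter), W,
    )
    if not converged:
        warnings.warn(
            f"coordinate descent did not converge in {max_iter} sweeps", RuntimeWarning
        )
    return InteractionMatrix(
        W, sys.tf_ids, sys.protein_ids, float(lambda1), float(lambda2), sys.rank,
        n_iter=n_iter, converged=converged, objective_path=list(path),
    )


def predict_expression(W: InteractionMatrix | pd.DataFrame | np.ndarray, D, P_new) -> pd.DataFrame:
    """Predicted expression Y_hat = D W P_new^T (genes x cells); no
    renormalization is applied."""
    if isinstance(W, InteractionMatrix):
        Wv, tf_ids, prot_ids = W.values, W.tf_ids, W.protein_ids
    elif isinstance(W, pd.DataFrame):
        Wv, tf_ids, prot_ids = W.to_numpy(float), list(W.index), list(W.columns)
    else:
        Wv, tf_ids, prot_ids = np.asarray(W, float), None, None
    if prot_ids is not None and isinstance(P_new, pd.DataFrame):
        missing = [p for p in prot_ids if p not in P_new.columns]
        extra = [p for p in P_new.columns if p not in prot_ids]
        if missing or extra:
            raise ValueError(
                f"protein ids do not match the model (missing={missing}, extra={extra})"
            )
        P_new = P_new[prot_ids]
    if tf_ids is not None and isinstance(D, pd.DataFrame):
        D = D[tf_ids]
    Dv, Pv = _values(D), _values(P_new)
    Yhat = Dv @ Wv @ Pv.T
    genes = _ids(D, 0)
    cells = _ids(P_new, 0)
    return pd.DataFrame(
        Yhat,
        index=genes if genes is not None else range(Yhat.shape[0]),
        columns=cells if cells is not None else range(Yhat.shape[1]),
    )


@dataclasses.dataclass
class CVResult:
    """Cross-validation summary over a (lambda1, lambda2) grid."""

    grid: list[tuple[float, float]]
    fold_scores: np.ndarray  # n_grid x folds mean per-cell Spearman
    best: tuple[float, float]
    best_index: int
    folds: int
    seed: int

    @property
    def mean_scores(self) -> np.ndarray:
        return np.nanmean(self.fold_scores, axis=1)


def _fit(sys: ReducedSystem, lambda1: float, lambda2: float, tol: float, max_iter: int):
    if lambda1 == 0.0:
        return solve_ridge_reduced(sys, lambda2)
    return solve_elastic_net(sys, lambda1, lambda2, tol=tol, max_iter=max_iter)


def cross_validate(
    Y,
    D,
    P,
    grid: Sequence[tuple[float, float]] | None = None,
    folds: int = 5,
    seed: int = 0,
    var_retained: float | None = 0.95,
    tol: float = 1e-8,
    max_iter: int = 100_000,
) -> CVResult:
    """K-fold cross-validation over cells, scored by mean per-cell Spearman
    correlation between predicted and measured expression on the held-out
    fold. Ties in the mean score are broken toward larger lambda1, then
    larger lambda2 (the sparser / smoother model).
    """
    from .evaluation import spearman_per_cell

    if grid is None:
        grid = DEFAULT_GRID
    grid = [(float(l1), float(l2)) for l1, l2 in grid]
    if not grid:
        raise ValueError("empty hyperparameter grid")
    Yv, Dv, Pv = _values(Y), _values(D), _values(P)
    M = Yv.shape[1]
    if M < folds:
        raise ValueError(f"need at least {folds} cells, got {M}")
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = np.full((len(grid), folds), np.nan)
    for f, (tr, te) in enumerate(kf.split(np.arange(M))):
        sys = build_reduced_system(Yv[:, tr], Dv, Pv[tr], var_retained)
        Yte = pd.DataFrame(Yv[:, te])
        for i, (l1, l2) in enumerate(grid):
            W = _fit(sys, l1, l2, tol, max_iter)
            Yhat = pd.DataFrame(Dv @ W.values @ Pv[te].T)
            rho = spearman_per_cell(Yhat, Yte)
            scores[i, f] = np.nanmean(rho.to_numpy())
    mean = np.nanmean(scores, axis=1)
    best_score = np.max(mean)
    tied = [i for i, m in enumerate(mean) if m == best_score]
    best_index = max(tied, key=lambda i: (grid[i][0], grid[i][1]))
    return CVResult(grid, scores, grid[best_index], best_index, folds, seed)


class AffinityRegression(RegressorMixin, BaseEstimator):
    """Bilinear regression of gene expression on surface-protein profiles
    through a TF-regulon prior, in scikit-learn estimator form.

    Cells are samples: ``fit(X, y)`` takes ``X`` as the cells x proteins
    matrix and ``y`` as the cells x genes expression matrix (the transpose
    of the genes x cells convention used by the functional API). The
    regulon prior is a constructor argument because it is an attribute of
    the genes, not of the samples.

    Parameters
    ----------
    prior
        Binary genes x TFs regulon membership matrix (DataFrame or array),
        aligned with the columns of ``y``.
    lambda1, lambda2
        L1 / L2 penalty weights of the elastic net.
    var_retained
        Fraction of squared singular values of the protein matrix retained
        by the SVD reduction (1.0 = full rank, None = no reduction).
    tol, max_iter
        Coordinate-descent stopping controls (used when ``lambda1 > 0``).

    Attributes
    ----------
    W_ : DataFrame, TFs x proteins
        Learned interaction matrix.
    interaction_ : InteractionMatrix
        The same weights with solver metadata.
    """

    def __init__(
        self,
        prior=None,
        lambda1: float = 0.0,
        lambda2: float = 1e-3,
        var_retained: float | None = 0.95,
        tol: float = 1e-9,
        max_iter: int = 100_000,
    ):
        self.prior = prior
        self.lambda1 = lambda1
        self.lambda2 = lambda2
        self.var_retained = var_retained
        self.tol = tol
        self.max_iter = max_iter

    def _check_prior(self, y):
        if self.prior is None:
            raise ValueError("AffinityRegression requires a regulon prior matrix")
        D = self.prior
        if isinstance(D, pd.DataFrame) and isinstance(y, pd.DataFrame):
            missing = [g for g in y.columns if g not in D.index]
            if missing:
                raise ValueError(f"prior lacks {len(missing)} genes, e.g. {missing[:5]}")
            D = D.loc[list(y.columns)]
        return D

    def fit(self, X, y):
        """Fit W from ``X`` (cells x proteins) and ``y`` (cells x genes)."""
        D = self._check_prior(y)
        Xv, yv = _values(X), _values(y)
        if Xv.ndim != 2 or yv.ndim != 2:
            raise ValueError("X and y must be 2-D")
        if Xv.shape[0] != yv.shape[0]:
            raise ValueError(
                f"X has {Xv.shape[0]} cells but y has {yv.shape[0]}"
            )
        Y = y.T if isinstance(y, pd.DataFrame) else yv.T  # genes x cells
        sys = build_reduced_system(Y, D, X, self.var_retained)
        self.reduced_system_ = sys
        self.interaction_ = _fit(sys, float(self.lambda1), float(self.lambda2),
                                 self.tol, self.max_iter)
        self.W_ = self.interaction_.to_frame()
        self.prior_ = D if isinstance(D, pd.DataFrame) else np.asarray(D)
        self.svd_rank_ = sys.rank
        self.singular_values_ = sys.singular_values
        self.n_iter_ = self.interaction_.n_iter
        self.converged_ = self.interaction_.converged
        self.n_features_in_ = Xv.shape[1]
        return self

    def predict(self, X):
        """Predict expression for new cells: cells x genes ``X W^T D^T``."""
        self._check_fitted()
        Yhat = predict_expression(self.interaction_, self.prior_, X)
        return Yhat.T

    def tf_activity(self, X, zscore: bool = False):
        """Inferred TF activities W P^T (TFs x cells) for protein profiles X."""
        from .inference import infer_tf_activity

        self._check_fitted()
        return infer_tf_activity(self.interaction_, X, zscore=zscore)

    def protein_activity(self, Y):
        """Projected protein activities Y^T D W (cells x proteins) from a
        genes x cells expression matrix."""
        from .inference import infer_protein_activity

        self._check_fitted()
        return infer_protein_activity(Y, self.prior_, self.interaction_)

    def score(self, X, y):
        """Mean per-cell Spearman correlation between predicted and
        measured expression (the field's evaluation metric, in place of R^2)."""
        from .evaluation import spearman_per_cell

        Yhat = self.predict(X)
        rho = spearman_per_cell(
            pd.DataFrame(_values(Yhat).T), pd.DataFrame(_values(y).T)
        )
        return float(np.nanmean(rho.to_numpy()))

    def _check_fitted(self):
        if not hasattr(self, "interaction_"):
            raise AttributeError("this AffinityRegression instance is not fitted yet")
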