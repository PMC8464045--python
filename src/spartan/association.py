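"""TF-receptor association analysis: correlation, pathway co-occurrence
enrichment, and protein-based cell-state clustering.

Within a cell type, inferred TF activities are correlated (Pearson) with
surface-protein expression across cells. The resulting TF-protein pairs
are tested for enrichment of shared pathway membership: pairs are labelled
correlated (|r| > 0.4) or uncorrelated (|r| < 0.2), the intermediate band
is excluded, and a one-sided hypergeometric test asks whether correlated
pairs share at least one annotated pathway more often than chance.

Cell states are defined by hierarchical clustering of the protein matrix
(Ward linkage on correlation distance) with an iterative refinement: the
dendrogram is first cut into ``init_groups`` clusters and the group count
is decremented until every cluster shows at least two differential
surface proteins (cluster-vs-rest rank-sum test, BH-FDR < 0.05).
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import logging
import warnings

import numpy as np
import pandas as pd
from gseapy.parser import read_gmt as _gseapy_read_gmt
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from scipy.stats import hypergeom, mannwhitneyu
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


def tf_protein_correlation(A: pd.DataFrame, P: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation between every TF activity row of ``A``
    (TFs x cells) and every protein column of ``P`` (cells x proteins),
    computed across the shared cells. Zero-variance features give NaN."""
    cells = [c for c in A.columns if c in P.index]
    if len(cells) < 3:
        raise ValueError(f"need >= 3 shared cells, got {len(cells)}")
    Av = A[cells].to_numpy(float)  # Q x M
    Pv = P.loc[cells].to_numpy(float)  # M x S
    Ac = Av - Av.mean(axis=1, keepdims=True)
    Pc = Pv - Pv.mean(axis=0, keepdims=True)
    sa = np.sqrt((Ac**2).sum(axis=1))
    sp_ = np.sqrt((Pc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Ac @ Pc) / np.outer(sa, sp_)
    r[~np.isfinite(r)] = np.nan
    n_nan = int(np.isnan(r).sum())
    if n_nan:
        log.info("tf_protein_correlation: %d pairs with zero variance -> NaN", n_nan)
    out = pd.DataFrame(r, index=A.index, columns=P.columns)
    out.attrs["n_cells"] = len(cells)
    return out


def read_gmt(path) -> dict[str, list[str]]:
    """Read MSigDB-style GMT pathway annotations (name, description,
    member symbols per line)."""
    return _gseapy_read_gmt(str(path))


def load_protein_aliases(path=None) -> dict[str, str]:
    """ADT antibody name -> gene symbol map used for GMT lookups
    (e.g. CD279 -> PDCD1). Ships with an editable default table."""
    if path is None:
        ref = importlib.resources.files("spartan").joinpath("data/protein_aliases.tsv")
        with importlib.resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t", comment="#", header=None)
    else:
        df = pd.read_csv(path, sep="\t", comment="#", header=None)
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


def build_cooccurrence(
    pathways: dict[str, list[str]],
    tf_ids,
    protein_ids,
    aliases: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Binary TFs x proteins matrix, 1 iff the pair shares at least one
    annotated pathway. Protein (antibody) names are mapped to gene symbols
    through ``aliases`` before lookup; unmapped names are used verbatim."""
    aliases = aliases or {}
    members = {name: set(genes) for name, genes in pathways.items()}
    cooc = pd.DataFrame(0, index=list(tf_ids), columns=list(protein_ids), dtype=np.int8)
    for prot in cooc.columns:
        symbol = aliases.get(str(prot), str(prot))
        prot_paths = {name for name, g in members.items() if symbol in g}
        if not prot_paths:
            continue
        for tf in cooc.index:
            if any(str(tf) in members[name] for name in prot_paths):
                cooc.at[tf, prot] = 1
    return cooc


def enrichment_test(
    corr: pd.DataFrame,
    cooc: pd.DataFrame,
    r_hi: float = 0.4,
    r_lo: float = 0.2,
) -> tuple[np.ndarray, float]:
    """Hypergeometric enrichment of pathway co-occurrence among correlated
    TF-protein pairs.

    Pairs with |r| > ``r_hi`` are "correlated", |r| < ``r_lo``
    "uncorrelated"; NaNs and the intermediate band are excluded. Returns
    the 2x2 contingency table (rows: shares a pathway yes/no; columns:
    correlated/uncorrelated) and the upper-tail hypergeometric p-value of
    at least the observed overlap.
    """
    cooc = cooc.loc[corr.index, corr.columns]
    r = corr.to_numpy(float).ravel()
    share = cooc.to_numpy().astype(bool).ravel()
    keep = ~np.isnan(r)
    r, share = r[keep], share[keep]
    correlated = np.abs(r) > r_hi
    uncorrelated = np.abs(r) < r_lo
    band = correlated | uncorrelated
    r, share, correlated = r[band], share[band], correlated[band]
    n_corr = int(correlated.sum())
    n_unc = int(len(r) - n_corr)
    if n_corr == 0 or n_unc == 0:
        raise ValueError(
            f"degenerate contingency margin: correlated={n_corr}, uncorrelated={n_unc}"
        )
    a = int((share & correlated).sum())
    b = int((share & ~correlated).sum())
    c = int((~share & correlated).sum())
    d = int((~share & ~correlated).sum())
    table = np.array([[a, b], [c, d]])
    N = a + b + c + d
    p = float(hypergeom.sf(a - 1, N, a + b, a + c))
    return table, p


@dataclasses.dataclass
class ClusterAssignment:
    """Protein-based cell-state clusters plus their differential-protein
    evidence."""

    labels: pd.Series  # cell -> cluster id (1-based)
    markers: pd.DataFrame  # cluster, protein, effect, p, q
    n_groups: int
    n_iterations: int
    converged: bool  # False when no cut down to 2 groups qualified


def _rank_test(x: np.ndarray, y: np.ndarray) -> float:
    if np.ptp(np.concatenate([x, y])) == 0:
        return 1.0
    return float(mannwhitneyu(x, y, alternative="two-sided").pvalue)


def _marker_table(X: pd.DataFrame, labels: np.ndarray, fdr: float) -> pd.DataFrame:
    rows = []
    for cl in np.unique(labels):
        in_cl = labels == cl
        if in_cl.all() or not in_cl.any():
            continue
        pvals, effects = [], []
        for prot in X.columns:
            x = X.loc[in_cl, prot].to_numpy()
            y = X.loc[~in_cl, prot].to_numpy()
            pvals.append(_rank_test(x, y))
            effects.append(float(x.mean() - y.mean()))
        qvals = multipletests(pvals, method="fdr_bh")[1]
        for prot, eff, p, q in zip(X.columns, effects, pvals, qvals):
            rows.append(dict(cluster=int(cl), protein=prot, effect=eff, p=p, q=q))
    return pd.DataFrame(rows, columns=["cluster", "protein", "effect", "p", "q"])


def cluster_cells_by_protein(
    P: pd.DataFrame,
    exclude: list[str] | tuple[str, ...] = (),
    init_groups: int = 10,
    fdr: float = 0.05,
    min_markers: int = 2,
) -> ClusterAssignment:
    """Ward-linkage hierarchical clustering of cells on correlation
    distance, refined by a differential-protein criterion.

    Starting from ``init_groups`` clusters, the same dendrogram is re-cut
    with one fewer group whenever any cluster lacks ``min_markers``
    proteins differential vs all other cells at BH q < ``fdr``; the
    process is deterministic and stops at the first qualifying cut or at
    2 groups (returned with ``converged=False`` if still unqualified).
    Lineage-marker proteins can be excluded from the clustering (they
    still appear in the marker tests).
    """
    if P.shape[0] < init_groups:
        raise ValueError(f"need >= {init_groups} cells, got {P.shape[0]}")
    X = P.drop(columns=list(exclude)) if exclude else P
    d = pdist(X.to_numpy(float), metric="correlation")
    d = np.nan_to_num(d, nan=0.0)  # constant cells are maximally similar
    Z = linkage(d, method="ward")
    n_iter = 0
    labels = None
    for g in range(init_groups, 1, -1):
        n_iter += 1
        labels = fcluster(Z, t=g, criterion="maxclust")
        markers = _marker_table(P, labels, fdr)
        if len(np.unique(labels)) < 2 or markers.empty:
            continue
        per_cluster = markers[markers["q"] < fdr].groupby("cluster").size()
        if all(per_cluster.get(cl, 0) >= min_markers for cl in np.unique(labels)):
            return _finish(P, labels, fdr, n_iter, converged=True)
    warnings.warn(
        "no cut down to 2 groups met the differential-protein criterion; "
        "returning the 2-group cut",
        UserWarning,
    )
    return _finish(P, labels, fdr, n_iter, converged=False)


def _finish(P, labels, fdr, n_iter, converged) -> ClusterAssignment:
    labels_s = _canonicalize(pd.Series(labels, index=P.index, name="cluster"))
    markers = _marker_table(P, labels_s.to_numpy(), fdr)
    return ClusterAssignment(
        labels_s, markers, int(labels_s.nunique()), n_iter, converged
    )


def _canonicalize(labels: pd.Series) -> pd.Series:
    """Relabel clusters 1..k by the sorted smallest member barcode so ids
    do not depend on cell input order."""
    first = labels.groupby(labels).apply(lambda s: min(map(str, s.index)))
    order = {old: new for new, old in enumerate(first.sort_values().index, start=1)}
    return labels.map(order)


def differential_activity(A: pd.DataFrame, clusters: ClusterAssignment) -> pd.DataFrame:
    """Cluster-vs-rest differential TF activity.

    For each TF and cluster: two-sample rank-sum test of cells in the
    cluster against all other cells, effect size = difference of means,
    BH-FDR across TFs within each cluster. Returns a tidy table
    (tf, cluster, effect, p, q).
    """
    labels = clusters.labels.reindex(A.columns)
    if labels.isna().any():
        raise ValueError("cluster assignment missing for some cells in A")
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least 2 clusters")
    rows = []
    Av = A.to_numpy(float)
    lab = labels.to_numpy()
    for cl in uniq:
        in_cl = lab == cl
        pvals, effects = [], []
        for i in range(Av.shape[0]):
            x, y = Av[i, in_cl], Av[i, ~in_cl]
            pvals.append(_rank_test(x, y))
            effects.append(float(x.mean() - y.mean()))
        qvals = multipletests(pvals, method="fdr_bh")[1]
        for tf, eff, p, q in zip(A.index, effects, pvals, qvals):
            rows.append(dict(tf=tf, cluster=int(cl), effect=eff, p=p, q=q))
    return pd.DataFrame(rows, columns=["tf", "cluster", "effect", "p", "q"])


def top_differential(table: pd.DataFrame, k: int = 20) -> pd.DataFrame:
    """Union over clusters of the top-k features by absolute effect size
    (the display convention for cluster heatmaps)."""
    tops = (
        table.assign(abs_effect=table["effect"].abs())
        .sort_values("abs_effect", ascending=False)
        .groupby("cluster")
        .head(k)
    )
    keep = tops["tf"].unique() if "tf" in table.columns else tops["protein"].unique()
    col = "tf" if "tf" in table.columns else "protein"
    return table[table[col].isin(keep)].reset_index(drop=True)
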