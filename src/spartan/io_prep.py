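"""Input handling for CITE-seq count data and regulon priors.

Covers reading CellRanger-style MTX triplets and dense CSV/TSV count
tables, cell-level quality control, the normalisations used for model
training (library-size log-normalisation for RNA, centred log-ratio for
ADT), construction of the binary TF-target prior matrix, and the final
alignment / unit-normalisation step that puts the three matrices on a
common set of genes and cells.

Conventions (used throughout the package)
-----------------------------------------
``Y``  genes x cells    log-normalised gene expression (DataFrame)
``P``  cells x proteins CLR-normalised ADT values      (DataFrame)
``D``  genes x TFs      binary regulon membership      (DataFrame)

Normalisation provenance is recorded in ``DataFrame.attrs["normalization"]``.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

log = logging.getLogger(__name__)

MODALITIES = ("rna", "adt")


@dataclasses.dataclass
class RawCounts:
    """A features x cells matrix of non-negative integer UMI/ADT counts.

    ``matrix`` is stored as CSR; ``feature_ids`` are gene symbols (RNA) or
    antibody names (ADT) and must be unique, as must ``cell_barcodes``.
    """

    matrix: sp.csr_matrix
    feature_ids: list[str]
    cell_barcodes: list[str]
    modality: str

    def __post_init__(self) -> None:
        if not sp.issparse(self.matrix):
            self.matrix = sp.csr_matrix(np.asarray(self.matrix))
        else:
            self.matrix = self.matrix.tocsr()
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.cell_barcodes = [str(b) for b in self.cell_barcodes]
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}, got {self.modality!r}")
        n_feat, n_cell = self.matrix.shape
        if n_feat != len(self.feature_ids):
            raise ValueError(
                f"matrix has {n_feat} rows but {len(self.feature_ids)} feature ids"
            )
        if n_cell != len(self.cell_barcodes):
            raise ValueError(
                f"matrix has {n_cell} columns but {len(self.cell_barcodes)} barcodes"
            )
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("feature_ids are not unique")
        if len(set(self.cell_barcodes)) != len(self.cell_barcodes):
            raise ValueError("cell_barcodes are not unique")
        data = self.matrix.data
        if data.size and (data.min() < 0 or np.any(np.mod(data, 1) != 0)):
            raise ValueError("counts must be non-negative integers")
        self.matrix = self.matrix.astype(np.int64)

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def to_frame(self) -> pd.DataFrame:
        """Dense features x cells DataFrame view."""
        return pd.DataFrame(
            self.matrix.toarray(), index=self.feature_ids, columns=self.cell_barcodes
        )


def _dedupe(names: Sequence[str]) -> list[str]:
    """Disambiguate duplicate names deterministically: later occurrences get
    suffixes ``.1``, ``.2``, ... in file order."""
    seen: dict[str, int] = {}
    out = []
    for name in names:
        name = str(name)
        if name in seen:
            seen[name] += 1
            out.append(f"{name}.{seen[name]}")
        else:
            seen[name] = 0
            out.append(name)
    return out


def _find(dirpath: Path, stem: str) -> Path:
    for cand in (dirpath / stem, dirpath / f"{stem}.gz"):
        if cand.exists():
            return cand
    raise FileNotFoundError(f"missing {stem}[.gz] in {dirpath}")


def read_counts(path: str | Path, format: str | None = None, modality: str = "rna") -> RawCounts:
    """Read a count matrix from an MTX triplet directory or a dense table.

    Parameters
    ----------
    path
        MTX directory (``matrix.mtx[.gz]``, ``features.tsv[.gz]``,
        ``barcodes.tsv[.gz]``) or a CSV/TSV file with feature ids in the
        first column and cell barcodes as header.
    format
        ``"mtx_dir"``, ``"csv"`` or ``"tsv"``; inferred from ``path`` when
        omitted.
    modality
        ``"rna"`` or ``"adt"``.
    """
    path = Path(path)
    if format is None:
        if path.is_dir():
            format = "mtx_dir"
        elif path.suffix in (".csv",):
            format = "csv"
        elif path.suffix in (".tsv", ".txt"):
            format = "tsv"
        else:
            raise ValueError(f"cannot infer format from {path}")
    if format == "mtx_dir":
        if not path.is_dir():
            raise FileNotFoundError(f"not a directory: {path}")
        mtx = _find(path, "matrix.mtx")
        feats = _find(path, "features.tsv")
        bars = _find(path, "barcodes.tsv")
        mat = sp.csr_matrix(mmread(str(mtx)))
        ftab = pd.read_csv(feats, sep="\t", header=None, dtype=str)
        # CellRanger features.tsv: id, symbol, feature type; use the symbol
        # column when present since priors are keyed by gene symbol.
        names = ftab.iloc[:, 1] if ftab.shape[1] >= 2 else ftab.iloc[:, 0]
        barcodes = pd.read_csv(bars, sep="\t", header=None, dtype=str).iloc[:, 0]
        if mat.shape != (len(names), len(barcodes)):
            raise ValueError(
                f"MTX header {mat.shape} does not match {len(names)} features x "
                f"{len(barcodes)} barcodes in {path}"
            )
        return RawCounts(mat, _dedupe(names), _dedupe(barcodes), modality)
    if format in ("csv", "tsv"):
        if not path.exists():
            raise FileNotFoundError(f"missing file: {path}")
        df = pd.read_csv(path, sep="," if format == "csv" else "\t", index_col=0)
        return RawCounts(
            sp.csr_matrix(df.to_numpy()), _dedupe(df.index), _dedupe(df.columns), modality
        )
    raise ValueError(f"unknown format {format!r}")


def write_counts(counts: RawCounts, path: str | Path, format: str = "mtx_dir") -> None:
    """Write counts back out (MTX triplet directory or dense CSV/TSV)."""
    path = Path(path)
    if format == "mtx_dir":
        path.mkdir(parents=True, exist_ok=True)
        mmwrite(str(path / "matrix.mtx"), sp.coo_matrix(counts.matrix))
        feat = pd.DataFrame(
            {0: counts.feature_ids, 1: counts.feature_ids, 2: "Gene Expression"}
        )
        feat.to_csv(path / "features.tsv", sep="\t", header=False, index=False)
        pd.Series(counts.cell_barcodes).to_csv(
            path / "barcodes.tsv", sep="\t", header=False, index=False
        )
    elif format in ("csv", "tsv"):
        counts.to_frame().to_csv(path, sep="," if format == "csv" else "\t")
    else:
        raise ValueError(f"unknown format {format!r}")


def qc_filter_cells(rna: RawCounts, min_genes: int = 300, max_genes: int = 5000) -> RawCounts:
    """Keep cells expressing between ``min_genes`` and ``max_genes`` genes
    (bounds inclusive); the upper bound guards against doublets."""
    if rna.modality != "rna":
        raise ValueError("qc_filter_cells expects RNA counts")
    expressed = (rna.matrix > 0).sum(axis=0).A1
    keep = (expressed >= min_genes) & (expressed <= max_genes)
    removed = [b for b, k in zip(rna.cell_barcodes, keep) if not k]
    if removed:
        log.info("qc_filter_cells removed %d cells: %s%s", len(removed),
                 ",".join(removed[:5]), "..." if len(removed) > 5 else "")
    if not keep.any():
        raise ValueError(
            "all cells removed by QC; review min_genes/max_genes thresholds"
        )
    return RawCounts(
        rna.matrix[:, keep],
        rna.feature_ids,
        [b for b, k in zip(rna.cell_barcodes, keep) if k],
        "rna",
    )


def filter_genes_by_umi(rna: RawCounts, min_umi: int = 3, min_cell_frac: float = 0.01) -> RawCounts:
    """Optional gene filter: keep genes with >= ``min_umi`` counts in at least
    ``min_cell_frac`` of cells. Off by default in the pipeline."""
    n_cells = rna.shape[1]
    enough = (rna.matrix >= min_umi).sum(axis=1).A1
    keep = enough >= np.ceil(min_cell_frac * n_cells)
    log.info("filter_genes_by_umi kept %d/%d genes", int(keep.sum()), len(keep))
    return RawCounts(
        rna.matrix[keep],
        [f for f, k in zip(rna.feature_ids, keep) if k],
        rna.cell_barcodes,
        rna.modality,
    )


def log_normalize_rna(rna: RawCounts, size_factor: float = 10_000.0) -> pd.DataFrame:
    """Library-size log-normalisation: ``ln(1 + size_factor * c / total)`` per
    cell, the standard scRNA-seq recipe. Returns a genes x cells DataFrame."""
    totals = np.asarray(rna.matrix.sum(axis=0)).ravel().astype(float)
    if np.any(totals <= 0):
        bad = [b for b, t in zip(rna.cell_barcodes, totals) if t <= 0]
        raise ValueError(f"cells with zero total counts (run QC first): {bad[:5]}")
    dense = rna.matrix.toarray().astype(float)
    out = np.log1p(size_factor * dense / totals[None, :])
    df = pd.DataFrame(out, index=rna.feature_ids, columns=rna.cell_barcodes)
    df.attrs["normalization"] = "lognorm"
    return df


def clr_normalize_adt(adt: RawCounts, variant: str = "centered") -> pd.DataFrame:
    """Centred log-ratio transform of ADT counts, centred across cells.

    The default variant is ``clr_ij = ln(1 + x_ij) - mean_j' ln(1 + x_ij')``
    per protein i, which guarantees a zero mean across cells for every
    protein. ``variant="seurat"`` reproduces Seurat's log1p/geometric-mean
    formula instead. Returns a cells x proteins DataFrame.
    """
    if adt.modality != "adt":
        raise ValueError("clr_normalize_adt expects ADT counts")
    x = adt.matrix.toarray().astype(float)  # proteins x cells
    logx = np.log1p(x)
    zero = ~x.any(axis=1)
    if zero.any():
        names = [f for f, z in zip(adt.feature_ids, zero) if z]
        log.warning("proteins with all-zero counts map to zero CLR columns: %s", names)
    if variant == "centered":
        out = logx - logx.mean(axis=1, keepdims=True)
    elif variant == "seurat":
        geo = np.exp(logx.mean(axis=1, keepdims=True))
        out = np.log1p(x / geo)
    else:
        raise ValueError(f"unknown CLR variant {variant!r}")
    df = pd.DataFrame(out.T, index=adt.cell_barcodes, columns=adt.feature_ids)
    df.attrs["normalization"] = f"clr:{variant}"
    return df


def read_prior_edges(path: str | Path) -> pd.DataFrame:
    """Read a TF->target edge list (2-3 column TSV: tf, gene[, sign])."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"prior edge list {path} needs at least 2 columns")
    # tolerate a header row
    if str(df.iloc[0, 0]).lower() in ("tf", "source") :
        df = df.iloc[1:]
    df = df.iloc[:, :2]
    df.columns = ["tf", "gene"]
    return df.reset_index(drop=True)


def build_prior_matrix(
    edges: pd.DataFrame | Iterable[tuple[str, str]],
    gene_universe: Sequence[str],
    expressed_tfs: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Build the binary genes x TFs regulon-membership matrix D.

    Edges pointing outside ``gene_universe`` are dropped (counted in the
    log); TFs not in ``expressed_tfs`` (when given) and TFs left without any
    surviving target are removed. Duplicate edges are idempotent.
    """
    if isinstance(edges, pd.DataFrame):
        pairs = list(zip(edges["tf"].astype(str), edges["gene"].astype(str)))
    else:
        pairs = [(str(t), str(g)) for t, g in edges]
    if not pairs:
        raise ValueError("empty edge list")
    universe = list(dict.fromkeys(str(g) for g in gene_universe))
    uset = set(universe)
    kept = [(t, g) for t, g in pairs if g in uset]
    if len(kept) < len(pairs):
        log.info("dropped %d edges outside the gene universe", len(pairs) - len(kept))
    if expressed_tfs is not None:
        eset = {str(t) for t in expressed_tfs}
        kept = [(t, g) for t, g in kept if t in eset]
    tfs = sorted({t for t, _ in kept})
    D = pd.DataFrame(0, index=universe, columns=tfs, dtype=np.int8)
    for t, g in kept:
        D.at[g, t] = 1
    nonzero = D.columns[D.sum(axis=0) > 0]
    if len(nonzero) < D.shape[1]:
        log.info("removed %d TFs with no surviving targets", D.shape[1] - len(nonzero))
    D = D[nonzero]
    if D.shape[1] == 0:
        raise ValueError("no TFs survive prior filtering")
    return D


def read_cell_labels(path: str | Path) -> pd.Series:
    """Read a 2-column TSV (barcode, cell-type label) into a Series."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    return pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values, name="label")


def _unit_normalize(values: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(values, axis=0)
    norms[norms == 0] = 1.0
    return values / norms


def align_and_unit_normalize(
    Y: pd.DataFrame, P: pd.DataFrame, D: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Restrict Y, P, D to shared cells and genes and L2-normalise columns.

    Cells shared by Y (columns) and P (rows) are kept in Y's order; likewise
    genes shared by Y (rows) and D (rows). All-zero columns (cells of Y,
    proteins of P, TFs of D) are dropped with dependent bookkeeping before
    each remaining column is divided by its L2 norm.
    """
    cells = Y.columns[Y.columns.isin(P.index)]
    if len(cells) == 0:
        raise ValueError("alignment failed: no shared cell barcodes (Y vs P)")
    genes = Y.index[Y.index.isin(D.index)]
    if len(genes) == 0:
        raise ValueError("alignment failed: no shared gene ids (Y vs D)")
    Y = Y.loc[genes, cells]
    P = P.loc[cells]
    D = D.loc[genes]
    for _ in range(3):  # drops can cascade at most cells -> proteins
        changed = False
        zero_cells = Y.columns[np.linalg.norm(Y.to_numpy(), axis=0) == 0]
        if len(zero_cells):
            log.info("dropping %d all-zero cells during alignment", len(zero_cells))
            Y = Y.drop(columns=zero_cells)
            P = P.drop(index=zero_cells)
            changed = True
        zero_prot = P.columns[np.linalg.norm(P.to_numpy(), axis=0) == 0]
        if len(zero_prot):
            log.info("dropping all-zero protein columns: %s", list(zero_prot))
            P = P.drop(columns=zero_prot)
            changed = True
        zero_tfs = D.columns[np.linalg.norm(D.to_numpy().astype(float), axis=0) == 0]
        if len(zero_tfs):
            log.info("dropping TF columns without targets: %s", list(zero_tfs))
            D = D.drop(columns=zero_tfs)
            changed = True
        if not changed:
            break
    if Y.shape[1] == 0 or P.shape[1] == 0 or D.shape[1] == 0:
        raise ValueError("alignment left an empty matrix")
    Yn = pd.DataFrame(_unit_normalize(Y.to_numpy(float)), index=Y.index, columns=Y.columns)
    Pn = pd.DataFrame(_unit_normalize(P.to_numpy(float)), index=P.index, columns=P.columns)
    Dn = pd.DataFrame(_unit_normalize(D.to_numpy(float)), index=D.index, columns=D.columns)
    for df, src in ((Yn, Y), (Pn, P), (Dn, D)):
        df.attrs.update(src.attrs)
        df.attrs["normalization"] = df.attrs.get("normalization", "") + "+unitnorm"
    return Yn, Pn, Dn
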