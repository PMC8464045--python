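"""Synthetic CITE-seq-like fixtures with planted bilinear structure.

The generator emits exactly the objects the model assumes: a sparse
binary regulon prior D, a planted interaction matrix W*, a non-negative
latent protein matrix P, and expression Y = D W* P^T plus Gaussian noise
at a requested SNR. Raw UMI-like counts are emulated by inverting the
pipeline's normalisations - multinomial sampling per cell with
probabilities softmax-shaped from the expression column, and Poisson ADT
counts with exp-scaled rates - so the I/O and normalisation path can be
tested end to end without external downloads. Every output is a pure
function of the configuration (seed included).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io_prep import RawCounts, align_and_unit_normalize, write_counts


@dataclasses.dataclass
class SimConfig:
    """Study conditions for a synthetic CITE-seq cohort.

    Exactly one of ``noise_sd`` / ``snr`` must be set; ``snr`` is the
    expected ratio ||Y_clean||_F^2 / ||noise||_F^2. ``count_depth`` is the
    per-cell UMI depth for the raw-count emulation and ``softmax_scale``
    the temperature (per-cell z-score scale) of the multinomial
    probabilities.
    """

    n_genes: int = 200
    n_cells: int = 100
    n_tfs: int = 20
    n_proteins: int = 10
    prior_density: float = 0.1
    w_sparsity: float = 0.3
    noise_sd: float | None = None
    snr: float | None = 10.0
    count_depth: int = 5000
    seed: int = 0
    softmax_scale: float = 1.0
    adt_rate_scale: float = 10.0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_cells", "n_tfs", "n_proteins"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0 < self.prior_density <= 1):
            raise ValueError("prior_density must be in (0, 1]")
        if not (0 <= self.w_sparsity < 1):
            raise ValueError("w_sparsity must be in [0, 1)")
        if (self.noise_sd is None) == (self.snr is None):
            raise ValueError("set exactly one of noise_sd / snr")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclasses.dataclass
class SimInstance:
    """A generated cohort: raw counts for the I/O path plus the latent
    truth (D, W*, P, clean and observed Y) for recovery checks."""

    rna: RawCounts
    adt: RawCounts
    D: pd.DataFrame
    W_star: pd.DataFrame
    P_latent: pd.DataFrame
    Y_clean: pd.DataFrame
    Y_obs: pd.DataFrame
    config: SimConfig


def _ids(prefix: str, n: int) -> list[str]:
    width = len(str(n))
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


def _sample_prior(rng: np.random.Generator, cfg: SimConfig) -> np.ndarray:
    D = (rng.random((cfg.n_genes, cfg.n_tfs)) < cfg.prior_density).astype(np.int8)
    for j in np.flatnonzero(D.sum(axis=0) == 0):  # every TF needs >= 1 target
        D[rng.integers(cfg.n_genes), j] = 1
    return D


def _emit_counts(
    rng: np.random.Generator, cfg: SimConfig, Y: np.ndarray, P: np.ndarray,
    gene_ids, cell_ids, protein_ids,
) -> tuple[RawCounts, RawCounts]:
    # RNA: multinomial per cell at count_depth, probabilities softmax-shaped
    # from the (per-cell standardized) expression column.
    Z = Y - Y.mean(axis=0, keepdims=True)
    sd = Y.std(axis=0, keepdims=True)
    sd[sd == 0] = 1.0
    Z = cfg.softmax_scale * Z / sd
    prob = np.exp(Z - Z.max(axis=0, keepdims=True))
    prob /= prob.sum(axis=0, keepdims=True)
    rna_counts = np.column_stack(
        [rng.multinomial(cfg.count_depth, prob[:, j]) for j in range(Y.shape[1])]
    )
    rna = RawCounts(sp.csr_matrix(rna_counts), gene_ids, cell_ids, "rna")
    # ADT: Poisson with exp-scaled rates so CLR recovers the latent ranks.
    lam = cfg.adt_rate_scale * np.exp(P)
    adt_counts = rng.poisson(lam).T  # proteins x cells
    adt = RawCounts(sp.csr_matrix(adt_counts), protein_ids, cell_ids, "adt")
    return rna, adt


def generate_instance(
    cfg: SimConfig, truth: tuple[pd.DataFrame, pd.DataFrame] | None = None
) -> SimInstance:
    """Generate a cohort with planted bilinear structure.

    ``truth=(D, W_star)`` reuses an existing prior and interaction matrix
    (e.g. to draw an independent validation cohort from the same model).
    """
    rng = np.random.default_rng(cfg.seed)
    gene_ids = _ids("G", cfg.n_genes)
    cell_ids = _ids("cell_", cfg.n_cells)
    tf_ids = _ids("TF", cfg.n_tfs)
    protein_ids = _ids("ADT", cfg.n_proteins)
    if truth is not None:
        D_df, W_df = truth
        D = D_df.to_numpy()
        W = W_df.to_numpy(float)
        gene_ids, tf_ids = list(D_df.index), list(D_df.columns)
        protein_ids = list(W_df.columns)
        # keep the RNG stream identical whether or not truth is supplied
        _sample_prior(rng, cfg)
        rng.standard_normal((cfg.n_tfs, cfg.n_proteins))
        rng.random((cfg.n_tfs, cfg.n_proteins))
    else:
        D = _sample_prior(rng, cfg)
        W = rng.standard_normal((cfg.n_tfs, cfg.n_proteins))
        if cfg.w_sparsity > 0:
            W[rng.random(W.shape) < cfg.w_sparsity] = 0.0
    P = np.abs(rng.standard_normal((cfg.n_cells, len(protein_ids))))
    Y_clean = D @ W @ P.T
    if cfg.noise_sd is not None:
        sd = cfg.noise_sd
    else:
        sd = np.linalg.norm(Y_clean) / np.sqrt(cfg.snr * Y_clean.size)
    Y_obs = Y_clean + sd * rng.standard_normal(Y_clean.shape)
    rna, adt = _emit_counts(rng, cfg, Y_obs, P, gene_ids, cell_ids, protein_ids)
    return SimInstance(
        rna,
        adt,
        pd.DataFrame(D, index=gene_ids, columns=tf_ids),
        pd.DataFrame(W, index=tf_ids, columns=protein_ids),
        pd.DataFrame(P, index=cell_ids, columns=protein_ids),
        pd.DataFrame(Y_clean, index=gene_ids, columns=cell_ids),
        pd.DataFrame(Y_obs, index=gene_ids, columns=cell_ids),
        cfg,
    )


def generate_null_instance(cfg: SimConfig) -> SimInstance:
    """Same outputs, but Y is pure noise, independent of D and P - the
    ground truth for significance calibration and chance-level CV."""
    rng = np.random.default_rng(cfg.seed)
    gene_ids = _ids("G", cfg.n_genes)
    cell_ids = _ids("cell_", cfg.n_cells)
    tf_ids = _ids("TF", cfg.n_tfs)
    protein_ids = _ids("ADT", cfg.n_proteins)
    D = _sample_prior(rng, cfg)
    W = rng.standard_normal((cfg.n_tfs, cfg.n_proteins))  # irrelevant to Y
    P = np.abs(rng.standard_normal((cfg.n_cells, cfg.n_proteins)))
    sd = cfg.noise_sd if cfg.noise_sd is not None else 1.0
    Y_obs = sd * rng.standard_normal((cfg.n_genes, cfg.n_cells))
    rna, adt = _emit_counts(rng, cfg, Y_obs, P, gene_ids, cell_ids, protein_ids)
    return SimInstance(
        rna,
        adt,
        pd.DataFrame(D, index=gene_ids, columns=tf_ids),
        pd.DataFrame(W, index=tf_ids, columns=protein_ids),
        pd.DataFrame(P, index=cell_ids, columns=protein_ids),
        pd.DataFrame(np.zeros_like(Y_obs), index=gene_ids, columns=cell_ids),
        pd.DataFrame(Y_obs, index=gene_ids, columns=cell_ids),
        cfg,
    )


def latent_training_data(
    inst: SimInstance,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Aligned, unit-normalized (Y, P, D) built from the latent matrices
    (bypassing the count emulation) - the standard input for recovery
    experiments."""
    return align_and_unit_normalize(inst.Y_obs, inst.P_latent, inst.D)


def planted_protein_clusters(
    n_per_group: int = 6,
    n_proteins: int = 10,
    n_shifted: int = 3,
    shift: float = 3.0,
    noise_sd: float = 0.5,
    seed: int = 13,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Two well-separated cell blobs differing in ``n_shifted`` proteins.

    Cells share a per-protein baseline profile (so same-blob cells are
    highly correlated); the second blob is shifted by ``shift`` on the
    first ``n_shifted`` proteins. Group sizes are deliberately small so
    that cluster-vs-rest tests are decisive only at the true two-group
    cut. Returns the cells x proteins matrix and the true labels (0/1).
    """
    rng = np.random.default_rng(seed)
    baseline = 2.0 * rng.standard_normal(n_proteins)
    n_cells = 2 * n_per_group
    truth = np.repeat([0, 1], n_per_group)
    X = baseline + noise_sd * rng.standard_normal((n_cells, n_proteins))
    X[truth == 1, :n_shifted] += shift
    cells = _ids("cell_", n_cells)
    prots = _ids("ADT", n_proteins)
    return pd.DataFrame(X, index=cells, columns=prots), truth


def write_instance(inst: SimInstance, out_dir: str | Path) -> None:
    """Write a cohort as plain-text fixtures: MTX triplet directories for
    RNA/ADT counts, the prior as an edge list, and the latent truth as
    TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_counts(inst.rna, out / "rna", format="mtx_dir")
    write_counts(inst.adt, out / "adt", format="mtx_dir")
    edges = [
        (tf, gene)
        for tf in inst.D.columns
        for gene in inst.D.index[inst.D[tf] > 0]
    ]
    pd.DataFrame(edges).to_csv(out / "prior_edges.tsv", sep="\t", header=False, index=False)
    inst.W_star.to_csv(out / "truth_W_star.tsv", sep="\t")
    inst.P_latent.to_csv(out / "truth_P_latent.tsv", sep="\t")
    with open(out / "sim_config.json", "w") as fh:
        json.dump(dataclasses.asdict(inst.config), fh, indent=2)
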