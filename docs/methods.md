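# Methods

## Model

The package links two single-cell measurements made on the same cells —
a genes × cells expression matrix **Y** and a cells × proteins
surface-protein (ADT) matrix **P** — through a binary genes × TFs
regulon prior **D** (which genes each transcription factor is believed
to regulate). The working hypothesis is that surface-receptor signaling
converges on transcription factors whose regulons shape expression, so
expression is modelled bilinearly:

    D W Pᵀ ≈ Y,

with **W** (TFs × proteins) the unknown interaction matrix. Column-wise
vectorization turns the bilinear fit into ordinary least squares,
`(P ⊗ D) vec(W) ≈ vec(Y)`, which is far too large at single-cell scale
(N·M equations). Left-multiplying both sides by **Yᵀ** compresses it to
M·M equations in the same unknowns:

    (P ⊗ YᵀD) vec(W) ≈ vec(YᵀY).

We minimize the penalized compressed objective

    f(W) = ½‖vec(YᵀY) − (P ⊗ G) vec(W)‖² + (λ₂/2)‖W‖_F² + λ₁‖W‖₁,

with `G = YᵀD`. The ½-scalings are an internal convention chosen so the
λ₁-only stationarity threshold is exactly `‖AᵀB‖∞` and the λ₁ = 0 limit
is the classical ridge solution `(AᵀA + λ₂I)⁻¹Aᵀb`; the ridge limit is
identical to minimizing the unscaled squared-error form, so only the
interpretation of λ₁'s magnitude depends on the convention.

### Assumptions

- Linearity and additivity of TF effects on their targets; no
  activator/repressor sign in **D** (negative activities of repressors
  must be interpreted with prior knowledge).
- The regulon prior is treated as fixed and binary; unit-normalized
  columns give every TF and protein the same prior scale.
- Cells of one model are a single population (the tool is designed to be
  trained per cell type, with labels supplied externally).

## Solvers and numerics

**Ridge (λ₁ = 0).** The compressed normal equations inherit Kronecker
structure: `AᵀA = Pg ⊗ Gg` with `Gg = GᵀG`, `Pg = PᵀP`. With
eigendecompositions `Gg = U diag(a) Uᵀ` and `Pg = V diag(t) Vᵀ`, the
solution is `W = U [ (Uᵀ C V)_{ij} / (a_i t_j + λ₂) ] Vᵀ`,
`C = GᵀBP` — exact, O(Q³ + S³), and testable against the explicit
Kronecker solve. A singular system at λ₂ = 0 raises with advice rather
than silently pseudo-inverting.

**Elastic net.** Cyclic coordinate descent over the entries of W on
precomputed Gram blocks, jitted for speed, always in the *original*
protein coordinates so that exact zeros of the iterate are exact zeros
of W (an L1 penalty is not rotation-invariant, so solving in SVD
coordinates would change the estimator). Convergence is declared when
the maximum KKT violation drops below `tol·max(1, ‖C‖∞)` with
`tol = 1e-9`; an objective-decrease rule was tried first and stalls at
~1e-3 relative accuracy because the constant `½‖B‖²_F` dominates the
objective. The iteration cap is 100 000 sweeps (ill-conditioned Gram
blocks need a few tens of thousands); non-convergence warns and returns
the best iterate with `converged=False`. The incremental residual is
recomputed every 100 sweeps to cancel floating-point drift, and
stagnation at floating-point resolution counts as convergence. Support
monotonicity along a λ₁ path usually holds but is not a theorem; single
support swaps can occur on some instances and are reported as such.

**SVD reduction.** `P` may be replaced by its rank-k truncation keeping
a fraction `var_retained` (default 0.95) of squared singular mass — a
compute device for large antibody panels. Ridge solves run in reduced
coordinates and are rotated back by `V_kᵀ`, which is exactly the
original-coordinate solution because `C V_⊥ = 0`. Recovery experiments
and the acceptance checks use `var_retained = 1.0`: truncation
deliberately discards protein variance and correspondingly caps how well
a planted dense W* can be recovered.

**Identifiability.** W is identifiable only when `G = YᵀD` has full
column rank, which for noise-free data requires rank(Y) ≥ Q, i.e. at
least as many proteins as TFs in the planted model. The noise-free
exact-fit check therefore uses a full-column-rank configuration
(8 TFs ≤ 10 proteins); with more TFs than proteins a noise-free
compressed system is singular and exact interpolation is provably
impossible. Noise-free oracle fixtures also train on *unnormalized* Y:
per-cell unit scaling gives every cell its own factor, which no single W
can absorb exactly (D and P column scalings, by contrast, are absorbed
by W). Per-cell Spearman scoring is invariant to per-cell scaling, so
this matches the evaluation convention.

## Preprocessing

- **Cell QC**: keep cells expressing between 300 and 5000 genes
  (inclusive bounds; the upper bound guards against doublets).
- **RNA**: `ln(1 + 10 000 · c/total)` per cell (library-size
  log-normalisation, pseudocount 1).
- **ADT**: centred log-ratio across cells per protein,
  `ln(1+x) − mean_cells ln(1+x)`, which makes the per-protein mean
  exactly zero — the testable invariant. Seurat's geometric-mean variant
  is available behind `variant="seurat"`.
- **Alignment**: Y, P, D are restricted to shared cells and genes;
  all-zero columns are dropped with dependent bookkeeping (a dead cell
  leaves both Y and P); every remaining column is scaled to unit L2 norm
  for conditioning.
- An optional gene filter (≥3 UMIs in ≥1% of cells) is provided but off
  by default.

## Inference and significance

TF activities are `A = W Pᵀ` (TFs × cells); projected protein
activities are `Yᵀ D W` (cells × proteins). Both are linear read-outs of
the trained model; z-scoring per TF is a display convention only.

The empirical null permutes the *gene labels* (rows) of Y and retrains
with the observed hyperparameters, `n_perm` times (desk-scale default
200; 5000-scale runs are a config change). Permuting rows severs the
Y–D gene correspondence that carries the signal while leaving each
cell's expression distribution — and, notably, the compressed target
`YᵀY` — exactly unchanged. Two-tailed empirical p-values use the +1
correction, `p = min(1, 2·min(b_hi+1, b_lo+1)/(n_perm+1))`, Bonferroni
correction across TFs within each cell, significance at adjusted
p < 0.15, and per-TF frequencies over cells (per cell type when labels
are supplied); BH q-values ride along as an extra column. Permuting
cells instead is available behind `perm_axis="cells"`.

Because row permutations preserve `YᵀY`, permuted designs explain a
similar share of the target with similar-magnitude weights: the null
calibrates the *distribution* of each activity, and calls arise only
where a TF's activity in a cell is extreme relative to that
distribution. A homogeneous i.i.d. synthetic cohort has no such cells,
so it correctly produces (calibrated) near-uniform p-values and no
calls; on heterogeneous real data, calls concentrate in cell states. The
attainability bound `min adjusted p = Q·2/(n_perm+1)` is checked and a
warning is emitted when no call could pass α.

## Evaluation

Per-cell Spearman correlation (average-rank ties; zero-variance columns
score NaN and are excluded from means with a log entry) between
predicted `D W P_testᵀ` and measured expression, under seeded K-fold CV
over cells; ties in CV model selection break toward larger λ₁, then
larger λ₂. The baseline predicts each test cell's expression as its
Euclidean-nearest training cell in protein space (ties to the lowest
index). Paired one-sided Wilcoxon signed-rank compares methods, zero
differences dropped, exact for small samples without ties and a
continuity-corrected normal approximation otherwise.

## Association analyses

Pearson correlation between each TF activity row and each protein
column across cells; pairs split into correlated (|r| > 0.4) and
uncorrelated (|r| < 0.2), the intermediate band excluded as implied by
the two-class definition; a one-sided hypergeometric test (equivalently
Fisher's exact) asks whether correlated pairs share ≥1 annotated
pathway (MSigDB GMT) more often than chance. Antibody names map to gene
symbols through an editable alias table shipped with the package.

Cell states come from Ward-linkage hierarchical clustering on
correlation distance between cells, cut into 10 groups and re-cut with
one fewer group until every cluster shows ≥2 differential proteins
(two-sample rank-sum cluster-vs-rest, BH-FDR < 0.05) — a deterministic
refinement in place of bootstrap support values, since the
differential-protein rule is the testable requirement that defines a
valid cluster. The rank-sum (two-sample) form is used for cluster-vs-rest
comparisons throughout; a signed-rank test would require paired
observations, which cluster comparisons do not have. Cluster ids are
canonicalized by smallest member barcode so labels do not depend on
input order.

## Synthetic data

The generator emits the exact objects the model assumes: `D ~
Bernoulli(0.1)` with ≥1 target per TF enforced, dense Gaussian `W*` with
a 30% zero mask, `P = |N(0,1)|` (non-negative, like CLR-scale ADT
abundances), and `Y = D W* Pᵀ + ε` with ε Gaussian at a requested SNR
(`‖Y_clean‖²_F/‖ε‖²_F`, default 10). Defaults are 200 genes × 100
cells × 20 TFs × 10 proteins — the scale at which every check runs in
seconds on one core.

Raw counts invert the normalisations so the I/O path is testable:
per-cell multinomial draws at depth 5000 with probabilities softmax-
shaped from the z-scored expression column (temperature 1.0), and
Poisson ADT counts with rates `10·exp(P)`. At depth 5000 over 200 genes
the multinomial floor limits worst-cell rank fidelity to ~0.92; by depth
10 000 every cell recovers the latent expression at rank correlation
≥ 0.95, which is where the fidelity property is exercised. A null
generator draws Y independent of D and P for calibration studies. All
outputs are pure functions of the configuration.

The planted-cluster fixture for refinement checks uses two blobs of six
cells sharing a per-protein baseline, with three proteins shifted by
+3 in one blob (noise SD 0.5). Group sizes are deliberately small:
cluster-vs-rest rank-sum tests see the between-blob shift from *any*
sub-blob cut, so only under-powered sub-blob comparisons let the
refinement walk down to the true two-group cut — with larger blobs the
10-group cut would self-certify. This is a designed property of the
fixture, documented so it is not mistaken for generality.

### What passing synthetic tests does and does not show

The generator matches the model's own assumptions (linear bilinear
signal, Gaussian noise, independent cells). It does not emulate
over-dispersed counts, dropout, batch structure, doublets beyond the
max-gene QC bound, or realistic cell-type proportions; passing tests
demonstrate correctness of the algorithms and calibration of the
statistics under the stated model, not robustness to real-data
violations of it.

## Parameter summary

| Parameter | Default | Meaning |
|---|---|---|
| `lambda1` | 0 | L1 penalty (sparsity of W) |
| `lambda2` | 1e-3 | L2 penalty (stability; required when the compressed system is singular) |
| `var_retained` | 0.95 | squared-singular-value mass of P kept by the SVD reduction (1.0 = full rank, None = no SVD) |
| `tol` | 1e-9 | KKT threshold of coordinate descent, relative to `‖AᵀB‖∞` |
| `max_iter` | 100 000 | coordinate-descent sweep cap |
| CV grid | 5×5 log-spaced in [1e-4, 1] | hyperparameter search |
| `folds` | 5 | CV folds over cells (seeded shuffle) |
| `n_perm` | 200 | permutations of the empirical null (5000 for paper-scale runs) |
| `alpha` | 0.15 | Bonferroni-adjusted significance threshold |
| QC bounds | [300, 5000] | expressed genes per kept cell |
| size factor | 10 000 | RNA log-normalisation scale |
| r bands | 0.4 / 0.2 | correlated / uncorrelated thresholds for enrichment |
| `init_groups` | 10 | initial dendrogram cut for cell-state refinement |

## Known limitations

- The prior is noisy, incomplete and unsigned; inferred activities are
  relative to it.
- The compressed fit treats `YᵀD` as a fixed design although noise
  enters it; at very low SNR this biases W toward the identifiable
  subspace.
- The permutation null shares permutations across cells, so p-values
  are correlated across (TF, cell) pairs; frequencies over cells are
  descriptive, not independent evidence.
- Cluster-vs-rest differential testing cannot distinguish "this cluster
  is coherent" from "the rest is heterogeneous"; the refinement
  criterion inherits that ambiguity.
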