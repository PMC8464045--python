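# spartan-cite

Affinity regression for CITE-seq: learn how cell-surface receptor
expression couples to transcription-factor activity, one cell type at a
time.

CITE-seq measures, in each cell, both the transcriptome (scRNA-seq) and
a panel of surface proteins (antibody-derived tags, ADT). This package
treats surface-protein abundance as a proxy for receptor signaling and
asks which transcription factors that signaling converges on. Given a
genes × cells expression matrix **Y**, a cells × proteins ADT matrix
**P**, and a binary genes × TFs regulon prior **D** (e.g. DoRothEA-style
TF→target edges), it fits the bilinear model

    D W Pᵀ ≈ Y

for the TFs × proteins interaction matrix **W**, by solving the
Kronecker-vectorized, Yᵀ-compressed elastic-net regression

    argmin_W  ½‖vec(YᵀY) − (P ⊗ YᵀD) vec(W)‖² + (λ₂/2)‖W‖_F² + λ₁‖W‖₁ .

The trained model maps each cell onto **inferred TF activities**
(W Pᵀ) and **projected surface-protein activities** (Yᵀ D W), with
permutation-based empirical significance, cross-validated evaluation
against a nearest-neighbor baseline, TF–receptor correlation and pathway
co-occurrence enrichment, and protein-based cell-state clustering with
differential testing. A synthetic-data module generates cohorts with
planted interaction structure so the whole pipeline is testable without
downloads.

Intended users: computational biologists analyzing CITE-seq (or any
paired protein/RNA single-cell assay) who want receptor–TF coupling
hypotheses per cell type, and methods developers who need a transparent,
oracle-tested reference implementation of affinity regression.

## Worked example

```python
import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

import spartan as sp

# a synthetic CITE-seq cohort with planted coupling W*
cfg = sp.SimConfig(n_genes=200, n_cells=100, n_tfs=20, n_proteins=10,
                   snr=10.0, seed=1)
inst = sp.generate_instance(cfg)
Y, P, D = sp.latent_training_data(inst)   # aligned, unit-normalized

model = sp.AffinityRegression(prior=D, lambda2=1e-3, var_retained=1.0)
model.fit(P, Y.T)                          # X: cells x proteins, y: cells x genes
corr = np.corrcoef(model.W_.to_numpy().ravel(),
                   inst.W_star.to_numpy().ravel())[0, 1]
print(f"corr(vec W_hat, vec W*) = {corr:.3f}")

# held-out prediction vs the nearest-neighbor baseline (5-fold CV)
rho_model, rho_nn = [], []
for tr, te in KFold(5, shuffle=True, random_state=1).split(np.arange(100)):
    fold = sp.AffinityRegression(prior=D, lambda2=1e-3, var_retained=1.0)
    fold.fit(P.iloc[tr], Y.iloc[:, tr].T)
    rho_model.append(sp.spearman_per_cell(fold.predict(P.iloc[te]).T, Y.iloc[:, te]))
    nn = sp.nearest_neighbor_baseline(P.iloc[tr], Y.iloc[:, tr], P.iloc[te])
    rho_nn.append(sp.spearman_per_cell(nn, Y.iloc[:, te]))
rho_model, rho_nn = pd.concat(rho_model), pd.concat(rho_nn)
stat, p = sp.compare_methods(rho_model, rho_nn)
print(f"mean per-cell Spearman: affinity {rho_model.mean():.3f}, "
      f"nearest neighbor {rho_nn.mean():.3f} (one-sided Wilcoxon p = {p:.1e})")

# per-cell TF activities through the trained model
A = model.tf_activity(P, zscore=True)
print(f"TF activity matrix: {A.shape[0]} TFs x {A.shape[1]} cells, "
      f"row means ~ {A.mean(axis=1).abs().max():.1e}")
```

Output:

```
corr(vec W_hat, vec W*) = 0.984
mean per-cell Spearman: affinity 0.913, nearest neighbor 0.734 (one-sided Wilcoxon p = 2.0e-18)
TF activity matrix: 20 TFs x 100 cells, row means ~ 2.7e-16
```

The first line says the fitted interaction matrix recovers the planted
receptor–TF coupling almost exactly at signal-to-noise 10; the second
that, on held-out cells, expression predicted through the model ranks
genes far better than simply copying the most protein-similar training
cell; the third shows the per-cell TF-activity read-out (z-scored per
TF for display).

Raw-count inputs go through the same pipeline the CLI uses: MTX/CSV
readers, cell QC (300–5000 expressed genes), log-normalisation of RNA
(size factor 10 000), centred log-ratio ADT normalisation, prior
construction from a TF→gene edge list, and joint alignment with
unit-norm columns — see `spartan.io_prep`.

## Command line

```sh
spartan simulate --n-genes 200 --n-cells 100 --seed 1 --out-dir fixtures/
spartan train  --rna fixtures/rna --adt fixtures/adt \
               --prior fixtures/prior_edges.tsv --lambda2 1e-3 \
               --min-genes 1 --out model.tsv
spartan infer  --model model.tsv --adt fixtures/adt --out tf_activity.csv
spartan infer-protein --model model.tsv --rna fixtures/rna \
               --prior fixtures/prior_edges.tsv --out protein_activity.csv
spartan significance --rna fixtures/rna --adt fixtures/adt \
               --prior fixtures/prior_edges.tsv --n-perm 200 --seed 0 \
               --out sig_report.csv
spartan eval   --rna fixtures/rna --adt fixtures/adt \
               --prior fixtures/prior_edges.tsv --folds 5 --seed 0 \
               --out eval.csv
```

Models are TSV (TFs × proteins) with a JSON sidecar carrying
hyperparameters, SVD rank and norms.

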