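# dvmppi

Sequence-based prediction of protein–protein interactions (PPIs) from
evolutionary profiles.  Experimental interaction screens are expensive and
noisy; this package implements an in-silico predictor that needs nothing but
the two protein sequences' PSI-BLAST profiles: a two-dimensional PCA (2DPCA)
descriptor over PSSM-derived matrices, classified by a **discriminative
vector machine (DVM)** — a robust k-nearest-neighbor representation
classifier.  It is aimed at computational biologists who want to score
candidate pairs, and at methods researchers who want a clean, tested
reference implementation of the DVM.

## Method

**Features.** A protein of length *L* is profiled by PSI-BLAST into an
*L* × 20 position-specific scoring matrix (PSSM) *P* of integer log-odds.
The length-free per-protein descriptor is the 20 × 20 evolution matrix
*A* = *P*ᵀ*P* (symmetric PSD).  From training matrices *A*₁…*A*_M with mean
*Ā*, 2DPCA builds the image scatter matrix

    G_t = (1/M) Σ_j (A_j − Ā)ᵀ (A_j − Ā)

and takes the top *d* orthonormal eigenvectors *X*₁…*X*_d of *G_t* (the
maximisers of the scatter criterion *J(X) = XᵀG_tX*).  Each protein maps to
the concatenation of *Y_k = A X_k*, a 20·*d* = 60-dim vector for the default
*d* = 3; a pair (a, b) is the 120-dim concatenation of the two protein
features.

**Classifier.** The DVM is a lazy learner.  For a query *y* it finds the *k*
nearest training samples *X_k* = [*x*₁…*x*_k] and solves

    min_β (y − X_k β)ᵀ P (y − X_k β) + δ‖β‖² + γ βᵀLβ

where *P* = diag(*p_i*) holds Welsch M-estimator weights
*p_i* = exp(−*r_i*²/σ²) of the residual *r* = *y* − *X_k β* with kernel width
σ² = θ·(*r*ᵀ*r*)/*d*, and *L* = *D* − *W* is the graph Laplacian of the
cosine-similarity graph among the neighbors.  The weight matrix and the
closed-form update β = (*X_k*ᵀ*PX_k* + δI + γL)⁻¹*X_k*ᵀ*Py* alternate
(half-quadratic optimisation).  The query is assigned the class *i* with the
smallest reconstruction residual *R_i* = ‖*y* − *X_ki* β_*ki*‖ over its own
neighbors; the margin *R*₀ − *R*₁ is the ROC score.  Defaults: δ = 1e-3,
γ = 1e-4, θ = 1.0.

Evaluation follows repeated (5×) stratified 5-fold cross-validation with
accuracy, sensitivity, precision, Matthews correlation coefficient and
ROC/AUC.

## Worked example

No external data is needed — the `simulate` command writes synthetic
PSI-BLAST-dialect PSSMs with a controllable class signal:

```sh
dvmppi simulate --out demo --n-proteins 20 --n-pos 60 --n-neg 60 --seed 7
dvmppi features --pssm-dir demo/pssm --pairs demo/pairs.tsv --out demo/features.tsv
dvmppi cv --features demo/features.tsv --folds 5 --repeats 5 --seed 7 --k 12 --out demo/report.json
```

prints

```
wrote 20 PSSMs and 120 pairs to demo
wrote 120 x 120 feature table to demo/features.tsv
Acc 98.67 +/- 2.32 %  Sen 99.00 %  Pre 98.44 %  MCC 0.9741  AUC 0.9969
report written to demo/report.json
```

`features.tsv` holds one row per pair (`id_a`, `id_b`, `label`,
`f1..f120`).  The `cv` line is the mean ± sd over all 25 fold evaluations:
on this clearly separated synthetic dataset the pipeline recovers the
interaction labels almost perfectly (Acc/Sen/Pre in percent, MCC in
[−1, 1], AUC in [0, 1]).  `report.json` carries per-fold and per-repeat
values; `report.folds.tsv` and `report.roc.tsv` the raw tables.  With
`--separation 0` at the simulate step the same pipeline scores at chance
(Acc ≈ 50 %), confirming that the signal measured is the injected one.

`dvmppi train` / `dvmppi predict` store a model directory and score query
pairs (`label_pred`, per-class residuals, margin).

Python equivalent:

```python
from dvmppi import SynthConfig, synth_pair_dataset, evolution_matrices, \
    pair_stack, make_pipeline, repeated_kfold

proteins, pairs = synth_pair_dataset(SynthConfig(seed=7))
X, y = pair_stack(evolution_matrices(proteins), pairs)   # (400, 2, 20, 20)
report = repeated_kfold(make_pipeline(), X, y, folds=5, repeats=5, seed=7)
print(report["summary"]["acc"])
```

Real PSSMs are produced with
`psiblast -db nr -evalue 0.001 -num_iterations 3 -out_ascii_pssm <id>.pssm`;
`dvmppi features` consumes that ASCII dialect directly (see
`docs/methods.md` for dataset-construction notes).

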