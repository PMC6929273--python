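# Methods

## Problem and model

The package predicts whether two proteins physically interact from sequence
alone.  Each protein is represented by its PSI-BLAST evolutionary profile
(an L×20 integer log-odds PSSM); the classifier sees a fixed-length pair
feature built in three steps:

1. **Evolution matrix.**  A = PᵀP, 20×20.  This is the only orientation that
   removes the length dependence (PPᵀ would be L×L).  A is symmetric PSD by
   construction.  Raw log-odds integers are used; no sigmoid or z-score
   transform is applied first.  A logistic squash (`normalize="sigmoid"`,
   CLI `--pssm-normalize`) is available for users following that convention,
   but it is off by default because the transpose-product on raw scores is
   the simplest faithful reading of the construction.  Rows with ambiguous
   residues (X, gaps) keep their printed scores; no row filtering.
2. **2DPCA.**  The image scatter matrix G_t of the training evolution
   matrices is eigendecomposed; the top d eigenvectors are the projection
   axes.  Each protein maps to [AX₁; …; AX_d] (axis-major flattening, frozen
   for reproducibility), the sample matrix itself — not the centered one —
   being projected.  d defaults to 3, giving the standard 60-dim protein and
   120-dim pair features on 20-row matrices.  Sign convention: each axis's
   largest-magnitude component is made positive, so the fitted basis does
   not depend on eigensolver sign choices.  Fitting requires non-identical
   samples (zero scatter has no informative axes and raises).
3. **Pair concatenation.**  [f_a ‖ f_b] in the listed pair order.  Pairs are
   not symmetrised by default; swap-augmentation is a trivial preprocessing
   step left to the caller, and keeping the listed order makes runs
   reproducible against the input file.

## The DVM classifier

A lazy robust-representation classifier (see README for the objective).
Numerical and design choices that the method itself leaves open:

- **Neighbor count k.**  Not part of the model definition; default
  `k = min(n, max(20, ceil(0.1·n)))`.  The classifier is insensitive to k
  within a wide band because the Welsch weights already down-weight
  dimensions that the neighborhood reconstructs poorly.
- **kNN metric.**  Euclidean on standardized features by default; cosine
  available.  (Cosine similarity is always what builds the neighbor graph
  W — that choice emphasises direction over magnitude.)
- **Similarity graph.**  w_pq = max(cos(x_p, x_q), 0), diagonal 0.  The
  floor at zero keeps all edge weights non-negative, which is what makes
  L = D − W a genuine graph Laplacian (diagonally dominant, hence PSD) and
  the manifold penalty βᵀLβ a semi-norm; a signed "Laplacian" can have
  negative eigenvalues and would turn the penalty into a reward for
  anti-parallel neighbors.  Zero-norm columns are isolated vertices.
- **Half-quadratic solve.**  β is initialised at the P = I
  (ridge + Laplacian) solution, then weight refresh and closed-form update
  alternate; max_iter = 20, tol = 1e-6 on ‖Δβ‖.  Each update minimises the
  fixed-P surrogate exactly, so the surrogate objective is non-increasing
  per iteration (asserted in tests via the recorded trace).  An exactly zero
  residual sets all weights to 1 and stops (σ would be 0).  δ > 0 keeps the
  k×k system well-posed even for rank-deficient neighborhoods; a singular
  solve surfaces with a condition-number diagnostic rather than silently.
- **Standardization.**  Train-set z-scoring is on by default: the kernel
  width σ² mixes feature dimensions, so wildly different scales would let a
  few dimensions dominate the Welsch weights.  Zero-variance dimensions get
  scale 1 (they standardise to 0 and carry no information).
- **Per-class residual.**  R_i slices the class-i sub-vector of the joint
  coefficients (`class_residual="slice"`); re-solving restricted to class-i
  neighbors (`"refit"`) is available.  A class absent from the neighborhood
  gets R_i = ‖y‖, the empty-reconstruction residual — it can still win only
  against an even worse reconstruction.
- **ROC score.**  The method defines only a label decision; the margin
  R_noninteract − R_interact is the natural continuous score and is what the
  ROC/AUC machinery consumes.
- **Determinism.**  Distance ties in the kNN search break by ascending
  training index with a stable sort, so permuting the training set changes
  no prediction (up to exact feature ties).

Hyperparameter defaults δ = 1e-3, γ = 1e-4, θ = 1.0 follow the method's
published operating point.

## Cross-validation harness

Stratified k-fold (default 5), repeated (default 5) with per-repeat derived
seeds; stratification is stricter than plain shuffling but prevents
degenerate folds on small or imbalanced sets.  Metrics are computed per fold
from the printed formulas; a zero denominator yields NaN with a warning
(never a silent 0).  The summary reports mean ± sd over all folds × repeats
(25 values for 5×5) and also per-repeat means, covering both conventions for
the ± column.  When the estimator is the `TwoDPCA → DVMClassifier` pipeline,
the projection basis is refit inside each training fold, so no information
from held-out pairs leaks into the features (`--basis-scope all` disables
this for precomputed feature tables).  AUC is a trapezoidal sweep over the
unique scores, equal to the Mann–Whitney ordering probability with ties
counted ½ (cross-checked against both an all-pairs oracle and sklearn).

## Synthetic data: what it does and does not show

The generator emulates the *shape* of the real inputs: integer L×20
log-odds matrices (clipped to −10..12, the typical PSI-BLAST span), lengths
drawn from 50–120 (the post-filter fragment threshold upward), and a
class signal injected at the PSSM column-mean level.  Two 20-vector
templates, `separation` apart per column, define two protein groups;
interacting pairs are drawn within a group, non-interacting pairs across
groups.  Column-mean structure survives PᵀP and the 2DPCA projection, which
is exactly why it is the right place to put a controllable signal.

Default study conditions: 40 proteins, 200+200 pairs, noise sd 2.0,
separation 12 (six noise sd) for separable runs.  At separation 0 the
templates coincide *and the labels are shuffled*: without the shuffle,
group membership would still leak through each protein's idiosyncratic
profile (pairs recur across folds), and the null would sit above chance —
the shuffle makes "no signal" mean what it says.

What passing tests show: the pipeline recovers a class signal of the stated
geometry essentially perfectly (CV accuracy ≥ 95 % at high separation) and
invents none when there is none (≈ 50 % on the null).  What they do not
show: performance on real profiles, whose position-dependent structure,
residue-composition biases, inter-column correlations and network redundancy
(paralog families, hub proteins) the generator deliberately does not model.

## Scope of the data plumbing

Building a real benchmark additionally requires retrieving interaction
databases, removing fragments (< 50 residues — implemented as
`filter_short_sequences`), de-redundancy clustering (e.g. CD-HIT at 0.4
similarity), negative sampling from distinct subcellular compartments, and
running PSI-BLAST against NR (e-value 0.001, 3 iterations).  Only the
fragment filter and the PSSM parser/writer are code; the external-tool steps
are documented here and in the README.  The parser detects body rows by
field shape (index, residue letter, ≥ 20 integers), not line position, to
tolerate PSI-BLAST dialect differences, and keeps only the log-odds block.

## Problem sizes

Tests and the acceptance script run the full pipeline at 400 pairs with
5×5-fold CV (one high-separation dataset; ten seeds for the null band),
100-instance batches for the solver/descent/AUC oracles, and 100 random
profiles for the evolution-matrix property — sizes at which every check is
exercised end-to-end while the whole suite stays interactive.

## Known limitations

- kNN search is exhaustive; no indexing or sparse acceleration, so very
  large training pools are slow (the method is per-query O(n·d + iter·k³)).
- Only the binary (interact / not) case is exercised, though the residual
  machinery is written for c classes.
- The Welsch surrogate guarantees per-iteration descent, not convergence to
  a global optimum; with max_iter = 20 the coefficients are effectively
  converged on all tested instances but no certificate is produced.
- Pair order is not symmetrised; models are trained on pairs as listed.
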