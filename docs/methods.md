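# Methods

This document records the model definitions, conventions, and numerical
choices implemented by the package, in enough detail to reimplement it.

## 1. Feature tables

Three lookup tables drive the sequence-to-feature mapping:

* **Chemical table** (64 rows, one per 3-mer): 8 PCA score components per
  3-mer, reduced from a raw 64 × 62 matrix of probe interaction descriptors
  (a minimum interaction energy P and an integrated interaction score Q for
  each of 31 chemical probes, evaluated around the central base of the
  3-mer).
* **Base-geometry table** (64 rows): shear, buckle, stretch, propeller,
  stagger, opening of the central base pair of each 3-mer. Angles in
  degrees, translations in Å.
* **Step-geometry table** (256 rows, one per 4-mer): shift, tilt, slide,
  roll, rise, twist of the central base-pair step of each 4-mer.

### PCA reduction

`reduce_chemical_features` standardizes each of the 62 raw columns to mean
0, sd 1 (sample sd, ddof = 1; constant columns are dropped with a warning),
eigendecomposes the resulting correlation matrix, and projects each
standardized row onto the top-k eigenvectors (k = 8 by default), ordered by
descending eigenvalue. Eigenvector signs are fixed so the largest-magnitude
loading is positive, making the table reproducible across linear-algebra
backends. `variance_explained` is the retained eigenvalue fraction. The
reduction requires at least k strictly positive eigenvalues and fails
loudly otherwise.

### Synthetic tables

The real measured tables (molecular-dynamics geometry averages, probe
interaction fields) are not redistributable, so `synthesize_feature_tables
(seed)` generates stand-ins with the same shapes and plausible units: the
raw chemical matrix is a low-rank (8) latent factor product plus Gaussian
noise, then PCA-reduced exactly as a real matrix would be; geometry values
are drawn uniformly (angles in [−30°, 40°], translations in [−2 Å, 2 Å]).
Everything is a pure function of the seed. Tables round-trip bit-exactly
through TSV (`%.17g` formatting, round-trip float parsing).

## 2. Sequence-to-feature mapping

A candidate site is a length-L core plus one base of genuine flanking
context per side. The extended L+2 sequence defines L overlapping 3-mers
(one centred on each core position) and L−1 overlapping 4-mers (one per
core step). Per core position j the vector contains:

* 8 chemical components of the forward-strand 3-mer,
* 8 chemical components of its reverse complement (the other strand reads
  a different 3-mer at the same physical position),
* 6 base-geometry components;

and per step s, 6 step-geometry components. Total dimension **28L − 6**
(L = 10 → 274 = 160 + 60 + 54). Blocks are laid out position-major:
all chemical features (fwd, then rev, per position), then base geometry,
then step geometry. Reverse-strand candidate sites are handled by mapping
the reverse-complemented core with swapped, complemented contexts.

When no genomic context is available (e.g. sites supplied as bare FASTA
sequences), the mapper can pad with G/C (the most "average" stacking
context) — an explicit, opt-out choice (`pad=False` raises instead).

## 3. Class-weighted soft-margin linear SVM

Training solves

  min ½‖w‖² + C₊ Σ_{k∈pos} ξ_k + C₋ Σ_{k∈neg} ξ_k
  s.t. y_k (w·x_k + d) ≥ 1 − ξ_k, ξ_k ≥ 0,

on standardized features (per-column mean/sd with an sd floor of 1;
standardization parameters are stored in the model, and
`effective_weights()` returns the equivalent raw-space (w, d)). The QP is
solved by libsvm (scikit-learn `SVC`, linear kernel) followed by an exact
active-set polish: starting from libsvm's multipliers, hypothesized
free/bound sets are solved through the KKT linear system and updated until
the full KKT conditions hold, which brings the objective to within ~1e−12
relative of a brute-force primal solve (verified against an independent
interior-point + SLSQP oracle in the tests). Classification is strict:
decision value > 0 is a site; 0 is not.

### Model selection

C₊ and C₋ are chosen by maximizing the cross-validated F-measure
(harmonic mean of precision and recall, F = 0 when TP = 0) over a coarse
11 × 11 grid of powers of two (exponents −5, −3, …, 15), then refining
around the winner with 3 × 3 neighbourhoods at log₂ spacings 1, ½, ¼, ⅛.
One seeded fold partition is reused for every penalty pair so the surface
is comparable across the grid. Ties on the coarse grid go to the smaller
(C₋, C₊); refinement stages recentre only on strict improvement, so a flat
plateau keeps the coarse winner instead of drifting.

### Cross-validation score V

Stratified 3-fold cross-validation repeated 10 times (default): V is the
pooled fraction of held-out positives classified as sites.

## 4. PWM baselines

All four baselines are additive scorers over a 4 × L matrix; natural
logarithms throughout. With n_{b,j} the training count of base b at
position j over N sites, f = n/N, and p_b the background frequency:

* **BvH**: score(S) = Σ_j ln((n_{S_j,j} + ½)/(n_{b*,j} + ½)), b* the modal
  base (ties broken A < C < G < T). Cutoff = mean training score; strict >.
* **Match**: information vector I_j = Σ_b f ln(4f) (0·ln0 = 0); raw score
  Σ_j I_j f_{S_j,j}, min–max normalized so the best-matching sequence
  scores 1 and the worst 0. A perfectly uniform matrix is rejected as
  uninformative. Cutoff = mean training score; strict >.
* **MATRIX SEARCH**: score(S) = Σ_j ln((f_{S_j,j} + 0.01)/p_{S_j}).
  Cutoff = mean training score; strict >.
* **QPMEME**: an energy matrix ε minimizes the variance of the energy of a
  random background sequence subject to every training site scoring
  ≤ −1; a sequence is a predicted site when its energy is ≤ −1.

### QPMEME gauge

The variance objective is invariant under adding a constant to any column
of ε, so the literal program is degenerate (a column shift can drive the
variance to zero while satisfying all constraints, classifying everything
as a site). The implementation fixes the natural gauge of the original
method: the background mean energy is zero per column (Σ_b p_b ε_{b,j}
= 0). In that gauge the objective is the strictly convex weighted second
moment Σ_{j,b} p_b ε². The program is solved exactly: each column is
expressed in a p-orthonormal basis of the gauge subspace (QR construction),
the dual — a box-constrained QP with one multiplier per site — is solved by
L-BFGS-B and finished with an active-set linear solve, and the solution is
verified against the site constraints before being returned. Tests confirm
agreement with a dense SLSQP oracle and the closed form for a single site
(variance 1/(3L), the site exactly at −1).

## 5. Genome scanning

Scanning scores every length-L window of every non-coding region on both
strands. Non-coding regions are the complement of the merged annotated
coding intervals. For the SVM, the linear decision function folds into one
64-entry lookup per core position (chemical forward + chemical reverse +
base geometry, pre-multiplied by the effective weights) plus one 256-entry
lookup per step and a constant — a handful of integer gathers per window,
verified in the tests to match the explicit mapping path to 1e−8. Window
context comes from the adjacent genome (coding or not); only windows at the
termini of linear sequences lack context and are skipped and counted
(circular sequences wrap). Reverse-strand hits are reported at
forward-strand coordinates with strand `-` and the reverse-complemented
site sequence. PWM models need no context and scan with per-position matrix
gathers; QPMEME hits are windows scoring ≤ its cutoff, all others strictly
above theirs.

## 6. Evaluation

* **ROC/AUC**: AUC is the Mann–Whitney statistic computed from ranks
  (ties count ½); the curve is a descending-score sweep with tied scores
  grouped. `auc_experiment` repeats 10 times: retrain on a 2/3 sample of
  the known sites (with freshly sampled background negatives), score the
  held-out 1/3 against all eligible background windows (capped by seeded
  subsampling). It requires ≥ 20 known sites and excludes the known sites'
  own windows from the background pool.
* **Region matching**: a prediction is validated when its sequence or
  reverse complement is a substring of any experimentally determined
  binding region; each prediction counts once. False positives = total −
  matched.
* **Relative performance**: RP = (other method's prediction count) /
  (SiteSleuth's prediction count).

## 7. Synthetic benchmark generator

`simulate` builds seeded scenarios: an i.i.d. genome with a chosen GC
fraction; ~half-coding annotation as 20 evenly spread intervals; n noisy
copies of a consensus motif (independent per-position substitution
probability θ) planted at non-overlapping non-coding positions on random
strands; training sets of the planted sites (with genuine genomic context)
plus uniformly sampled non-coding negative windows that exclude the planted
intervals. The acceptance benchmark uses a 200 kb genome, 30 sites of a
12-base consensus at θ = 0.02, and 10,000 negatives; at that scale the SVM
reaches V ≥ 0.9 and scan recall ≥ 0.9 in well under a minute. The
θ-monotonicity check runs at a reduced scale (2,000 negatives, 3
repetitions) with a 0.05 slack for fold-assignment noise — a package-level
choice to keep the suite fast, not a property of the method.

## 8. Numerical and engineering choices

* libsvm tolerance 1e−6 with a 2·10⁷ iteration cap; tighter tolerances
  stall without improving the objective, hence the exact KKT polish on top.
* Standardization sd floor 1 prevents near-constant features from blowing
  up; PCA uses ddof = 1 throughout.
* All randomness flows through `numpy.random.default_rng` seeds; every
  generator and experiment is reproducible from its seed.
* CLI writes a JSON run manifest (tool version, parameters, SHA-256 input
  digests, timestamp) beside its outputs.

## 9. Limitations

* The shipped feature tables are synthetic stand-ins; absolute predictive
  performance on real genomes depends on real measured tables.
* Only single-TF, fixed-L models; no gapped or variable-length motifs.
* The scanner loads sequences in memory; it targets bacterial-scale
  genomes (megabases), not mammalian assemblies.
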