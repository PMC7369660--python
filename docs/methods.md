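# Methods

This note records the model, the numerical choices, and the limits of what
the tests demonstrate. It is the package's own account; empirical numbers
quoted here are only those the test suite and `scripts/acceptance.py`
compute themselves.

## Neutrosophic image domain

Every pixel receives truth/indeterminacy/falsity degrees computed from the
a×a local mean ḡ and the homogeneity residual δ = |g − ḡ| (see README for
the formulas). Choices that were genuinely open:

* **Window a = 5** (`--ns-window`). The window trades noise suppression in
  T against preservation of fine texture; 5 is small enough that run-length
  statistics of the membership maps still reflect local structure. Exposed
  because the right value is resolution-dependent.
* **Border policy: symmetric reflection.** Zero padding would inject a
  spurious dark frame into ḡ and hence a bright frame into F; reflection
  keeps border statistics unbiased. The same policy is used by the
  synthetic generator's smoothing and the SLT padding, for consistency.
* **Per-image min/max normalization.** T and I are normalized per image,
  not per dataset: each map then attains 0 and 1 exactly, T is invariant to
  affine intensity rescaling and I to intensity shifts (both property
  tested). The alternative — dataset-global normalization — would couple
  images through a preprocessing statistic and break these invariances.
* **Degenerate inputs.** A constant image leaves both normalizations
  undefined; we raise a typed error rather than emit NaN maps, and the
  batch extractor logs and skips such images instead of failing the run.
* **Window preconditions.** Only oddness/positivity are enforced; windows
  larger than an image dimension are legal because reflection padding
  defines the neighborhood (the 1×3 worked example in the tests relies on
  this).

## Slantlet filter bank

For `l` scales the bank has `2l` channels. The intermediate-scale filters
g_i (support 2^(i+1), downsampling 2^(i+1), i = 1..l−1) are linear on each
half of their support and satisfy: unit norm, two vanishing moments, and
orthogonality to their own time-reverse. The coarse pair (h_l, f_l) spans
the affine signals on each 2^l block: h_l is the normalized constant and
f_l the normalized centered ramp.

Rather than solving the constraint system with a generic least-squares
routine, we solve it in closed form: inside the 2-dimensional space W of
half-linear vectors orthogonal to constants and ramps, time reversal has
one symmetric eigenvector u and one antisymmetric eigenvector v (both with
elementary closed forms), and the unit vectors orthogonal to their own
reverse are exactly (u ± v)/√2. The sign is fixed so each filter's first
nonzero tap is positive; with that convention the construction is unique
and fully deterministic. Orthonormality of the induced transform matrix is
verified to 1e-10 for l ≤ 4 and lengths ≤ 64 by the test suite (observed
error is at machine precision), as are the vanishing moments, annihilation
of affine signals by the g_i channels, Parseval energy preservation of the
separable 2D transform, and exact reconstruction.

Note on supports: for l = 1 the pair degenerates to the Haar pair of
support 2 = 2^l; the "support 2^(i+1)" rule applies to the slantlets g_i,
not to the lowpass pair — with these supports (and only these) the shifted
basis functions tile the signal without overlap and the coefficient count
equals the sample count.

Defaults: `l = 2` (`--slt-scales`; 512 and 128 are divisible by 4, and
larger l shrinks the subbands that feed texture statistics);
small-coefficient suppression `eps = 0` (off, `--slt-eps`) — the relative
threshold zeroes |c| < eps·max|c| when enabled. Images whose sides are not
multiples of 2^l are reflection-padded to the next multiple before the
transform.

## Texture statistics

All three families run on a quantized image: uniform binning of
[min, max] into N_g levels labeled 1..N_g. **N_g = 8 by default**
(`--levels`): coefficient images are smooth after rescaling, and 8 levels
keeps co-occurrence matrices well populated at 128–512 px while preserving
contrast structure.

Conventions, chosen once and used everywhere:

* Entropies use the natural logarithm, with 0·ln 0 := 0.
* The GLCM is **directional, not symmetrized**: the symmetry feature
  Σ|P(i,j) − P(j,i)| and the odd difference moments vanish identically on a
  symmetrized matrix, which would delete four of the ten features.
* GLCM features are averaged over the four distance-1 offsets (0°, 45°,
  90°, 135°), GLRLM features over the same four directions; GLDS uses
  displacement (1, 1) by default. Averaging gives rotation robustness and
  is standard texture-analysis practice.
* Gray levels are 1-indexed so the low-gray-level emphasis (1/i²) is
  defined; GLN and RLN square the per-level and per-length run-count
  marginals respectively (the classical forms — squaring individual matrix
  entries would make the two features identical).
* A correlation with zero marginal variance (legitimate for a constant
  subband) is reported as 0 and flagged, never NaN.

Every feature is validated against an independent pure-Python nested-loop
oracle (tests/oracles.py) to 1e-10 on random 8×8 quantized images, and the
raw co-occurrence counts additionally against scikit-image's
`graycomatrix`.

In multi-map scenarios (ns, ns-slt) a feature is computed per membership
channel and aggregated by the T + I + F sum, making the composite features
additive over channels (property tested). The full SLT coefficient array is
treated as a single image — affinely rescaled to [0, 1] after optional
suppression, then quantized — rather than extracting per subband; the
rescale is required because the quantizer needs a bounded range.

## Feature selection

Columns are z-scored with the population (1/n) standard deviation — the
convention of sklearn's `StandardScaler`; the ANOVA F ratio is invariant to
the 1/n vs 1/(n−1) choice. Ranking uses the classical one-way F statistic
with p from the F-distribution upper tail, validated against both
`scipy.stats.f_oneway` and a 2000-draw label-permutation null. The selected
count k is user configuration (k = 3 for the run-length family in the
shipped study); ties in p break by original column order so selection is
deterministic and row-permutation invariant. By default selection is fitted
inside each training fold; `--global-fit` fits it once on the full table,
which mildly leaks test information and is provided only for comparability
with full-dataset protocols.

## Evaluation

Stratified 10-fold cross-validation, metrics reported as mean ± SD across
folds; an optional stratified 20% held-out split is available. The four
classifiers are standard implementations (RBF SVM with C = 1, γ = scale;
unpruned CART tree; 5-NN; Gaussian naive Bayes) — the source study names
neural-network variants of these without specifying them, so the standard
forms are used and hyperparameters are exposed in code. Malignant is the
positive class. ROC curves come from a threshold sweep with ties collapsed;
the trapezoid AUC equals the Mann–Whitney pair statistic with ties counted
one-half (asserted to 1e-12 in the tests). Metrics with empty denominators
are flagged and reported as 0 rather than NaN.

## Synthetic phantoms

The generator emulates exactly the properties the pipeline measures:

* **benign-like**: Gaussian noise smoothed with kernel σ = 0.8 + 3.2·s,
* **malignant-like**: σ = 0.8 plus 3 random elliptical blobs of contrast
  ±0.6·s,

with separation dial s ∈ [0, 1] (default 0.8), pixel noise SD 0.05, an
8-pixel zero margin (so the bounding-box crop is exercised), intensities in
[0, 1], and per-image seeded substreams. At s = 0 the two classes share one
generative process, giving an exchangeable null. Kernel width maps
monotonically onto run lengths (smoother → longer runs → higher LRE, lower
SRE), which the tests verify.

What the phantoms do **not** model: anatomy, MR acquisition physics, bias
fields, partial-volume effects, class-dependent intensity distributions, or
inter-scanner variation. Passing the end-to-end tests therefore shows the
pipeline recovers *textural* class structure it was designed to measure; it
does not certify diagnostic performance on clinical data.

## Problem sizes

The shipped study uses 20 phantoms per class at 128×128 with s = 0.8 and
k = 3 selected run-length features — sizes chosen so the whole study runs
in seconds while keeping ≥ 2 samples per class per fold at 10 folds. The
512×512 preprocessing contract is exercised at its default size in its own
tests. An imbalanced mode (2.8 : 1 malignant : benign, mirroring the
reference cohort) is available behind a flag; the balanced default gives
stabler fold statistics.

## Known limitations

* The composite domain's advantage over `ns` or `slt` alone is visible on
  phantoms only as a property (all scenarios separate well-separated
  classes); ranking scenarios requires realistic data.
* GLRLM run statistics are resolution-sensitive; comparing features across
  images requires the shared resize stage.
* The eighth run-length feature named (but not defined) in the source
  literature is not implemented; the seven defined formulas are.
* NIfTI reading selects single slices; no 3D texture matrices.
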