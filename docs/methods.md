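# Methods

This note documents the models, defaults and design choices behind
`qdcoloc`, and what the synthetic validation does and does not demonstrate
about real micrographs.

## Synthetic scenes

**Cell network.** Root epidermis is a pavement of elongated cell files.
The generator emulates this with an anisotropic nearest-seed tessellation:
seed points are scattered uniformly at density `1 / (mean_cell_length ×
mean_cell_width)` and pixels are assigned to their nearest seed under a
metric that compresses the root axis by `anisotropy` (default 4), producing
cells elongated along image rows. The wall mask is the region edge set
dilated to `boundary_thickness_px` (default 2 px). This preserves the one
geometric property the colocalization statistic depends on — thin walls
separating large interiors — while making the true wall set known exactly.
It does not reproduce curved root outlines, out-of-focus tissue layers, or
intensity gradients of real brightfield images.

**Channels.** The wall channel renders the mask as bright lines (background
100 counts, amplitude 120, Gaussian blur σ = 1 px, additive noise
σ = 6) — an idealized high-contrast wall image. The QD channel renders each
emitter as a *pixel-integrated* Gaussian PSF (error-function quadrature per
pixel) of width `psf_sigma_px` (default 1.5 px, a nominal value for a 40×
EMCCD system whose true pixel scale is configurable) carrying
`spot_photon_mean` photons (default 2000) on a 100-count background, with
Poisson shot noise plus Gaussian read noise (σ = 5), digitized to 16 bits.
Peak SNR ≈ 9 at defaults. QD blinking, z-projection artifacts and
autofluorescence are not modelled.

**Spot placement.** `round-half-up(n_spots × f_boundary)` spots are placed
on wall pixels and jittered uniformly within a disc of radius
`boundary_jitter_px` (default 1 px), modelling emitters lining the apoplast
rather than sitting on a 1-px skeleton; the remainder are placed strictly
farther than twice the jitter from any wall pixel, so the two truth classes
are unambiguous. Rejection sampling enforces a minimum pairwise separation
(default 5 px) with a bounded retry budget.

**Seeds.** Every generator is a pure function of its spec. Compound
operations split one top-level seed into per-operation streams via
`SeedSequence(seed, spawn_key=(stream,))`, folded to 31-bit integers.

**Tables.** Genotype counts are one multinomial draw. Growth tables are a
full treatment × genotype factorial, `value = baseline + treatment effect +
genotype effect + plate effect + residual`; the plate random-effect SD
defaults to 0 (fixed-effects view; fixtures enable it explicitly) and the
residual SD to 1 mm, with 10 seeds/plate and 4 plates/treatment as the
emulated design.

## Boundary probability maps

The per-pixel features are raw intensity plus, for each scale in
{1, 2.5, 5} px: Gaussian-smoothed intensity, gradient magnitude, Laplacian
and the largest Hessian eigenvalue (4 × n_scales + 1 features). Discrete
second-derivative kernels carry a small DC pedestal (their weights do not
sum exactly to zero); the Laplacian feature subtracts the operator's
constant response so flat images yield exactly-zero features.

The classifier is a seeded random forest (50 trees, depth ≤ 12) behind a
`predict_probability` contract; any calibrated probabilistic classifier
could substitute. When training labels are sampled from a ground-truth
mask, pixels within 2 px of a wall are excluded from the *negative* class —
a "don't-care" band, as when labels are painted with a brush. Without it
the posterior is spatially sharper than the biological jitter of
wall-adjacent emitters and spots 1 px off the wall score ≈ 0; with it the
wall neighbourhood receives intermediate probabilities, which is what the
lenient 0.2 threshold is designed to accept.

The training-free fallback is Sato tubeness (bright ridges) over the same
scales, normalized by clipping at the 1st–99th percentiles and rescaling to
[0, 1] (robust to hot pixels); constant images map to all zeros.

## Spot detection and localization

Candidates are local maxima of the negated, scale-normalized
Laplacian-of-Gaussian response at σ = `psf_sigma_px`, median-subtracted (the
discrete kernel's DC pedestal again), thresholded at `k × 1.4826 × MAD` of
the response (default k = 5; absolute thresholds available), and
non-maximum-suppressed within `min_separation_px` (Chebyshev window; of two
closer peaks the brighter survives). Order is descending score, ties broken
lexicographically by (y, x), so detection is bit-reproducible.

Centroids are refined in a (2r+1)² window (r = 5): the window-perimeter
median is the local background (robust, local, deterministic), negative
residuals are clipped, and the intensity-weighted centroid is taken.
Windows leaving the frame keep the integer position and carry a `border`
flag (included in colocalization by default, switchable); non-positive net
intensity keeps the integer position with a `low_intensity` flag.
Coordinates are 0-based (row, col) = (y, x) with pixel centers at integers,
stated in every file sidecar.

## Colocalization

"Proximity to a boundary" is the probability-map value at the centroid —
a lookup, not a distance transform: nearest-pixel by default, bilinear
optionally. The boundary-colocalized fraction counts spots with probability
**≥** the threshold (default 0.2); inclusive comparison makes the statistic
right-continuous in the threshold, and a strict switch exists. The
histogram uses 20 uniform bins on [0, 1], left-closed right-open with the
last bin closed, so counts always sum to the number of spots. A zero-spot
image is an error (the statistic is undefined), distinct from fraction 0.
Whether fractions are computed per image then compared, or pooled across
spots, is an explicit choice (see below); per-image is the default to avoid
pseudoreplication.

**Group comparison.** A two-sided permutation test on the difference in
group means. The resampling unit is the image — each image is one seedling
on one plate, the independent replicate. When the number of distinct
relabellings is within the permutation budget the null distribution is
enumerated exhaustively (exact p = tail share, observed split included);
otherwise Monte Carlo with the add-one rule (b+1)/(m+1). A consequence of
exchangeability at the image level: with 3 images per group the two-sided p
can never fall below 2/20 = 0.1, regardless of effect size. For that
regime `unit="spot"` pools per-spot threshold indicators within groups and
permutes spot labels — more powerful, at the cost of treating spots as
exchangeable across images; the pipeline reports both. The demo
configuration (3 scenes per group) claims significance from the pooled
test and shows the image-level fractions alongside.

The permutation test's type-I calibration is validated at the
per-image-fraction level (binomial fraction estimates with the pipeline's
50 spots/image, 6 images/group, 1000 replicates) rather than by simulating
thousands of full image sets; this checks the same distributional property
at a defensible cost. Slight conservatism (rejection ≈ 0.03–0.05) comes
from ties in the discrete permutation distribution.

## Segregation chi-square

Pearson's Σ(O−E)²/E against expected counts n·w/Σw, df = k−1, **no
continuity correction** — the canonical worked example (8, 2, 0) vs 1:2:1
gives 16.4 exactly without correction (12.85 with), which pins the
convention. Expected counts below 5 warn (the approximation is rough at
n ≈ 10) but do not error, since such sample sizes are the realistic use.

## Growth statistics

Seedlings are pseudoreplicates: tables are averaged by plate before
testing, and all inference runs on plate means. One-way ANOVA uses the
standard between/within decomposition; pairwise comparisons are t-tests on
the pooled MSE with Holm–Šidák step-down adjustment (sorted raw p's,
adjusted pᵢ = 1−(1−p₍ᵢ₎)^(m−i+1), running-maximum monotonicity); Tukey HSD
is available as the alternative some analyses report. The two-way
genotype × treatment model uses Type II sums of squares (robust to the mild
imbalance plate losses cause); within-treatment genotype comparisons use
the full model's residual error with single-step Šidák adjustment over the
number of treatments; a factor with one observed level drops out of the
model. The linear-trend contrast uses equally spaced integer coefficients
centred at zero (−1,0,1; −3,−1,1,3 …) on ordered dose groups over the
pooled error — rank coding by default, with dose-value and log-dose codings
switchable, since a "linear trend with increasing concentration" is
ambiguous between the three. Normality is assumed (not tested). Nothing in
this module is stochastic; all p-values are bit-reproducible.

## Problem sizes and numerical choices

Validation uses 512×512 scenes with 50 spots for recovery and detection
checks (30 and 4 scenes respectively), 256×256 scenes for the two-group
comparison (20 repetitions × 6 scenes), 10⁴ multinomial replicates for
chi-square calibration and 10³ replicates for ANOVA and permutation
calibration — sizes chosen so the whole suite runs in minutes on one CPU
while keeping Monte Carlo error well inside the asserted bands.
Permutation tail comparisons use a 10⁻¹² slack so float rounding never
flips a count; probability maps are validated to lie in [0, 1] on every
construction path.

## Known limitations

* The synthetic wall channel is far cleaner than real brightfield tissue;
  passing recovery tests bounds algorithmic error, not the error on real
  images, where classifier quality will dominate.
* The probability-map lookup scores proximity only through the map's
  spatial spread; it is not a geometric distance measure.
* Spots are assumed sparse and diffraction-limited; no deconvolution,
  tracking, or z-stack handling (images are treated as 2-D projections).
* The pooled-spot permutation ignores between-image variance; it is the
  pragmatic option for 3-image groups, not a replacement for adequate
  replication.
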