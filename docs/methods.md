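# Methods

This note documents the models behind each module, the defaults that matter,
the numerical choices, and what the synthetic data do and do not show about
real fMRI.

## Smoothing and the signal-mix decomposition

Smoothing is separable discrete Gaussian convolution in voxel space. The 1-D
kernel is the Gaussian sampled on integers, truncated at `ceil(4σ)` and
renormalized to unit sum, which bounds the truncated mass below 1e-4;
boundaries are zero-padded, which biases edge voxels toward zero (documented
rather than corrected — every simulation that needs stationarity generates on
a padded grid and crops instead, see below).

The *signal mix* at a voxel is defined on the continuous kernel: the internal
fraction is the mass of the isotropic 3-D Gaussian (sd σ per axis) inside the
central unit voxel cube, `[erf(1/(2σ√2))]³`. The alternative — the discrete
kernel's center weight — gives ≈0.104 at FWHM 2 voxels instead of 0.0875; the
continuous definition is used because it is resolution-independent and
because it is the natural continuum statement of "how much signal stays
home". At FWHM = 1 voxel this definition yields an external/internal ratio of
1.27 (internal fraction 0.4407); the neighborhood's contribution at that
width is therefore larger than the voxel's own but *not* twice as large, a
figure sometimes quoted — we report the ratio our definition produces and
flag the discrepancy rather than force it.

Smoothed-vs-unsmoothed GLM fits on a blob phantom exhibit the central
trade-off: the peak t statistic rises (noise averaging) while the peak fitted
effect size falls (signal dilution). This dissociation is asserted in the
test suite with a seeded simulation.

## Voxelwise GLM

The HRF is the canonical double gamma: a gamma-density response with shape 6
and unit dispersion minus one sixth of a gamma undershoot with shape 16,
zero for t ≤ 0, peaking near 5 s. The task regressor is the condition boxcar
sampled at TR/16, convolved with the HRF, downsampled to scan times, and
mean-centered. Per voxel the model `y = b0 + beta * x + e` is solved by OLS;
`t = beta / se(beta)` with `dof = n_scans − 2`. Perfect fits (residual sum of
squares at round-off level relative to the total sum of squares) report
`sigma2 = 0` and a ±inf sentinel in the t map, excluded from calibration
tests. No temporal autocorrelation is modeled: the synthetic noise is white
by construction, so prewhitening would be an identity; fits to real,
autocorrelated data would need it.

## Cluster-extent null simulation

Each iteration draws an i.i.d. standard-normal field, smooths it to the
target FWHM, renormalizes, thresholds at the one-sided normal quantile of
the cluster-forming p (default one-sided voxel p = 0.01, z ≈ 2.326), and
records the sizes of all 26-connected components (connectivity is a flag;
26 is the common volumetric choice). Two numerical decisions keep the
simulation calibrated:

* **Stationarity.** Noise is generated on a grid padded by the kernel
  truncation radius and cropped after smoothing, so there is no edge-variance
  deficit anywhere in the analyzed field.
* **Variance renormalization.** The cropped field is divided by the analytic
  interior standard deviation of smoothed white noise, `sqrt((Σ w_i²)³)` for
  the separable kernel, so the voxelwise exceedance rate equals the
  cluster-forming p exactly. (Without this, applied smoothness and effective
  threshold would confound.)

The *uncorrected cluster p* of extent k is the pooled tail probability
P(size ≥ k) over all null clusters from all iterations — not the max-size
distribution — and the minimum significant size is the smallest k with that
tail below α = 0.05. This uncorrected value still requires a
multiple-comparisons step across observed clusters, which `bh_fdr`
(Benjamini–Hochberg step-up, via statsmodels) supplies.

Defaults: 64³ field, 1000 iterations. At FWHM 4 voxels, seed 0, the minimum
significant cluster size is 70 voxels; it is threshold-sensitive (larger for
cluster-forming p = 0.05, smaller for 0.001), which the acceptance tests
record explicitly.

**Scaling with smoothness.** Null cluster volumes scale roughly with
FWHM^D in D dimensions, so in these 3-D simulations doubling the smoothness
from 4 to 8 voxels multiplies the minimum cluster size by ≈6.7 (471/70 at
seed 0; slightly below the unbounded-domain factor of 8 because large
clusters are truncated by the 64³ boundary). The often-quoted "doubling
smoothness quadruples the minimum cluster size" is the exact *2-D* scaling;
a 3-D simulation cannot reproduce a factor near 4, and we report the 3-D
factor rather than adjust the setup to match the 2-D statement.

Effective smoothness is estimated from the variance ratio of first
differences: smoothed white noise has lag-one autocorrelation
`rho(1) = exp(−1/(4σ²))` (the kernel correlates with itself), which is
solved for σ per axis and combined by geometric mean; a ratio at white-noise
level maps to FWHM 0. On 64³ fields the estimator recovers an applied FWHM
of 3 voxels to within a few percent.

## Group-level heterogeneity

The heterogeneity simulation works at a single location: a group of
n = 20 subjects contains r responders with values from N(δ, 1) and n − r
non-responders from N(0, 1); the one-sided one-sample t-test against zero
(df = n − 1) is repeated (default 1000 reps; 10,000 in the acceptance run)
for every composition r = 0..20 — the explicit r = 0 row doubles as the null
calibration — and six effect offsets δ ∈ {0.5, 1.0, 1.5, 2.0, 2.5, 3.0}
(the offsets are a package default, exposed in the API and config). One-sided
testing matches the directional "activation" question; a two-sided flag
exists.

Each cell records the mean and median p, the rejection rates at 0.05 and
0.001, and a significance category (n.s. / mild 0.01–0.05 / moderate
0.001–0.01 / high < 0.001). **The category is assigned from the median p**,
i.e. the typical single simulated study. The mean p is stored but not used
for binning: the p distribution under an effect is heavily right-skewed, so
the mean is dominated by rare large values and understates what a typical
study reports (at r = 10, δ = 3: mean p ≈ 0.002 but median p ≈ 0.0008, with
56% of studies below 0.001 — in close agreement with a noncentral-t
approximation that treats the fixed-composition sample as i.i.d. draws with
the mixture's mean δ/2 and variance 1 + δ²/4).

The conjunction-side operations are deterministic set algebra: `overlap_map`
is the voxelwise AND with per-subject retention |overlap|/|mask|;
`subject_count_map` counts subjects exceeding a threshold per voxel (counts
strictly between 0 and n mark exactly the voxels where the group and the
individuals disagree); `map_similarity` is the Pearson correlation of
unthresholded maps.

## Synthetic data

Phantoms are concentric ellipsoidal tissue shells (white core, gray shell,
CSF rim; fractions of the brain radius are spec parameters) with spherical
activation blobs whose centers must lie in gray matter — spheres rather than
irregular cortical patches so that the ground-truth voxel count is exactly
the discrete ball volume, enumerable by brute force. Time series are
`truth × regressor + noise` with i.i.d. Gaussian noise, optionally given
intrinsic spatial smoothness by the same pad–smooth–crop–renormalize recipe,
so the marginal voxel variance is preserved. Cohorts derive subject i's
generator from `SeedSequence(cohort_seed, spawn_key=(i,))`, making every
subject reproducible independently of cohort size; responder counts round
half toward responders so 20 composition levels map onto 0..20 responders.

What this emulates about real data: compact activations inside gray matter,
hemodynamically delayed block responses, controlled smoothness, and
between-subject spatial variability. What it does not: vasculature and
draining veins, physiological and temporally autocorrelated noise, motion,
distortion, inter-subject anatomical variability beyond rigid blob jitter,
or surface topology. Passing tests therefore validate the *statistical
mechanisms* (leakage, sieving, heterogeneity masking) — they do not certify
effect sizes on any real acquisition.

## Problem sizes

Default simulation scales — 64³ null fields with 1000 iterations, 10,000
repetitions per heterogeneity cell in the acceptance run, 20-seed Monte
Carlo for the smoothness estimator — were chosen so the pooled null contains
10⁵–10⁶ clusters and binomial standard errors on reported rates stay below a
percentage point, while a full test run stays in the minutes range on a
single CPU.
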