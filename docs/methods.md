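# Methods

## The measurement being modeled

A ²²Na positron source sits between two spheroid samples; a fast-timing
spectrometer records, for 10⁶ coincidences per measurement, the delay
between the 1274 keV prompt photon (positron birth) and a 511 keV
annihilation photon (positron death).  The delay histogram is a mixture of
four decay channels plus accidental background:

| channel | mean lifetime | role |
|---|---|---|
| p-Ps | 0.125 ns (fixed) | singlet positronium self-annihilation |
| source | 0.374 ns (fixed) | annihilation in the Kapton-wrapped source — nuisance |
| free | 0.395 ns | direct e⁺e⁻ annihilation without positronium |
| o-Ps | ≈1.8–1.9 ns | triplet positronium, shortened by pick-off/conversion — the biomarker |

Every channel is smeared by the detector timing response.  With a Gaussian
response of standard deviation σ, a channel of mean lifetime τ starting at
time-zero t₀ has the exponentially modified Gaussian density

    f(t) = 1/(2τ) · exp(σ²/2τ² − (t−t₀)/τ) · erfc((σ/τ − (t−t₀)/σ)/√2).

Numerically the textbook form overflows when σ/τ is large (the p-Ps channel
has σ ≈ τ), so for non-negative erfc arguments the implementation uses the
scaled function erfcx, leaving only the Gaussian factor exp(−(t−t₀)²/2σ²)
in the exponent; this is stable for σ/τ well past 10 and agrees with direct
numeric convolution at the 1e-14 relative level.  The CDF is evaluated as
Φ((t−t₀)/σ) − τ·f(t), which inherits that stability in both tails.

## Tunable parameters and defaults

- **Timing resolution**: single Gaussian, FWHM 0.25 ns (typical for a
  BaF₂-based fast spectrometer).  A weighted multi-Gaussian response with
  per-term shifts is supported but off by default.  The resolution of the
  actual instrument is not published, so this is an explicit modeling
  choice; all recovery claims are made against the simulator's own truth,
  which uses the same response.
- **Window and binning**: (−2, 25) ns with 0.025 ns bins (1080 bins).  The
  window covers > 13 o-Ps lifetimes at the water-like 1.8 ns, so truncation
  of the biomarker channel is negligible.
- **Background**: a uniform fraction of events over the window (accidental
  coincidences), default 0.005; free in fits, initialized from the bins
  more than 4σ before the peak.
- **Condition truths**: the four measured conditions (WM266-4/WM115 ×
  day 4/8) define the o-Ps lifetime and intensity of the generator;
  the unpublished short-channel intensities default to a 10% source
  fraction, p-Ps at one third of o-Ps, free annihilation as remainder.

## Estimation

Binned Poisson maximum likelihood: the fit minimizes the Cash deviance
C = 2Σ_b [μ_b − k_b + k_b ln(k_b/μ_b)] (empty bins contribute 2μ_b) with
per-bin expectations computed as exact CDF differences, not midpoint
density × width.  The midpoint rule errs by ~2% on the steep Gaussian
flank at 0.025 ns bins (the usual w²/24 curvature term), which is exactly
where the short components carry their information; CDF differences make
the estimates independent of bin width (halving the width moves the fitted
o-Ps lifetime by well under one σ).  Weighted least squares was rejected
because Gaussian weights bias the low-count tail where the o-Ps channel
lives; Pearson χ²/ndf is still reported as a familiar goodness-of-fit
number and sits in (0.8, 1.2) for well-specified simulations.

Constraint policy (all configurable via `FitConstraints`):

- p-Ps and source lifetimes fixed (0.125, 0.374 ns) — the 0.374/0.395 ns
  pair cannot be resolved freely at these statistics;
- source intensity fixed at its calibration value (an empty-chamber,
  source-only measurement; the simulator has a matching
  `calibration_model`);
- I(p-Ps) = I(o-Ps)/3, the singlet:triplet formation ratio fixed by spin
  statistics.  This tie matters: a Fisher-information analysis shows that
  leaving the p-Ps intensity free roughly doubles the o-Ps lifetime
  uncertainty at 10⁶ events (0.011 vs 0.0099 ns) through the short-time
  intensity degeneracy, without adding physical content;
- t₀ free (initialized at the histogram peak), resolution fixed by
  default.

The intensity simplex (ΣIᵢ + background = 1) is enforced by
parameterization: the free-annihilation channel, the largest unfixed
component, is the remainder.  A linear remainder was chosen over a
stick-breaking transform because the map from free parameters to the
reported o-Ps intensity stays the identity, so its Hessian uncertainty
needs no Jacobian gymnastics; the simplex is still enforced exactly, with
a penalty barrier if a proposal leaves [0, 1].

Optimization is L-BFGS-B with numeric gradients (deviance tolerance 1e-8);
when the line search stalls — which happens occasionally at the optimum
with finite-difference gradients — a Nelder-Mead polish certifies
convergence, and up to three seeded, jittered re-initializations are tried
before reporting `converged=False` (never an exception).  Uncertainties
come from the inverse of the central-difference Hessian of the deviance
(covariance = 2 H⁻¹); a profile-likelihood interval (deviance rise of 1,
bisection with warm-started nuisance re-minimization) is available as a
robust cross-check and agrees with the Hessian σ to better than 5% at 10⁶
events, where the deviance is quadratic.

## What the simulator does and does not emulate

Events are drawn exactly from the generative model the fitter assumes:
categorical channel choice, exponential decay plus Gaussian smearing,
uniform background, events outside the window kept until binning so
intensities remain true formation fractions.  It does **not** model photon
energies, detector geometry, scatter, pile-up, source-position effects, or
3-photon o-Ps decay kinematics.  Passing recovery tests therefore
demonstrates that the estimator is unbiased and calibrated *under the
stated spectral model* — it cannot certify the instrument-specific
systematics of a real spectrometer (unknown resolution shape, source
corrections), which is why the uncertainty-scale check is only required to
match the published per-condition precision within a factor of two.

The same logic applies to the radial module: synthetic spheroid images are
two radial Gaussians (rim ridge + core) on a disk with i.i.d. Gaussian
pixel noise; real confocal images have structured noise, optical
sectioning and segmentation ambiguity that the generator does not imitate.
The zone definitions — necrotic core [50, 100) µm, proliferation rim
[100, 200) µm from the intensity-weighted centroid — are half-open and
disjoint by construction, and configurable because layer sizes scale with
spheroid size.

## Statistical comparisons

Two fitted conditions are compared by z = |x_a − x_b|/√(s_a² + s_b²) on
the o-Ps lifetime or intensity.  No multiple-testing correction is applied
(two planned contrasts in an exploratory setting).  The end-to-end
calibration check simulates *identical* truths, fits both, and verifies
that z across replicates is consistent with a half-normal distribution —
a single test that exercises the simulator, the fitter, and the Hessian
uncertainties together.  Replicate counts in the shipped checks (20 for
recovery/precision, 10 for discrimination, 30 for calibration, with
200k-event spectra where only calibration, not absolute precision, is at
stake) were chosen as the smallest ensembles whose pass/fail criteria have
comfortable binomial or KS margins.

Group comparisons of radial zone means use Welch's two-sample t-test
(no equal-variance assumption; the test behind the published p-values is
not stated, so this is a documented choice), with an exact-equality
shortcut (p = 1) for degenerate identical groups.

## Growth arithmetic

Doubling time DT = t·ln2/ln(V₂/V₁) assumes exponential growth over the
interval; it is scale-invariant and composes consistently under a constant
rate.  Shrinkage gives a negative DT with a `GrowthWarning` rather than an
error, since regression phases are real and the formula stays defined;
V₂ = V₁ raises.  Volumes from diameters use V = (π/6)d³.  The published
doubling times (≈7.5 and 6 days for WM115 and WM266-4) derive from
untabulated volume curves and are treated as context, not as recovery
targets.

## Known limitations

- The o-Ps lifetime–intensity correlation (≈ −0.8) is intrinsic at these
  statistics; both are reported with their marginal σ, and the full
  covariance is serialized for anyone propagating jointly.
- Fitting a multi-Gaussian resolution is not supported (single-Gaussian
  FWHM only, and off by default).
- Intensities are fractions of all events in the fit window, not
  source-corrected fractions; when comparing to analyses that renormalize
  after source subtraction, divide by (1 − I_source − background).
- The histogram dialect requires uniform bin centers; variable-width
  binning is out of scope.
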