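# palspheroid

Positron annihilation lifetime spectroscopy (PALS) analysis for 3-D tumor
spheroids.

When a positron from a ²²Na source annihilates in soft matter it often first
forms positronium, and the mean lifetime of the triplet state
(ortho-positronium, o-Ps) is set by the size of the intermolecular voids it
is trapped in — from 142 ns in vacuum down to ≈1.8 ns in water.  That makes
the o-Ps lifetime a candidate biomarker: denser, more proliferative tissue
shows shorter lifetimes.  This package implements the full analysis chain
for spheroid PALS experiments on melanoma cell lines (WM266-4, malignant;
WM115, primary), with a Monte-Carlo simulator standing in for the
measurements so every step can be validated against known ground truth:

- **`palspheroid.spectrum`** — the forward model.  Each annihilation channel
  (p-Ps 0.125 ns, source/Kapton 0.374 ns, free annihilation 0.395 ns, and
  o-Ps near 1.8–1.9 ns) is a one-sided exponential convolved with the
  Gaussian timing resolution — an exponentially modified Gaussian
  f(t) = 1/(2τ)·exp(σ²/2τ² − (t−t₀)/τ)·erfc((σ/τ − (t−t₀)/σ)/√2) —
  summed with intensities Iᵢ plus a flat accidental-coincidence background.
  Per-bin expectations are exact CDF differences.
- **`palspheroid.simulate`** — seeded event-level simulation
  (channel ~ Categorical(I₁…I₄, bg), t = t₀ + Exp(τᵢ) + N(0, σ)) and the
  ground-truth models for the four measured conditions (cell line × day).
- **`palspheroid.fit`** — constrained Poisson maximum likelihood
  (`SpectrumFitter`, scikit-learn style): minimizes the Cash deviance
  C = 2Σ[μ_b − k_b + k_b ln(k_b/μ_b)], enforces the intensity simplex by
  parameterization, fixes the short lifetimes and the calibrated source
  fraction, ties I(p-Ps) = I(o-Ps)/3 (spin statistics), and reports
  Hessian and profile-likelihood 1σ uncertainties.
- **`palspheroid.compare`** — condition contrasts in combined-σ units,
  z = |τ_a − τ_b| / √(σ_a² + σ_b²), plus replicate-level discrimination
  power via paired simulate-and-fit runs.
- **`palspheroid.growth`** — spheroid growth arithmetic: V = (π/6)d³,
  fold change, and doubling time DT = t·ln2 / ln(V₂/V₁).
- **`palspheroid.radial`** — synthetic spheroid fluorescence images
  (bright proliferation rim, dim/bright core), annulus-averaged radial
  intensity profiles, necrotic-core (50–100 µm) and proliferation-rim
  (100–200 µm) zone means, and Welch t-tests between spheroid groups.
- **`palspheroid.io` / `palspheroid.cli`** — two-column ASCII histograms
  (bin center [ns] TAB counts, `#` metadata headers), YAML run configs,
  JSON results with provenance, and the `palspheroid` command with verbs
  `simulate`, `fit`, `recover`, `compare`, `discriminate`, `growth`,
  `profile`.

## Worked example

Simulate a million-event spectrum of WM266-4 spheroids on culture day 4
(true o-Ps lifetime 1.876 ns, intensity 16.5%), then decompose it:

```bash
$ palspheroid simulate --condition WM266-4:4 --n-events 1000000 --seed 1 --out spectrum.tsv
$ palspheroid fit spectrum.tsv --out result.json
Poisson-ML spectrum fit  (converged=True)
  I_free         = 0.671954 +/- 0.001603
  I_o-Ps         = 0.16729 +/- 0.001188
  I_p-Ps         = 0.0557633 +/- 0.0003959
  I_source       = 0.1 (fixed)
  background     = 0.0049932 +/- 0.0001012
  fwhm           = 0.25 (fixed)
  t0             = 7.02651e-05 +/- 0.0002911
  tau_free       = 0.394145 +/- 0.001037
  tau_o-Ps       = 1.86697 +/- 0.00983
  tau_p-Ps       = 0.125 (fixed)
  tau_source     = 0.374 (fixed)
  Cash = 1167.17, Pearson chi2/ndf = 1121.7/1075 = 1.043
```

The fitted o-Ps lifetime 1.8670 ± 0.0098 ns and intensity 16.73 ± 0.12%
recover the generating truth (1.876 ns, 16.5%) within two standard
deviations on this draw, and the
Pearson χ²/ndf ≈ 1.04 says the four-component model describes the
simulated histogram.  Comparing two such results gives the contrast in
combined-σ units:

```bash
$ palspheroid discriminate --condition-a WM115:4 --condition-b WM266-4:4 --seed 7
median lifetime z over 10 replicates: 2.712 (0 non-converged)
```

i.e. at a million events per measurement, the day-4 lifetime difference
between the two cell lines (1.909 vs 1.876 ns) is resolved at better than
two combined standard deviations.

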