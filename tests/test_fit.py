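"""Poisson-ML spectrum decomposition: recovery, uncertainties, goodness of
fit and equivalence with an independent unbinned EM mixture fit."""

import numpy as np
import pytest
from sklearn.base import clone

from palspheroid.fit import (
    FitConstraints,
    SpectrumFitter,
    fit_spectrum,
    goodness_of_fit,
    profile_uncertainty,
)
from palspheroid.simulate import (
    SimulationConfig,
    melanoma_condition_model,
    simulate_histogram,
)
from palspheroid.spectrum import (
    DecayComponent,
    LifetimeHistogram,
    ResolutionFunction,
    SpectrumModel,
    default_edges,
    expected_counts,
)

TOY_CONSTRAINTS = FitConstraints(
    fixed_lifetimes={}, fixed_intensities={"background": 0.0}, fit_t0=False
)


def _single_exp_model(tau=2.0, n_events=100_000):
    return SpectrumModel(
        components=(DecayComponent("exp", tau, 1.0),),
        t0=0.0,
        resolution=ResolutionFunction(fwhm=0.02),
        background_fraction=0.0,
        window=(-0.5, 50.0 * tau),
    ).with_updates(n_events=n_events)


def _simulate_and_fit_toy(tau, n_events, seed, tau_init=1.5):
    model = _single_exp_model(tau, n_events)
    hist = simulate_histogram(
        SimulationConfig(model=model, seed=seed),
        bin_edges=default_edges(model.window, 0.05),
    )
    init = model.with_updates(components=(DecayComponent("exp", tau_init, 1.0),))
    return hist, fit_spectrum(hist, init=init, constraints=TOY_CONSTRAINTS)


def test_single_component_recovery_at_cramer_rao_scale():
    """The fitted mean lifetime lands within 3 tau/sqrt(n) of truth — the
    Cramer-Rao bound for an exponential mean with n events."""
    tau, n = 2.0, 100_000
    _, result = _simulate_and_fit_toy(tau, n, seed=3)
    bound = 3.0 * tau / np.sqrt(n)
    assert abs(result.estimates["tau_exp"] - tau) < bound
    assert result.converged
    # Hessian uncertainty agrees with the Cramer-Rao scale
    assert result.uncertainties["tau_exp"] == pytest.approx(tau / np.sqrt(n), rel=0.15)


def test_table_condition_recovery_within_three_sigma(wm266_day4_replicate_fits):
    """Simulated million-event melanoma spectra return the generating o-Ps
    lifetime within 3 fitted sigma."""
    result = wm266_day4_replicate_fits[0]
    tau_hat = result.estimates["tau_o-Ps"]
    sigma = result.uncertainties["tau_o-Ps"]
    assert result.converged
    assert abs(tau_hat - 1.876) < 3.0 * sigma


def test_asimov_self_consistency():
    """Refitting the model's own expected counts returns the truth to
    1e-3 relative (run at 1e8 events so integer rounding of the tail bins
    is negligible against the parameter scale)."""
    model = melanoma_condition_model("WM266-4", 4, n_events=100_000_000)
    edges = default_edges()
    asimov = LifetimeHistogram(edges, np.rint(expected_counts(model, edges)).astype(int))
    result = fit_spectrum(asimov)
    for name, truth in [
        ("tau_o-Ps", 1.876),
        ("tau_free", 0.395),
        ("I_o-Ps", 0.165),
        ("background", 0.005),
    ]:
        assert result.estimates[name] == pytest.approx(truth, rel=1e-3)
    assert goodness_of_fit(result) < 0.05


def test_goodness_of_fit_well_specified(wm266_day4_replicate_fits):
    """A correctly specified fit has reduced Pearson chi2 near one."""
    assert 0.8 < goodness_of_fit(wm266_day4_replicate_fits[0]) < 1.2


def test_goodness_of_fit_detects_missing_ops_component(wm266_day4_model):
    """Dropping the o-Ps channel from the fit inflates chi2/ndf beyond 2."""
    hist = simulate_histogram(SimulationConfig(model=wm266_day4_model, seed=5))
    short = SpectrumModel(
        components=(
            DecayComponent("p-Ps", 0.125, 0.055),
            DecayComponent("source", 0.374, 0.10),
            DecayComponent("free", 0.395, 0.840),
        ),
        t0=0.0,
        background_fraction=0.005,
        window=wm266_day4_model.window,
        n_events=hist.n_events,
    )
    constraints = FitConstraints(fixed_intensities={"source": 0.10})
    result = fit_spectrum(hist, init=short, constraints=constraints)
    assert goodness_of_fit(result) > 2.0


def test_goodness_of_fit_requires_positive_ndf(wm266_day4_replicate_fits):
    from dataclasses import replace

    broken = replace(wm266_day4_replicate_fits[0], ndf=0)
    with pytest.raises(ValueError):
        goodness_of_fit(broken)


def test_profile_interval_matches_hessian_in_quadratic_regime(
    wm266_day4_model, wm266_day4_replicate_fits
):
    """At a million events the deviance is quadratic, so the profile
    interval half-width equals the Hessian sigma within 5%."""
    hist = simulate_histogram(SimulationConfig(model=wm266_day4_model, seed=1))
    result = wm266_day4_replicate_fits[0]
    lo, hi = profile_uncertainty(hist, result, "tau_o-Ps")
    half_width = 0.5 * (hi - lo)
    assert lo < result.estimates["tau_o-Ps"] < hi
    assert half_width == pytest.approx(result.uncertainties["tau_o-Ps"], rel=0.05)


def test_profile_width_shrinks_like_root_n():
    """Doubling the event count shrinks the profile half-width by about
    sqrt(2) (ratio within (1.2, 1.7))."""
    widths = []
    for n, seed in ((200_000, 11), (400_000, 11)):
        hist, result = _simulate_and_fit_toy(2.0, n, seed)
        lo, hi = profile_uncertainty(hist, result, "tau_exp")
        widths.append(0.5 * (hi - lo))
    ratio = widths[0] / widths[1]
    assert 1.2 < ratio < 1.7


def test_profile_requires_convergence(wm266_day4_replicate_fits):
    from dataclasses import replace

    hist = simulate_histogram(
        SimulationConfig(model=melanoma_condition_model("WM266-4", 4), seed=1)
    )
    broken = replace(wm266_day4_replicate_fits[0], converged=False)
    with pytest.raises(ValueError):
        profile_uncertainty(hist, broken, "tau_o-Ps")


def test_all_zero_histogram_rejected():
    edges = default_edges((-2.0, 25.0))
    hist = LifetimeHistogram(edges, np.zeros(edges.size - 1, dtype=int))
    with pytest.raises(ValueError):
        fit_spectrum(hist)


def test_init_violating_constraints_rejected(wm266_day4_model):
    """Fixed intensities that leave no room for the remainder are an error."""
    hist = simulate_histogram(
        SimulationConfig(model=wm266_day4_model, seed=8, n_events=10_000)
    )
    bad = FitConstraints(fixed_intensities={"source": 0.95, "free": 0.9})
    with pytest.raises(ValueError):
        fit_spectrum(hist, constraints=bad)


def test_intensity_simplex_and_covariance_shape(wm266_day4_replicate_fits):
    result = wm266_day4_replicate_fits[0]
    total = (
        sum(v for k, v in result.estimates.items() if k.startswith("I_"))
        + result.estimates["background"]
    )
    assert total == pytest.approx(1.0, abs=1e-6)
    cov = result.covariance
    assert np.allclose(cov, cov.T, atol=1e-8)
    assert np.all(np.linalg.eigvalsh(cov) > -1e-8)
    assert all(v >= 0 for v in result.uncertainties.values())


def test_monotone_response_to_true_lifetime():
    """Raising the true o-Ps lifetime from 1.861 to 1.909 ns raises the
    mean fitted lifetime — the discriminating direction between
    conditions."""
    means = []
    for cell_line, day in (("WM266-4", 8), ("WM115", 4)):
        model = melanoma_condition_model(cell_line, day)
        taus = [
            fit_spectrum(
                simulate_histogram(SimulationConfig(model=model, seed=s))
            ).estimates["tau_o-Ps"]
            for s in (31, 32, 33)
        ]
        means.append(np.mean(taus))
    assert means[1] > means[0]


def test_bin_width_invariance(wm266_day4_model):
    """Halving the bin width moves the fitted o-Ps lifetime by less than
    one fitted sigma (CDF-based expectations are binning-exact)."""
    from palspheroid.simulate import bin_events, sample_events

    times = sample_events(SimulationConfig(model=wm266_day4_model, seed=17))
    results = []
    for width in (0.025, 0.0125):
        hist = bin_events(times, default_edges(wm266_day4_model.window, width))
        results.append(fit_spectrum(hist))
    delta = abs(results[0].estimates["tau_o-Ps"] - results[1].estimates["tau_o-Ps"])
    assert delta < results[0].uncertainties["tau_o-Ps"]


def _em_exponential_mixture(times, tau_init, n_iter=500):
    """Independent oracle: unbinned EM for a two-exponential mixture."""
    tau = np.asarray(tau_init, dtype=float)
    w = np.array([0.5, 0.5])
    t = np.asarray(times)
    for _ in range(n_iter):
        dens = w[None, :] / tau[None, :] * np.exp(-t[:, None] / tau[None, :])
        resp = dens / dens.sum(axis=1, keepdims=True)
        w = resp.mean(axis=0)
        tau = (resp * t[:, None]).sum(axis=0) / resp.sum(axis=0)
    return tau, w


def test_binned_mle_matches_unbinned_em_oracle():
    """On a resolution-free two-component mixture the binned Poisson MLE
    agrees with a direct unbinned EM fit within 2 sigma."""
    model = SpectrumModel(
        components=(
            DecayComponent("fast", 0.5, 0.6),
            DecayComponent("slow", 3.0, 0.4),
        ),
        t0=0.0,
        resolution=ResolutionFunction(fwhm=1e-12),
        background_fraction=0.0,
        window=(-0.5, 60.0),
        n_events=200_000,
    )
    from palspheroid.simulate import sample_events, bin_events

    times = sample_events(SimulationConfig(model=model, seed=21))
    hist = bin_events(times, default_edges(model.window, 0.05))
    init = model.with_updates(
        components=(
            DecayComponent("fast", 0.3, 0.5),
            DecayComponent("slow", 4.0, 0.5),
        )
    )
    result = fit_spectrum(hist, init=init, constraints=TOY_CONSTRAINTS)
    em_tau, _ = _em_exponential_mixture(times[times > 0], [0.3, 4.0])
    for label, em_value in zip(("fast", "slow"), sorted(em_tau)):
        sigma = result.uncertainties[f"tau_{label}"]
        assert abs(result.estimates[f"tau_{label}"] - em_value) < 2.0 * sigma


def test_sklearn_estimator_protocol(wm266_day4_model):
    fitter = SpectrumFitter(n_restarts=2, random_state=7)
    params = fitter.get_params()
    assert params["n_restarts"] == 2
    cloned = clone(fitter)
    assert cloned.get_params() == params
    hist = simulate_histogram(
        SimulationConfig(model=wm266_day4_model, seed=13, n_events=300_000)
    )
    fitter.fit(hist)
    assert fitter.converged_
    assert set(fitter.lifetimes_) == {"p-Ps", "source", "free", "o-Ps"}
    mu = fitter.predict()
    assert mu.shape == hist.counts.shape
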