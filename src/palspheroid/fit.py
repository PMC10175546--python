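"""Constrained Poisson maximum-likelihood decomposition of PALS spectra.

The binned spectrum is fit by minimizing the Poisson deviance (Cash
statistic)

    C = 2 * sum_b [ mu_b - k_b + k_b * ln(k_b / mu_b) ]

over the free model parameters, with terms for empty bins reducing to
``2 mu_b``.  The deviance, unlike weighted least squares, stays unbiased in
the low-count tail at long times where the o-Ps channel lives.  Pearson
chi-square is reported alongside for familiarity.

Constraint policy (all configurable): the p-Ps and source lifetimes are
fixed at 0.125 and 0.374 ns, and the source intensity at its calibration
value — the 0.374/0.395 ns pair is too degenerate to resolve freely.  The
p-Ps intensity is tied to one third of the o-Ps intensity (positronium
forms in the singlet state in 1/4 of cases and the triplet in 3/4, so the
ratio is fixed by spin statistics); untying it roughly doubles the o-Ps
lifetime uncertainty through the short-time degeneracy.  The intensity
simplex (components + background summing to one) is enforced by
parameterization: the free-annihilation channel takes the remainder.

The estimator is scikit-learn flavoured: construct a
:class:`SpectrumFitter`, call ``fit`` on a :class:`~.spectrum.LifetimeHistogram`,
read the fitted attributes.  :func:`fit_spectrum` is the functional wrapper.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
from scipy import optimize, special
from sklearn.base import BaseEstimator

from .spectrum import (
    FWHM_TO_SIGMA,
    DecayComponent,
    LifetimeHistogram,
    ResolutionFunction,
    SpectrumModel,
    expected_counts,
)

__all__ = [
    "FitConstraints",
    "FitResult",
    "SpectrumFitter",
    "fit_spectrum",
    "profile_uncertainty",
    "goodness_of_fit",
]

_PENALTY = 1e12


def _default_fixed_lifetimes() -> Dict[str, float]:
    return {"p-Ps": 0.125, "source": 0.374}


def _default_fixed_intensities() -> Dict[str, float]:
    # Source fraction from the empty-chamber calibration measurement.
    return {"source": 0.10}


def _default_tied_intensities() -> Dict[str, Tuple[str, float]]:
    # Singlet:triplet positronium formation ratio is 1:3 by spin statistics.
    return {"p-Ps": ("o-Ps", 1.0 / 3.0)}


@dataclass(frozen=True)
class FitConstraints:
    """Which parameters are fixed, which are free, and their bounds.

    ``fixed_intensities`` may contain the special key ``"background"`` to
    pin the accidental-coincidence fraction.  ``tied_intensities`` maps a
    component to ``(other_component, factor)`` meaning its intensity is
    ``factor`` times the other's (ties naming components absent from the
    model are silently inactive, so the default p-Ps/o-Ps tie does not get
    in the way of toy fits).  ``bounds`` maps parameter names
    (``tau_<label>``, ``I_<label>``, ``background``, ``t0``, ``fwhm``) to
    ``(low, high)`` pairs overriding the defaults.
    """

    fixed_lifetimes: Mapping[str, float] = field(default_factory=_default_fixed_lifetimes)
    fixed_intensities: Mapping[str, float] = field(default_factory=_default_fixed_intensities)
    fit_t0: bool = True
    fit_resolution: bool = False
    bounds: Mapping[str, Tuple[float, float]] = field(default_factory=dict)
    tied_intensities: Mapping[str, Tuple[str, float]] = field(
        default_factory=_default_tied_intensities
    )

    def __post_init__(self) -> None:
        object.__setattr__(self, "fixed_lifetimes", dict(self.fixed_lifetimes))
        object.__setattr__(self, "fixed_intensities", dict(self.fixed_intensities))
        object.__setattr__(self, "bounds", dict(self.bounds))
        object.__setattr__(
            self,
            "tied_intensities",
            {k: (v[0], float(v[1])) for k, v in dict(self.tied_intensities).items()},
        )
        for name, (src, factor) in self.tied_intensities.items():
            if name == src:
                raise ValueError(f"component {name!r} cannot be tied to itself")
            if not factor > 0:
                raise ValueError(f"tie factor for {name!r} must be > 0, got {factor}")
        for name, value in self.fixed_lifetimes.items():
            if not value > 0:
                raise ValueError(f"fixed lifetime for {name!r} must be > 0, got {value}")
        for name, value in self.fixed_intensities.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(
                    f"fixed intensity for {name!r} must be in [0, 1], got {value}"
                )
        for name, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ValueError(f"bounds for {name!r} must be ordered, got ({lo}, {hi})")


@dataclass(frozen=True)
class FitResult:
    """Decomposition result: point estimates, uncertainties and diagnostics.

    ``estimates`` holds every model parameter (lifetimes ``tau_<label>``,
    intensities ``I_<label>``, ``background``, ``t0``, ``fwhm``), fixed or
    free; ``uncertainties`` holds 1-sigma errors for the free parameters
    (plus the derived remainder intensity).  ``covariance`` is ordered as
    ``param_names``.  ``cash`` is -2 log-likelihood up to a data-only
    constant; ``ndf`` is bins minus free parameters.
    """

    estimates: Dict[str, float]
    uncertainties: Dict[str, float]
    covariance: np.ndarray
    param_names: Tuple[str, ...]
    cash: float
    pearson_chi2: float
    ndf: int
    converged: bool
    n_events_fit: int
    model: SpectrumModel
    constraints: FitConstraints
    metadata: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cov = np.asarray(self.covariance, dtype=float)
        if cov.shape != (len(self.param_names),) * 2:
            raise ValueError("covariance shape must match param_names")
        if not np.allclose(cov, cov.T, atol=1e-8):
            raise ValueError("covariance must be symmetric")
        object.__setattr__(self, "covariance", cov)

    def summary(self) -> str:
        lines = [f"Poisson-ML spectrum fit  (converged={self.converged})"]
        for name in sorted(self.estimates):
            err = self.uncertainties.get(name)
            tail = f" +/- {err:.4g}" if err is not None else " (fixed)"
            lines.append(f"  {name:14s} = {self.estimates[name]:.6g}{tail}")
        lines.append(
            f"  Cash = {self.cash:.2f}, Pearson chi2/ndf = "
            f"{self.pearson_chi2:.1f}/{self.ndf} = {self.pearson_chi2 / self.ndf:.3f}"
        )
        return "\n".join(lines)


def cash_statistic(counts: np.ndarray, mu: np.ndarray) -> float:
    """Poisson deviance ``2 sum(mu - k + k ln(k/mu))``; 0-count terms give 2 mu."""
    mu = np.maximum(mu, 1e-300)
    return float(2.0 * np.sum(mu - counts + special.xlogy(counts, counts / mu)))


def pearson_chi2(counts: np.ndarray, mu: np.ndarray) -> float:
    """Pearson chi-square over bins with positive expectation."""
    ok = mu > 0
    return float(np.sum((counts[ok] - mu[ok]) ** 2 / mu[ok]))


class _Parameterization:
    """Maps a free-parameter vector to a SpectrumModel and back.

    One component's intensity (the unfixed component with the largest
    initial intensity, normally free annihilation) is the simplex
    remainder; all other unfixed intensities, the background, unfixed
    lifetimes, t0 and optionally the resolution FWHM are free parameters.
    """

    def __init__(self, init: SpectrumModel, constraints: FitConstraints):
        self.constraints = constraints
        labels = [c.label for c in init.components]
        for name in constraints.fixed_lifetimes:
            if name not in labels:
                raise ValueError(f"fixed lifetime for unknown component {name!r}")
        for name in constraints.fixed_intensities:
            if name != "background" and name not in labels:
                raise ValueError(f"fixed intensity for unknown component {name!r}")

        fixed_i = constraints.fixed_intensities
        self.background_fixed = "background" in fixed_i
        # Active ties: both endpoints present, tied side not fixed, no chains.
        self.ties = {
            name: (src, fac)
            for name, (src, fac) in constraints.tied_intensities.items()
            if name in labels and src in labels and name not in fixed_i
        }
        for name, (src, _) in self.ties.items():
            if src in self.ties:
                raise ValueError(
                    f"intensity tie chain {name!r} -> {src!r} is not supported"
                )
        candidates = [
            c for c in init.components if c.label not in fixed_i and c.label not in self.ties
        ]
        if not candidates:
            raise ValueError("at least one component intensity must be free")
        self.remainder = max(candidates, key=lambda c: c.intensity).label
        #: total tie factor hanging off the remainder component
        self._rem_tie_factor = sum(
            fac for _, (src, fac) in self.ties.items() if src == self.remainder
        )

        # Apply the fixed/tied values to the initial model so init respects
        # them, absorbing any imbalance into the remainder component:
        # R (1 + sum of tie factors onto R) = 1 - bg - other masses.
        values = {c.label: c.intensity for c in init.components}
        values.update({k: v for k, v in fixed_i.items() if k != "background"})
        bg = fixed_i.get("background", init.background_fraction)
        known = bg
        for label, v in values.items():
            if label == self.remainder or label in self.ties:
                continue
            known += v
        for _, (src, fac) in self.ties.items():
            if src != self.remainder:
                known += fac * values[src]
        values[self.remainder] = (1.0 - known) / (1.0 + self._rem_tie_factor)
        for name, (src, fac) in self.ties.items():
            values[name] = fac * values[src]
        comps = []
        for c in init.components:
            lt = constraints.fixed_lifetimes.get(c.label, c.lifetime)
            it = values[c.label]
            if not 0.0 <= it <= 1.0:
                raise ValueError(
                    "initial model violates the intensity constraints "
                    f"(component {c.label!r} would need intensity {it:.4g})"
                )
            comps.append(DecayComponent(c.label, lt, it))
        self.init = replace(init, components=tuple(comps), background_fraction=bg)

        names: List[str] = []
        bounds: List[Tuple[float, float]] = []
        x0: List[float] = []
        for c in self.init.components:
            if c.label not in constraints.fixed_lifetimes:
                names.append(f"tau_{c.label}")
                bounds.append(constraints.bounds.get(f"tau_{c.label}", (1e-3, 50.0)))
                x0.append(c.lifetime)
        for c in self.init.components:
            if c.label in fixed_i or c.label in self.ties or c.label == self.remainder:
                continue
            names.append(f"I_{c.label}")
            bounds.append(constraints.bounds.get(f"I_{c.label}", (0.0, 1.0)))
            x0.append(c.intensity)
        if not self.background_fixed:
            names.append("background")
            bounds.append(constraints.bounds.get("background", (0.0, 0.5)))
            x0.append(self.init.background_fraction)
        if constraints.fit_t0:
            names.append("t0")
            bounds.append(
                constraints.bounds.get("t0", (self.init.t0 - 0.5, self.init.t0 + 0.5))
            )
            x0.append(self.init.t0)
        if constraints.fit_resolution:
            if self.init.resolution.terms is not None:
                raise ValueError("fitting a multi-Gaussian resolution is not supported")
            names.append("fwhm")
            bounds.append(constraints.bounds.get("fwhm", (0.01, 2.0)))
            x0.append(self.init.resolution.fwhm)
        self.names = tuple(names)
        self.bounds = tuple(bounds)
        self.x0 = np.array(x0, dtype=float)
        for x, (lo, hi), name in zip(self.x0, self.bounds, self.names):
            if not lo <= x <= hi:
                raise ValueError(f"initial {name} = {x} outside bounds ({lo}, {hi})")

    def _value(self, label: str, x: np.ndarray, idx: Dict[str, int]) -> float:
        """Intensity of a non-remainder, non-tied component at ``x``."""
        key = f"I_{label}"
        if key in idx:
            return float(x[idx[key]])
        return self.init.component(label).intensity

    def remainder_intensity(self, x: np.ndarray) -> float:
        idx = {n: i for i, n in enumerate(self.names)}
        known = (
            x[idx["background"]] if "background" in idx else self.init.background_fraction
        )
        for c in self.init.components:
            if c.label == self.remainder or c.label in self.ties:
                continue
            known += self._value(c.label, x, idx)
        for _, (src, fac) in self.ties.items():
            if src != self.remainder:
                known += fac * self._value(src, x, idx)
        return (1.0 - known) / (1.0 + self._rem_tie_factor)

    def build(self, x: np.ndarray) -> Optional[SpectrumModel]:
        """Model for parameter vector ``x``; None if the simplex is violated."""
        idx = {n: i for i, n in enumerate(self.names)}
        i_rem = self.remainder_intensity(x)
        if not 0.0 <= i_rem <= 1.0:
            return None
        comps = []
        for c in self.init.components:
            lt = x[idx[f"tau_{c.label}"]] if f"tau_{c.label}" in idx else c.lifetime
            if c.label == self.remainder:
                it = i_rem
            elif c.label in self.ties:
                src, fac = self.ties[c.label]
                it = fac * (i_rem if src == self.remainder else self._value(src, x, idx))
            else:
                it = self._value(c.label, x, idx)
            if lt <= 0 or not 0.0 <= it <= 1.0:
                return None
            comps.append(DecayComponent(c.label, lt, it))
        bg = x[idx["background"]] if "background" in idx else self.init.background_fraction
        t0 = x[idx["t0"]] if "t0" in idx else self.init.t0
        res = (
            ResolutionFunction(fwhm=x[idx["fwhm"]])
            if "fwhm" in idx
            else self.init.resolution
        )
        if not self.init.window[0] < t0 < self.init.window[1]:
            return None
        # Remainder construction makes the intensity sum exactly 1 up to
        # float rounding, so the model's own simplex validation passes.
        model = replace(
            self.init,
            components=tuple(comps),
            background_fraction=bg,
            t0=t0,
            resolution=res,
        )
        return model

    def remainder_gradient(self) -> np.ndarray:
        """d(remainder intensity)/d(free parameters), for error propagation."""
        grad = np.zeros(len(self.names))
        denom = 1.0 + self._rem_tie_factor
        for i, name in enumerate(self.names):
            if name == "background":
                grad[i] = -1.0 / denom
            elif name.startswith("I_"):
                label = name[2:]
                tie_load = sum(
                    fac for _, (src, fac) in self.ties.items() if src == label
                )
                grad[i] = -(1.0 + tie_load) / denom
        return grad

    def full_estimates(self, x: np.ndarray) -> Dict[str, float]:
        model = self.build(x)
        est: Dict[str, float] = {}
        for c in model.components:
            est[f"tau_{c.label}"] = c.lifetime
            est[f"I_{c.label}"] = c.intensity
        est["background"] = model.background_fraction
        est["t0"] = model.t0
        est["fwhm"] = model.resolution.components[0][0]
        return est


def _numeric_hessian(f, x: np.ndarray, f0: float) -> np.ndarray:
    """Central-difference Hessian of a scalar function."""
    n = x.size
    h = 1e-3 * np.maximum(np.abs(x), 0.01)
    H = np.empty((n, n))
    fp = np.empty(n)
    fm = np.empty(n)
    for i in range(n):
        ei = np.zeros(n)
        ei[i] = h[i]
        fp[i] = f(x + ei)
        fm[i] = f(x - ei)
        H[i, i] = (fp[i] - 2.0 * f0 + fm[i]) / h[i] ** 2
    for i in range(n):
        for j in range(i + 1, n):
            ei = np.zeros(n)
            ej = np.zeros(n)
            ei[i] = h[i]
            ej[j] = h[j]
            fpp = f(x + ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (
                fpp - fp[i] - fp[j] + 2.0 * f0 - fm[i] - fm[j] + fmm
            ) / (2.0 * h[i] * h[j])
    return H


def default_init(
    hist: LifetimeHistogram, constraints: Optional[FitConstraints] = None
) -> SpectrumModel:
    """Data-driven initial model for a four-component melanoma-style fit.

    t0 starts at the histogram peak, the background at the pre-peak count
    level, the o-Ps lifetime at the water-like 1.8 ns, intensities at
    typical spheroid values.
    """
    constraints = constraints or FitConstraints()
    centers = hist.bin_centers
    t0 = float(centers[int(np.argmax(hist.counts))])
    sigma_guess = 0.25 * FWHM_TO_SIGMA
    pre = centers < t0 - 4.0 * sigma_guess
    n_total = max(hist.n_events, 1)
    if pre.any():
        bg = float(hist.counts[pre].mean()) * hist.counts.size / n_total
    else:
        bg = 0.005
    bg = float(np.clip(bg, 1e-5, 0.2))
    i_ops, i_src = 0.17, constraints.fixed_intensities.get("source", 0.10)
    i_pps = i_ops / 3.0
    i_free = 1.0 - bg - i_ops - i_pps - i_src
    components = (
        DecayComponent("p-Ps", constraints.fixed_lifetimes.get("p-Ps", 0.125), i_pps),
        DecayComponent("source", constraints.fixed_lifetimes.get("source", 0.374), i_src),
        DecayComponent("free", 0.395, i_free),
        DecayComponent("o-Ps", 1.8, i_ops),
    )
    window = (float(hist.bin_edges[0]), float(hist.bin_edges[-1]))
    return SpectrumModel(
        components=components,
        t0=t0,
        resolution=ResolutionFunction(),
        background_fraction=bg,
        window=window,
        n_events=n_total,
    )


class SpectrumFitter(BaseEstimator):
    """Poisson maximum-likelihood PALS spectrum decomposition.

    Parameters
    ----------
    init_model : SpectrumModel, optional
        Starting model.  Default: a data-driven four-component
        initialization (:func:`default_init`).
    constraints : FitConstraints, optional
        Fixed/free parameter policy; default fixes the p-Ps and source
        lifetimes and the calibrated source intensity.
    tol : float
        Convergence tolerance on the deviance.
    max_iter : int
        Iteration cap for the optimizer.
    n_restarts : int
        Jittered re-initializations attempted when the optimizer stalls.
    random_state : int
        Seed for the restart jitter.

    Attributes
    ----------
    result_ : FitResult
    estimates_, uncertainties_ : dict
    lifetimes_, intensities_ : dict per component label
    t0_, background_, cash_, pearson_chi2_, ndf_, converged_ : scalars
    """

    def __init__(
        self,
        init_model: Optional[SpectrumModel] = None,
        constraints: Optional[FitConstraints] = None,
        tol: float = 1e-8,
        max_iter: int = 2000,
        n_restarts: int = 3,
        random_state: int = 0,
    ):
        self.init_model = init_model
        self.constraints = constraints
        self.tol = tol
        self.max_iter = max_iter
        self.n_restarts = n_restarts
        self.random_state = random_state

    def fit(self, X: LifetimeHistogram, y=None) -> "SpectrumFitter":
        hist = X
        if not isinstance(hist, LifetimeHistogram):
            raise TypeError("X must be a LifetimeHistogram")
        counts = hist.counts
        if counts.sum() == 0:
            raise ValueError("cannot fit an all-zero histogram")
        constraints = self.constraints or FitConstraints()
        init = self.init_model or default_init(hist, constraints)
        param = _Parameterization(init, constraints)
        edges = hist.bin_edges

        def objective(x: np.ndarray) -> float:
            model = param.build(x)
            if model is None:
                return _PENALTY + float(np.sum(np.square(x)))
            mu = expected_counts(model, edges)
            return cash_statistic(counts, mu)

        rng = np.random.default_rng(self.random_state)
        ftol = self.tol / max(1.0, float(counts.sum()) ** 0.5)  # relative ftol
        best = None
        best_ok = False
        x_start = param.x0.copy()
        for attempt in range(1 + self.n_restarts):
            res = optimize.minimize(
                objective,
                x_start,
                method="L-BFGS-B",
                bounds=param.bounds,
                options={"maxiter": self.max_iter, "ftol": ftol, "gtol": 1e-8},
            )
            ok = bool(res.success)
            if not ok and res.fun < _PENALTY:
                # Line searches on numeric gradients can stall at the
                # optimum; certify with a derivative-free polish.
                polish = optimize.minimize(
                    objective,
                    res.x,
                    method="Nelder-Mead",
                    bounds=param.bounds,
                    options={"xatol": 1e-7, "fatol": self.tol, "maxiter": 4000},
                )
                if polish.fun <= res.fun:
                    res = polish
                    ok = bool(polish.success)
            if best is None or res.fun < best.fun:
                best = res
                best_ok = ok
            if best_ok and best.fun < _PENALTY:
                break
            # jitter within bounds for a fresh start
            scale = 0.05 * np.maximum(np.abs(param.x0), 0.01)
            x_start = param.x0 + rng.normal(0.0, scale)
            x_start = np.clip(
                x_start,
                [lo for lo, _ in param.bounds],
                [hi for _, hi in param.bounds],
            )

        x_hat = np.asarray(best.x, dtype=float)
        converged = bool(best_ok and best.fun < _PENALTY)
        model_hat = param.build(x_hat)
        if model_hat is None:  # pragma: no cover - penalty keeps us inside
            model_hat = param.init
            converged = False
        mu_hat = expected_counts(model_hat, edges)
        cash = cash_statistic(counts, mu_hat)
        chi2 = pearson_chi2(counts, mu_hat)
        ndf = counts.size - len(param.names)

        cov = np.full((len(param.names),) * 2, np.nan)
        uncertainties: Dict[str, float] = {}
        if len(param.names):
            H = _numeric_hessian(objective, x_hat, cash)
            try:
                cov = 2.0 * np.linalg.inv(H)
            except np.linalg.LinAlgError:
                cov = 2.0 * np.linalg.pinv(H)
                converged = False
            cov = 0.5 * (cov + cov.T)
            diag = np.diag(cov)
            if np.any(diag < 0):
                converged = False
            with np.errstate(invalid="ignore"):
                errs = np.sqrt(np.maximum(diag, 0.0))
            uncertainties = dict(zip(param.names, errs))
            # Derived 1-sigma of the remainder intensity (linear map of the
            # free intensities and background) and of tied intensities.
            coeff = param.remainder_gradient()
            var_rem = float(coeff @ cov @ coeff)
            sigma_rem = math_sqrt_nonneg(var_rem)
            uncertainties[f"I_{param.remainder}"] = sigma_rem
            for name, (src, fac) in param.ties.items():
                if src == param.remainder:
                    uncertainties[f"I_{name}"] = fac * sigma_rem
                elif f"I_{src}" in uncertainties:
                    uncertainties[f"I_{name}"] = fac * uncertainties[f"I_{src}"]

        estimates = param.full_estimates(x_hat)
        self.result_ = FitResult(
            estimates=estimates,
            uncertainties=uncertainties,
            covariance=np.nan_to_num(cov, nan=0.0, posinf=0.0, neginf=0.0)
            if np.isnan(cov).any()
            else cov,
            param_names=param.names,
            cash=cash,
            pearson_chi2=chi2,
            ndf=ndf,
            converged=converged,
            n_events_fit=int(counts.sum()),
            model=model_hat,
            constraints=constraints,
            metadata=dict(hist.metadata),
        )
        self.estimates_ = estimates
        self.uncertainties_ = uncertainties
        self.lifetimes_ = {c.label: c.lifetime for c in model_hat.components}
        self.intensities_ = {c.label: c.intensity for c in model_hat.components}
        self.t0_ = model_hat.t0
        self.background_ = model_hat.background_fraction
        self.cash_ = cash
        self.pearson_chi2_ = chi2
        self.ndf_ = ndf
        self.converged_ = converged
        self._hist = hist
        self._param = param
        return self

    def predict(self, bin_edges=None) -> np.ndarray:
        """Expected counts of the fitted model on the given (or fit) binning."""
        if not hasattr(self, "result_"):
            raise AttributeError("fit the estimator first")
        edges = self._hist.bin_edges if bin_edges is None else bin_edges
        return expected_counts(self.result_.model, edges)


def math_sqrt_nonneg(x: float) -> float:
    return float(np.sqrt(x)) if x > 0 else 0.0


def fit_spectrum(
    hist: LifetimeHistogram,
    init: Optional[SpectrumModel] = None,
    constraints: Optional[FitConstraints] = None,
    **kwargs,
) -> FitResult:
    """Fit a lifetime histogram; functional wrapper over :class:`SpectrumFitter`."""
    fitter = SpectrumFitter(init_model=init, constraints=constraints, **kwargs)
    return fitter.fit(hist).result_


def goodness_of_fit(result: FitResult) -> float:
    """Pearson reduced chi-square of a fit; raises when ndf <= 0."""
    if result.ndf <= 0:
        raise ValueError(f"ndf must be positive, got {result.ndf}")
    return result.pearson_chi2 / result.ndf


def profile_uncertainty(
    hist: LifetimeHistogram,
    result: FitResult,
    parameter: str,
    rise: float = 1.0,
) -> Tuple[float, float]:
    """Profile-likelihood 1-sigma interval for one free parameter.

    Scans the parameter away from its estimate, re-minimizing the deviance
    over the remaining free parameters, and bisects for the points where
    the profile deviance exceeds the minimum by ``rise`` (1.0 for 68%).
    """
    if not result.converged:
        raise ValueError("profile_uncertainty requires a converged fit")
    param = _Parameterization(result.model, result.constraints)
    if parameter not in param.names:
        raise KeyError(f"{parameter!r} is not a free parameter of this fit")
    k = param.names.index(parameter)
    counts = hist.counts
    edges = hist.bin_edges
    free_idx = [i for i in range(len(param.names)) if i != k]

    def objective(x: np.ndarray) -> float:
        model = param.build(x)
        if model is None:
            return _PENALTY + float(np.sum(np.square(x)))
        return cash_statistic(counts, expected_counts(model, edges))

    x_hat = param.x0.copy()
    c_min = objective(x_hat)

    def profile(value: float, warm: np.ndarray) -> Tuple[float, np.ndarray]:
        if not free_idx:
            x = warm.copy()
            x[k] = value
            return objective(x), x

        def restricted(z: np.ndarray) -> float:
            x = warm.copy()
            x[k] = value
            x[free_idx] = z
            return objective(x)

        res = optimize.minimize(
            restricted,
            warm[free_idx],
            method="L-BFGS-B",
            bounds=[param.bounds[i] for i in free_idx],
            options={"ftol": 1e-13, "gtol": 1e-9},
        )
        x = warm.copy()
        x[k] = value
        x[free_idx] = res.x
        return float(res.fun), x

    sigma0 = result.uncertainties.get(parameter) or 0.1 * max(abs(x_hat[k]), 1e-3)
    lo_b, hi_b = param.bounds[k]

    def find_crossing(direction: float) -> float:
        step = 1.5 * sigma0
        inner = x_hat[k]
        warm = x_hat.copy()
        outer = None
        for _ in range(30):
            cand = x_hat[k] + direction * step
            cand = min(max(cand, lo_b), hi_b)
            c_val, warm = profile(cand, warm)
            if c_val >= c_min + rise:
                outer = cand
                break
            inner = cand
            if cand in (lo_b, hi_b):
                return cand  # bound reached before the rise: truncated interval
            step *= 2.0
        if outer is None:
            return inner
        for _ in range(40):
            mid = 0.5 * (inner + outer)
            c_val, warm = profile(mid, warm)
            if c_val >= c_min + rise:
                outer = mid
            else:
                inner = mid
            if abs(outer - inner) < 1e-3 * sigma0:
                break
        return 0.5 * (inner + outer)

    low = find_crossing(-1.0)
    high = find_crossing(+1.0)
    return (min(low, high), max(low, high))
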