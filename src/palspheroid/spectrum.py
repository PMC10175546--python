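"""Forward model for positron annihilation lifetime (PALS) spectra.

A coincidence lifetime spectrum is a histogram of time differences between
the 1274 keV "start" photon emitted promptly after a ``22Na`` beta decay and
one of the 511 keV annihilation photons.  Each annihilation channel —
para-positronium (p-Ps), annihilation inside the foil-wrapped source,
free electron–positron annihilation, and ortho-positronium (o-Ps) — decays
exponentially with its own mean lifetime, and the spectrometer smears every
channel with its timing resolution.  For a Gaussian resolution each channel
is an exponentially modified Gaussian (EMG); the full spectrum is an
intensity-weighted sum of EMGs plus a flat background of accidental
coincidences over the measurement window.

All times are in nanoseconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence, Tuple

import numpy as np
from scipy import special

__all__ = [
    "FWHM_TO_SIGMA",
    "DecayComponent",
    "ResolutionFunction",
    "SpectrumModel",
    "LifetimeHistogram",
    "emg_density",
    "emg_cdf",
    "expected_counts",
    "default_components",
    "default_edges",
]

#: Conversion from a Gaussian full width at half maximum to its sigma.
FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))

_SQRT2 = math.sqrt(2.0)


@dataclass(frozen=True)
class DecayComponent:
    """One annihilation channel: a label, mean lifetime [ns] and intensity.

    The intensity is the fraction of all coincidence events produced by this
    channel (before any window truncation).
    """

    label: str
    lifetime: float
    intensity: float

    def __post_init__(self) -> None:
        if not self.lifetime > 0:
            raise ValueError(
                f"component {self.label!r}: lifetime must be > 0 ns, "
                f"got {self.lifetime}"
            )
        if not 0.0 <= self.intensity <= 1.0:
            raise ValueError(
                f"component {self.label!r}: intensity must be in [0, 1], "
                f"got {self.intensity}"
            )


@dataclass(frozen=True)
class ResolutionFunction:
    """Gaussian timing resolution, FWHM-parameterized.

    A single Gaussian by default.  A weighted sum of Gaussians (each with its
    own FWHM, weight and time shift) is supported for spectrometers whose
    response is not well described by one Gaussian; weights must sum to 1.
    """

    fwhm: float = 0.25
    terms: Tuple[Tuple[float, float, float], ...] | None = None

    def __post_init__(self) -> None:
        if self.terms is None:
            if not self.fwhm > 0:
                raise ValueError(f"fwhm must be > 0 ns, got {self.fwhm}")
        else:
            terms = tuple((float(f), float(w), float(s)) for f, w, s in self.terms)
            object.__setattr__(self, "terms", terms)
            if any(f <= 0 for f, _, _ in terms):
                raise ValueError("all resolution FWHMs must be > 0")
            if any(w < 0 for _, w, _ in terms):
                raise ValueError("resolution weights must be >= 0")
            total = sum(w for _, w, _ in terms)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"resolution weights must sum to 1, got {total}")

    @property
    def components(self) -> Tuple[Tuple[float, float, float], ...]:
        """(fwhm, weight, shift) triples; a single-Gaussian response has one."""
        if self.terms is None:
            return ((self.fwhm, 1.0, 0.0),)
        return self.terms

    @property
    def sigma(self) -> float:
        """Weighted RMS sigma of the response [ns] (exact for one Gaussian)."""
        var = sum(w * ((f * FWHM_TO_SIGMA) ** 2 + s**2) for f, w, s in self.components)
        return math.sqrt(var)


def default_components() -> Tuple[DecayComponent, ...]:
    """The canonical four-channel decomposition of a ``22Na``-source spectrum.

    p-Ps at 0.125 ns, source (Kapton foil) at 0.374 ns, free annihilation at
    0.395 ns and o-Ps at a water-like 1.8 ns.  Intensities follow the 1:3
    p-Ps:o-Ps formation ratio with a typical 10% source fraction.
    """
    i_ops = 0.17
    i_pps = i_ops / 3.0
    i_src = 0.10
    i_free = 1.0 - 0.005 - i_ops - i_pps - i_src
    return (
        DecayComponent("p-Ps", 0.125, i_pps),
        DecayComponent("source", 0.374, i_src),
        DecayComponent("free", 0.395, i_free),
        DecayComponent("o-Ps", 1.8, i_ops),
    )


@dataclass(frozen=True)
class SpectrumModel:
    """Generative model of a binned PALS spectrum.

    Parameters
    ----------
    components
        Decay channels with lifetimes [ns] and intensities (event fractions).
    t0
        Time-zero offset of the spectrometer [ns].
    resolution
        Gaussian timing response.
    background_fraction
        Fraction of events uniformly distributed over ``window`` (accidental
        coincidences).  Component intensities plus background must sum to 1.
    window
        ``(t_min, t_max)`` measurement window [ns]; must bracket ``t0``.
    n_events
        Total number of coincidence events.
    """

    components: Tuple[DecayComponent, ...] = field(default_factory=default_components)
    t0: float = 0.0
    resolution: ResolutionFunction = field(default_factory=ResolutionFunction)
    background_fraction: float = 0.005
    window: Tuple[float, float] = (-2.0, 25.0)
    n_events: int = 1_000_000

    def __post_init__(self) -> None:
        object.__setattr__(self, "components", tuple(self.components))
        object.__setattr__(self, "window", (float(self.window[0]), float(self.window[1])))
        if not 0.0 <= self.background_fraction <= 1.0:
            raise ValueError(
                f"background_fraction must be in [0, 1], got {self.background_fraction}"
            )
        total = sum(c.intensity for c in self.components) + self.background_fraction
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"component intensities + background must sum to 1, got {total:.12f}"
            )
        t_min, t_max = self.window
        if not t_min < self.t0 < t_max:
            raise ValueError(
                f"window {self.window} must strictly bracket t0 = {self.t0}"
            )
        if not int(self.n_events) >= 1:
            raise ValueError(f"n_events must be a positive integer, got {self.n_events}")

    def with_updates(self, **kwargs) -> "SpectrumModel":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    def intensity_of(self, label: str) -> float:
        return self.component(label).intensity

    def component(self, label: str) -> DecayComponent:
        for c in self.components:
            if c.label == label:
                return c
        raise KeyError(f"no component labelled {label!r}")


@dataclass(frozen=True)
class LifetimeHistogram:
    """Binned coincidence lifetime spectrum.

    ``bin_edges`` are strictly increasing and uniformly spaced times [ns];
    ``counts`` are the non-negative integer event counts per bin.
    ``metadata`` carries free-form provenance (seed, generating model, ...).
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    metadata: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        counts = np.asarray(self.counts)
        if edges.ndim != 1 or edges.size < 2:
            raise ValueError("bin_edges must be a 1-D array of at least two times")
        widths = np.diff(edges)
        if np.any(widths <= 0):
            raise ValueError("bin_edges must be strictly increasing")
        width = widths[0]
        if np.any(np.abs(widths - width) > max(1e-12, 1e-9 * width)):
            raise ValueError("bin widths must be uniform")
        if counts.ndim != 1 or counts.size != edges.size - 1:
            raise ValueError("counts must have length len(bin_edges) - 1")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(counts.dtype, np.integer):
            rounded = np.rint(np.asarray(counts, dtype=float))
            if np.any(np.abs(counts - rounded) > 1e-9):
                raise ValueError("counts must be integers")
            counts = rounded.astype(np.int64)
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "counts", counts.astype(np.int64))
        object.__setattr__(self, "metadata", dict(self.metadata))

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def n_events(self) -> int:
        return int(self.counts.sum())


def _check_emg_args(lifetime: float, sigma: float) -> None:
    if not lifetime > 0:
        raise ValueError(f"lifetime must be > 0 ns, got {lifetime}")
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0 ns, got {sigma}")


def emg_density(t, lifetime: float, t0: float = 0.0, sigma: float = 0.0):
    """Exponentially modified Gaussian density [1/ns].

    The convolution of a one-sided exponential decay with mean lifetime
    ``lifetime`` starting at ``t0`` with a centred Gaussian of standard
    deviation ``sigma``::

        f(t) = 1/(2 tau) * exp(sigma^2/(2 tau^2) - (t - t0)/tau)
                         * erfc((sigma/tau - (t - t0)/sigma) / sqrt(2))

    Evaluated through the scaled complementary error function where the
    textbook form would overflow (short lifetimes comparable to the timing
    resolution), so it is stable for ``sigma/lifetime`` well beyond 10.
    ``sigma = 0`` returns the pure one-sided exponential.
    """
    _check_emg_args(lifetime, sigma)
    t = np.asarray(t, dtype=float)
    u = t - t0
    tau = float(lifetime)
    if sigma == 0.0:
        out = np.where(u >= 0.0, np.exp(-np.maximum(u, 0.0) / tau) / tau, 0.0)
        return out if out.ndim else float(out)

    z = sigma / tau - u / sigma
    out = np.empty_like(u)
    # z >= 0: naive exponent sigma^2/(2 tau^2) - u/tau can overflow; rewrite
    # with erfcx so the only exponential is the Gaussian factor.
    pos = z >= 0.0
    out[pos] = (
        0.5 / tau * special.erfcx(z[pos] / _SQRT2) * np.exp(-0.5 * (u[pos] / sigma) ** 2)
    )
    neg = ~pos
    out[neg] = (
        0.5
        / tau
        * np.exp(0.5 * (sigma / tau) ** 2 - u[neg] / tau)
        * special.erfc(z[neg] / _SQRT2)
    )
    return out if out.ndim else float(out)


def emg_cdf(t, lifetime: float, t0: float = 0.0, sigma: float = 0.0):
    """Cumulative distribution of the exponentially modified Gaussian.

    Uses the identity ``F(t) = Phi((t - t0)/sigma) - tau * f(t)`` where ``f``
    is the stable :func:`emg_density`, which keeps the result accurate in
    both tails.  Monotone non-decreasing from 0 to 1.
    """
    _check_emg_args(lifetime, sigma)
    t = np.asarray(t, dtype=float)
    u = t - t0
    tau = float(lifetime)
    if sigma == 0.0:
        out = np.where(u >= 0.0, -np.expm1(-np.maximum(u, 0.0) / tau), 0.0)
        return out if out.ndim else float(out)
    out = special.ndtr(u / sigma) - tau * np.asarray(
        emg_density(t, lifetime, t0, sigma)
    )
    out = np.clip(out, 0.0, 1.0)
    return out if out.ndim else float(out)


def default_edges(
    window: Tuple[float, float] = (-2.0, 25.0), bin_width: float = 0.025
) -> np.ndarray:
    """Uniform bin edges spanning ``window`` with the given width [ns]."""
    t_min, t_max = window
    n_bins = int(round((t_max - t_min) / bin_width))
    return t_min + bin_width * np.arange(n_bins + 1)


def expected_counts(model: SpectrumModel, bin_edges: Sequence[float]) -> np.ndarray:
    """Expected event counts per histogram bin under ``model``.

    Per-bin expectations are exact CDF differences (not midpoint density
    times width), so fits are insensitive to binning.  The flat background
    contributes in proportion to each bin's overlap with the model window.
    The total over a window-covering histogram is at most ``n_events``
    (decay mass can leak outside any finite window).
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be 1-D and strictly increasing")
    mass = np.zeros(edges.size - 1)
    for comp in model.components:
        if comp.intensity == 0.0:
            continue
        for fwhm, weight, shift in model.resolution.components:
            cdf = emg_cdf(edges, comp.lifetime, model.t0 + shift, fwhm * FWHM_TO_SIGMA)
            mass += comp.intensity * weight * np.diff(cdf)
    t_min, t_max = model.window
    if model.background_fraction > 0.0:
        overlap = np.clip(
            np.minimum(edges[1:], t_max) - np.maximum(edges[:-1], t_min), 0.0, None
        )
        mass += model.background_fraction * overlap / (t_max - t_min)
    return float(model.n_events) * mass
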