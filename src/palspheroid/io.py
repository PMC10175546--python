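"""File formats: ASCII lifetime histograms, YAML run configs, JSON results.

Histogram dialect: two tab-separated columns, bin *center* [ns] and integer
counts, preceded by ``#``-prefixed header lines.  Bin centers must be
uniformly spaced; edges are reconstructed from the centers.  A ``# metadata:
{...}`` header line carries JSON provenance and round-trips losslessly.
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path
from typing import Dict, Optional, Union

import numpy as np
import yaml

from . import __version__
from .fit import FitConstraints, FitResult
from .spectrum import (
    DecayComponent,
    LifetimeHistogram,
    ResolutionFunction,
    SpectrumModel,
)

__all__ = [
    "read_histogram",
    "write_histogram",
    "read_config",
    "write_config",
    "model_to_dict",
    "model_from_dict",
    "constraints_to_dict",
    "constraints_from_dict",
    "write_result",
    "read_result",
    "config_hash",
]

PathLike = Union[str, Path]


def write_histogram(hist: LifetimeHistogram, path: PathLike) -> None:
    """Write the two-column ASCII dialect with metadata headers."""
    path = Path(path)
    centers = hist.bin_centers
    lines = [
        "# palspheroid lifetime histogram",
        f"# bin_width_ns: {hist.bin_width!r}",
        f"# metadata: {json.dumps(hist.metadata, sort_keys=True)}",
    ]
    for c, k in zip(centers, hist.counts):
        lines.append(f"{float(c)!r}\t{int(k)}")
    path.write_text("\n".join(lines) + "\n")


def read_histogram(path: PathLike) -> LifetimeHistogram:
    """Parse the two-column ASCII dialect back into a histogram.

    Non-uniform centers and non-integer or negative counts are rejected
    with the offending row number.
    """
    path = Path(path)
    metadata: Dict[str, object] = {}
    centers = []
    counts = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.startswith("metadata:"):
                metadata = json.loads(body[len("metadata:") :].strip())
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 'center<TAB>counts'")
        centers.append(float(parts[0]))
        try:
            count = int(parts[1])
        except ValueError:
            raise ValueError(
                f"{path}:{lineno}: counts must be integers, got {parts[1]!r}"
            ) from None
        if count < 0:
            raise ValueError(f"{path}:{lineno}: counts must be non-negative")
        counts.append(count)
    if len(centers) < 2:
        raise ValueError(f"{path}: need at least two histogram rows")
    centers_arr = np.asarray(centers)
    diffs = np.diff(centers_arr)
    width = diffs[0]
    bad = np.nonzero(np.abs(diffs - width) > max(1e-9, 1e-6 * abs(width)))[0]
    if width <= 0 or bad.size:
        row = int(bad[0]) + 2 if bad.size else 2
        raise ValueError(
            f"{path}: bin centers are not uniformly spaced (first offending "
            f"data row {row})"
        )
    edges = np.concatenate([centers_arr - 0.5 * width, [centers_arr[-1] + 0.5 * width]])
    return LifetimeHistogram(edges, np.asarray(counts, dtype=np.int64), metadata)


# ---------------------------------------------------------------------------
# run configuration (YAML)


def model_to_dict(model: SpectrumModel) -> dict:
    res = model.resolution
    res_block: dict = (
        {"fwhm_ns": res.fwhm}
        if res.terms is None
        else {"terms": [list(t) for t in res.terms]}
    )
    return {
        "components": [
            {"label": c.label, "lifetime_ns": c.lifetime, "intensity": c.intensity}
            for c in model.components
        ],
        "t0_ns": model.t0,
        "resolution": res_block,
        "background_fraction": model.background_fraction,
        "window_ns": list(model.window),
        "n_events": int(model.n_events),
    }


def model_from_dict(data: dict) -> SpectrumModel:
    res_block = data.get("resolution", {})
    if "terms" in res_block:
        resolution = ResolutionFunction(terms=tuple(tuple(t) for t in res_block["terms"]))
    else:
        resolution = ResolutionFunction(fwhm=res_block.get("fwhm_ns", 0.25))
    return SpectrumModel(
        components=tuple(
            DecayComponent(c["label"], c["lifetime_ns"], c["intensity"])
            for c in data["components"]
        ),
        t0=data.get("t0_ns", 0.0),
        resolution=resolution,
        background_fraction=data.get("background_fraction", 0.0),
        window=tuple(data.get("window_ns", (-2.0, 25.0))),
        n_events=data.get("n_events", 1_000_000),
    )


def constraints_to_dict(constraints: FitConstraints) -> dict:
    return {
        "fixed_lifetimes": dict(constraints.fixed_lifetimes),
        "fixed_intensities": dict(constraints.fixed_intensities),
        "fit_t0": constraints.fit_t0,
        "fit_resolution": constraints.fit_resolution,
        "bounds": {k: list(v) for k, v in constraints.bounds.items()},
        "tied_intensities": {
            k: [src, fac] for k, (src, fac) in constraints.tied_intensities.items()
        },
    }


def constraints_from_dict(data: dict) -> FitConstraints:
    return FitConstraints(
        fixed_lifetimes=data.get("fixed_lifetimes", {}),
        fixed_intensities=data.get("fixed_intensities", {}),
        fit_t0=data.get("fit_t0", True),
        fit_resolution=data.get("fit_resolution", False),
        bounds={k: tuple(v) for k, v in data.get("bounds", {}).items()},
        tied_intensities={
            k: (v[0], v[1])
            for k, v in data.get(
                "tied_intensities", {"p-Ps": ["o-Ps", 1.0 / 3.0]}
            ).items()
        },
    )


def write_config(config: dict, path: PathLike) -> None:
    """Serialize a run config (model / constraints / simulation blocks)."""
    Path(path).write_text(yaml.safe_dump(config, sort_keys=True))


def read_config(path: PathLike) -> dict:
    return yaml.safe_load(Path(path).read_text())


def config_hash(config: dict) -> str:
    """Stable short hash of a run config for provenance records."""
    canon = json.dumps(config, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# fit results (JSON)


def write_result(
    result: FitResult,
    path: PathLike,
    input_path: Optional[str] = None,
    seed: Optional[int] = None,
    config: Optional[dict] = None,
) -> None:
    """Write a fit result as structured JSON with provenance."""
    payload = {
        "estimates": {k: float(v) for k, v in result.estimates.items()},
        "uncertainties": {k: float(v) for k, v in result.uncertainties.items()},
        "covariance": {
            "labels": list(result.param_names),
            "matrix": np.asarray(result.covariance).tolist(),
        },
        "statistic": {"cash": result.cash, "pearson_chi2": result.pearson_chi2},
        "ndf": result.ndf,
        "converged": result.converged,
        "n_events_fit": result.n_events_fit,
        "model": model_to_dict(result.model),
        "constraints": constraints_to_dict(result.constraints),
        "input_metadata": result.metadata,
        "provenance": {
            "input_path": input_path,
            "config_hash": config_hash(config) if config is not None else None,
            "seed": seed,
            "timestamp": datetime.now(timezone.utc).isoformat(),
            "package_version": __version__,
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_result(path: PathLike) -> dict:
    return json.loads(Path(path).read_text())
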