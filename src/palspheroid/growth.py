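"""Spheroid growth arithmetic: volumes, fold changes and doubling time.

Doubling time assumes exponential growth between two observations:

    DT = t * ln(2) / ln(V2 / V1)

with ``t`` the elapsed time between them.  A shrinking spheroid gives a
negative DT, returned as-is with a warning — the formula remains well
defined and callers may want to treat regression phases explicitly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GrowthRecord",
    "GrowthWarning",
    "doubling_time",
    "sphere_volume",
    "fold_change",
    "read_growth_csv",
    "spheroids_per_plate",
    "cells_per_well",
]


class GrowthWarning(UserWarning):
    """Raised (as a warning) for well-defined but unusual growth arithmetic."""


@dataclass(frozen=True)
class GrowthRecord:
    """One observation of a spheroid culture.

    At least one of volume [µm³], diameter [µm] or cell count must be
    present; ``time`` is days since seeding.
    """

    time: float
    volume: Optional[float] = None
    diameter: Optional[float] = None
    cell_count: Optional[float] = None

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"time must be >= 0 days, got {self.time}")
        quantities = {
            "volume": self.volume,
            "diameter": self.diameter,
            "cell_count": self.cell_count,
        }
        present = {k: v for k, v in quantities.items() if v is not None}
        if not present:
            raise ValueError("at least one of volume, diameter, cell_count required")
        for name, value in present.items():
            if not value > 0:
                raise ValueError(f"{name} must be > 0, got {value}")

    def get(self, quantity: str) -> Optional[float]:
        return getattr(self, quantity)


def doubling_time(v1: float, v2: float, t: float) -> float:
    """Exponential-growth doubling time ``t ln 2 / ln(v2/v1)`` [days].

    ``v1`` and ``v2`` are the quantity (volume, cell count, ...) at the start
    and end of an interval of length ``t`` days.  Negative for shrinkage
    (with a :class:`GrowthWarning`); ``v2 == v1`` is undefined and raises.
    """
    if not (v1 > 0 and v2 > 0):
        raise ValueError(f"quantities must be > 0, got v1={v1}, v2={v2}")
    if not t > 0:
        raise ValueError(f"elapsed time must be > 0 days, got {t}")
    if v2 == v1:
        raise ValueError("doubling time is undefined for v2 == v1 (no net growth)")
    dt = t * math.log(2.0) / math.log(v2 / v1)
    if dt < 0:
        warnings.warn(
            f"shrinkage over the interval (v2 < v1): doubling time {dt:.4g} d "
            "is negative",
            GrowthWarning,
            stacklevel=2,
        )
    return dt


def sphere_volume(diameter: float) -> float:
    """Volume [µm³] of a sphere of the given diameter [µm]: (π/6) d³."""
    if not diameter > 0:
        raise ValueError(f"diameter must be > 0, got {diameter}")
    return math.pi / 6.0 * diameter**3


def fold_change(
    series: Sequence[GrowthRecord], quantity: Optional[str] = None
) -> np.ndarray:
    """Per-time-point fold change of a growth series relative to its start.

    ``quantity`` selects volume / diameter / cell_count; by default the
    single quantity present in every record is used (mixed or ambiguous
    series raise).  The first entry is exactly 1.
    """
    if not series:
        raise ValueError("series must be non-empty")
    times = [r.time for r in series]
    if any(b < a for a, b in zip(times, times[1:])):
        raise ValueError("series must be sorted by time")
    if quantity is None:
        candidates = [
            q
            for q in ("volume", "diameter", "cell_count")
            if all(r.get(q) is not None for r in series)
        ]
        if len(candidates) != 1:
            raise ValueError(
                "quantity is ambiguous or records are mixed; pass quantity= "
                f"explicitly (candidates: {candidates})"
            )
        quantity = candidates[0]
    values = [r.get(quantity) for r in series]
    if any(v is None for v in values):
        raise ValueError(f"not every record has {quantity!r}")
    values = np.asarray(values, dtype=float)
    folds = values / values[0]
    folds[0] = 1.0
    return folds


def read_growth_csv(path) -> List[GrowthRecord]:
    """Read a growth series CSV with columns ``time_days`` and at least one
    of ``volume_um3``, ``diameter_um``, ``cell_count``."""
    frame = pd.read_csv(path)
    if "time_days" not in frame.columns:
        raise ValueError("growth CSV must have a time_days column")
    records = []
    for _, row in frame.iterrows():
        records.append(
            GrowthRecord(
                time=float(row["time_days"]),
                volume=float(row["volume_um3"]) if "volume_um3" in frame else None,
                diameter=float(row["diameter_um"]) if "diameter_um" in frame else None,
                cell_count=float(row["cell_count"]) if "cell_count" in frame else None,
            )
        )
    return records


def spheroids_per_plate(n_wells: int = 12, cavities_per_well: int = 750) -> int:
    """Spheroids grown per plate: forming wells times microcavities per well."""
    if n_wells < 1 or cavities_per_well < 1:
        raise ValueError("counts must be positive")
    return n_wells * cavities_per_well


def cells_per_well(cells_per_cavity: int = 1500, cavities_per_well: int = 750) -> int:
    """Cells seeded per well: cells per microcavity times cavities per well."""
    if cells_per_cavity < 1 or cavities_per_well < 1:
        raise ValueError("counts must be positive")
    return cells_per_cavity * cavities_per_well
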