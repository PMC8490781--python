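"""Diameters, ellipsoid volumes, progression deltas, cohort summaries and
RMSE validation of registration parameters.

Volume convention
-----------------
The ellipsoid-from-diameters volume is ``L * W * H * pi/6`` (the ``classic``
convention, ~0.5236 L*W*H, and the default).  A second convention,
``printed``-style ``L * W * H * 0.52 / (pi/6)`` (~0.9931 L*W*H), is kept
behind a flag because some published tumour-volume tables print the formula
that way; every report states which convention produced its numbers.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from statistics import median

log = logging.getLogger(__name__)

__all__ = [
    "RoiMeasurement",
    "ProgressionRecord",
    "RmseReport",
    "ellipsoid_volume",
    "progression",
    "diameter_delta",
    "cohort_summary",
    "rmse",
]


@dataclass
class RoiMeasurement:
    """A segmented region's reported dimensions, all in cm."""

    length: float
    width: float
    height: float
    diameter: float
    volume: float
    timepoint: str  # {"t1", "t2"}
    method: str = "auto"  # {"manual", "auto"}
    convention: str = "classic"

    def __post_init__(self) -> None:
        for name in ("length", "width", "height", "diameter", "volume"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class ProgressionRecord:
    """Per-patient interval change: dv = V(t2) - V(t1) in cm^3."""

    patient_id: str
    dv: float
    direction: str
    method: str = "auto"
    d_diameter_t1: float | None = None  # auto - manual, cm
    d_diameter_t2: float | None = None


@dataclass
class RmseReport:
    dtx_rmse: float  # mm
    dty_rmse: float  # mm
    n: int
    samples: list[tuple[float, float]] | None = None  # (predicted, observed)


def ellipsoid_volume(
    length: float, width: float, height: float, convention: str = "classic"
) -> float:
    """Ellipsoid volume from the three principal diameters (cm -> cm^3).

    ``classic``: V = L*W*H*pi/6, the standard ellipsoid-from-diameters
    formula.  ``printed``: V = L*W*H*0.52*6/pi, the literal form some tables
    print (almost certainly a typo for 0.52*L*W*H); net factor ~0.9931.
    """
    if min(length, width, height) < 0:
        raise ValueError("dimensions must be >= 0")
    if convention == "classic":
        return length * width * height * math.pi / 6.0
    if convention == "printed":
        return length * width * height * 0.52 / (math.pi / 6.0)
    raise ValueError(f"unknown convention {convention!r}")


def progression(v_t1: float, v_t2: float) -> tuple[float, str]:
    """Interval volume change dV = V(t2) - V(t1) and its direction label."""
    if v_t1 < 0 or v_t2 < 0:
        raise ValueError("volumes must be >= 0")
    dv = v_t2 - v_t1
    direction = "progression" if dv > 0 else ("stable" if dv == 0 else "regression")
    return dv, direction


def diameter_delta(manual: float, auto: float) -> float:
    """Automated minus manual diameter (cm); negative means the automated
    reading is smaller."""
    if manual < 0 or auto < 0:
        raise ValueError("diameters must be >= 0")
    return auto - manual


def _mad(values: list[float]) -> float:
    m = median(values)
    return median([abs(v - m) for v in values])


def cohort_summary(records: list[ProgressionRecord]) -> dict[str, float]:
    """Cohort statistics of the per-patient volume changes.

    Returns the median dV per method (midpoint rule for even n) plus the
    overall min, max and median absolute deviation.  Dispersion is
    reported as MAD rather than a parenthesised +/- figure, whose defining
    statistic is ambiguous in clinical tables.
    """
    if not records:
        raise ValueError("cohort_summary requires at least one record")
    out: dict[str, float] = {}
    for method in sorted({r.method for r in records}):
        dvs = [r.dv for r in records if r.method == method]
        out[f"median_dv_{method}"] = median(dvs)
        out[f"mad_dv_{method}"] = _mad(dvs)
    all_dv = [r.dv for r in records]
    out["min_dv"] = min(all_dv)
    out["max_dv"] = max(all_dv)
    return out


def rmse(predicted: list[float], observed: list[float]) -> float:
    """Root mean square error between predicted and observed values."""
    if len(predicted) != len(observed):
        raise ValueError(
            f"length mismatch: {len(predicted)} predicted vs {len(observed)} observed"
        )
    if not predicted:
        raise ValueError("rmse requires at least one sample")
    return math.sqrt(
        sum((p - o) ** 2 for p, o in zip(predicted, observed)) / len(predicted)
    )
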