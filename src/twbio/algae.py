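"""Microalgal physiology: photosynthetic efficiency recovery and
removal/production efficiencies.

Fv/Fm (the quantum efficiency of Photosystem II from dark-adapted
chlorophyll fluorescence) is used as a stress proxy for cultures grown
on wastewater versus a paired control on synthetic medium.  The
relative efficiency Fv/Fm% expresses the culture as a percentage of its
control; a culture is considered recovered once it first exceeds 75% of
the control, with linear interpolation between measurement times.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "NOT_REACHED",
    "PhotoTrajectory",
    "RecoveryResult",
    "relative_efficiency",
    "recovery_time",
    "efficiency",
]

#: sentinel for a recovery threshold never crossed
NOT_REACHED = math.inf


@dataclass
class PhotoTrajectory:
    """Fv/Fm time series for one culture."""

    culture_id: str
    times: np.ndarray
    fvfm: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.fvfm = np.asarray(self.fvfm, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError(f"culture {self.culture_id!r}: times must be strictly increasing")
        if np.any((self.fvfm < 0) | (self.fvfm > 1)):
            raise ValueError(f"culture {self.culture_id!r}: Fv/Fm outside [0, 1]")


@dataclass
class RecoveryResult:
    """Relative-efficiency series and the interpolated recovery time."""

    times: np.ndarray
    relative_pct: np.ndarray
    recovery_time: float
    threshold: float = 75.0


def relative_efficiency(
    tw: PhotoTrajectory,
    control: PhotoTrajectory,
    mode: str = "ratio",
) -> np.ndarray:
    """Fv/Fm% of a wastewater culture relative to its control.

    ``mode='ratio'`` (default) returns 100 * Fv/Fm_TW / Fv/Fm_C — the
    "percent of control" convention under which 100% means unstressed
    and the >75% rule defines recovery.  ``mode='deficit'`` returns the
    complementary loss, 100 * (Fv/Fm_C - Fv/Fm_TW) / Fv/Fm_C.  Control
    values are linearly interpolated onto the culture's time grid when
    the grids differ; a zero control value makes the ratio undefined
    (NaN) at that point.
    """
    if mode not in ("ratio", "deficit"):
        raise ValueError(f"mode must be 'ratio' or 'deficit', got {mode!r}")
    ctrl = np.interp(tw.times, control.times, control.fvfm)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(ctrl > 0, 100.0 * tw.fvfm / ctrl, np.nan)
    return ratio if mode == "ratio" else 100.0 - ratio


def recovery_time(
    times: np.ndarray,
    relative_pct: np.ndarray,
    threshold: float = 75.0,
    from_minimum: bool = False,
) -> float:
    """Smallest time at which Fv/Fm% reaches the threshold.

    The measured series is linearly interpolated between consecutive
    points; returns 0 if the series already meets the threshold at the
    first observation, and :data:`NOT_REACHED` (infinity) if it never
    does.  ``from_minimum=True`` restricts the search to times at or
    after the series minimum — useful when the trajectory starts at the
    unstressed 100% before the shock sets in, so that the reported time
    is the recovery from the trough rather than the pre-stress level.
    """
    times = np.asarray(times, dtype=float)
    rel = np.asarray(relative_pct, dtype=float)
    if len(times) < 2:
        raise ValueError("recovery time needs at least 2 time points")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if from_minimum:
        i_min = int(np.argmin(rel))
        if i_min > 0:
            times = times[i_min:]
            rel = rel[i_min:]
            if len(times) < 2:
                return 0.0 if rel[0] >= threshold else NOT_REACHED
    if rel[0] >= threshold:
        return 0.0
    for i in range(1, len(times)):
        if rel[i] >= threshold:
            # crossing inside (t[i-1], t[i]]; linear interpolation
            t0, t1 = times[i - 1], times[i]
            v0, v1 = rel[i - 1], rel[i]
            if v1 == v0:
                return float(t1)
            return float(t0 + (threshold - v0) / (v1 - v0) * (t1 - t0))
    return NOT_REACHED


def efficiency(initial: float, final: float, mode: str = "removal") -> float:
    """Removal or production efficiency (%) from first and last values.

    removal    = 100 * (initial - final) / initial   (e.g. eta-NH4-N)
    production = 100 * (final - initial) / initial   (e.g. eta-VSS)

    The production mode is sign-corrected so that growth reports a
    positive percentage.
    """
    if initial <= 0:
        raise ValueError("efficiency undefined: initial value must be positive")
    if mode == "removal":
        return 100.0 * (initial - final) / initial
    if mode == "production":
        return 100.0 * (final - initial) / initial
    raise ValueError(f"mode must be 'removal' or 'production', got {mode!r}")
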