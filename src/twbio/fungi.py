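"""Fungal decolorization and laccase quantification.

Colour removal of white-rot fungal cultures is tracked through the
three-wavelength colour index (OD sum at 445/540/660 nm) relative to the
day-0 baseline.  Laccase activity is quantified from ABTS oxidation
kinetics at 420 nm: the linear-region slope of absorbance vs time is
converted to International Units per litre of original sample
(1 IU = 1 umol ABTS oxidized per minute) using the molar extinction
coefficient eps420 = 36,000 M^-1 cm^-1 and the assay dilutions (the
1:1:1 sample:buffer:ABTS mix is a fixed x3 dilution on top of any
explicit pre-dilution).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .characterization import colour_index

__all__ = [
    "Censored",
    "parse_censored",
    "DecolorizationRecord",
    "AbtsKinetics",
    "colour_removal",
    "laccase_activity",
    "strain_summary",
]

#: ABTS molar extinction coefficient at 420 nm, M^-1 cm^-1
EPSILON_420 = 36000.0
#: 1:1:1 sample:buffer:substrate reaction mix dilutes the sample 3-fold
MIX_DILUTION = 3.0


@dataclass(frozen=True)
class Censored:
    """A value below a detection limit, e.g. laccase '<0.5 IU/L'.

    Displays verbatim and is excluded from means.
    """

    limit: float

    def __str__(self) -> str:
        return f"<{self.limit:g}"


def parse_censored(token) -> float | Censored | None:
    """Parse a table cell that may be numeric, '<limit' or NA."""
    if token is None or (isinstance(token, float) and math.isnan(token)):
        return None
    if isinstance(token, str):
        stripped = token.strip()
        if stripped in ("", "NA", "na"):
            return None
        if stripped.startswith("<"):
            return Censored(float(stripped[1:]))
        return float(stripped)
    return float(token)


@dataclass
class DecolorizationRecord:
    """One observation of a fungal culture on a wastewater sample."""

    strain: str
    sample_id: str
    day: float
    od445: float
    od540: float
    od660: float
    ph: float | None = None
    biomass_dw: float | None = None
    laccase: float | Censored | None = None

    def __post_init__(self) -> None:
        for od in (self.od445, self.od540, self.od660):
            if od < 0:
                raise ValueError(
                    f"{self.strain}/{self.sample_id} day {self.day}: negative OD"
                )

    @property
    def colour_index(self) -> float:
        return colour_index(self.od445, self.od540, self.od660)


@dataclass
class AbtsKinetics:
    """Absorbance-at-420-nm kinetics of one ABTS assay well."""

    t_min: np.ndarray
    a420: np.ndarray
    sample_dilution: float = 1.0
    path_cm: float = 0.5
    epsilon: float = EPSILON_420
    mix_dilution: float = MIX_DILUTION
    saturation_threshold: float = 3.5

    def __post_init__(self) -> None:
        self.t_min = np.asarray(self.t_min, dtype=float)
        self.a420 = np.asarray(self.a420, dtype=float)
        if len(self.t_min) < 2:
            raise ValueError("ABTS kinetics need at least 2 readings")
        if self.path_cm <= 0:
            raise ValueError("optical path must be positive")


def colour_removal(
    record: DecolorizationRecord,
    baseline: DecolorizationRecord,
) -> float:
    """Colour removal (%) of a record relative to the day-0 baseline.

    100 * (index_t0 - index_t) / index_t0; negative values (colour
    increase) are reported as such.
    """
    idx0 = baseline.colour_index
    if idx0 <= 0:
        raise ValueError(
            f"{baseline.strain}/{baseline.sample_id}: zero baseline colour index"
        )
    return 100.0 * (idx0 - record.colour_index) / idx0


def laccase_activity(kin: AbtsKinetics) -> float:
    """Laccase activity in IU per litre of original sample.

    IU/L = (dA420/dt [min^-1]) / (eps * path) * 1e6 * mix_dilution
           * sample_dilution

    The slope comes from ordinary least squares over the linear region
    (readings at or above the saturation threshold are excluded).  A
    non-positive slope reports zero activity with a warning.
    """
    keep = kin.a420 < kin.saturation_threshold
    if keep.sum() < 2:
        raise ValueError("fewer than 2 unsaturated ABTS readings")
    slope = stats.linregress(kin.t_min[keep], kin.a420[keep]).slope
    if slope < 0:
        warnings.warn("negative ABTS slope; reporting zero activity", stacklevel=2)
        return 0.0
    molar_per_min = slope / (kin.epsilon * kin.path_cm)
    return molar_per_min * 1e6 * kin.mix_dilution * kin.sample_dilution


def strain_summary(records: list[DecolorizationRecord]) -> pd.DataFrame:
    """Per-strain/sample/day table of colour removal and laccase.

    Colour removal is computed against each sample's earliest record;
    replicates (same strain, sample, day) are aggregated as mean +/- sd
    (sd is NaN for a single record).  Censored laccase values are
    excluded from means and surface in the ``laccase_censored`` count.
    """
    if not records:
        raise ValueError("no records to summarize")
    rows = []
    by_culture: dict[tuple[str, str], list[DecolorizationRecord]] = {}
    for rec in records:
        by_culture.setdefault((rec.strain, rec.sample_id), []).append(rec)
    for (strain, sample_id), recs in by_culture.items():
        recs = sorted(recs, key=lambda r: r.day)
        baseline = recs[0]
        by_day: dict[float, list[DecolorizationRecord]] = {}
        for rec in recs:
            by_day.setdefault(rec.day, []).append(rec)
        for day, day_recs in sorted(by_day.items()):
            removals = [colour_removal(r, baseline) for r in day_recs]
            lac = [r.laccase for r in day_recs if isinstance(r.laccase, (int, float))]
            censored = sum(isinstance(r.laccase, Censored) for r in day_recs)
            rows.append({
                "strain": strain,
                "sample_id": sample_id,
                "day": day,
                "n": len(day_recs),
                "colour_removal_mean": float(np.mean(removals)),
                "colour_removal_sd": float(np.std(removals, ddof=1)) if len(removals) > 1 else math.nan,
                "laccase_mean": float(np.mean(lac)) if lac else math.nan,
                "laccase_sd": float(np.std(lac, ddof=1)) if len(lac) > 1 else math.nan,
                "laccase_censored": censored,
            })
    return pd.DataFrame(rows)
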