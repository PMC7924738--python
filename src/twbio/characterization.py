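"""Wastewater characterization: sample records, summary statistics and
derived chemistry.

Handles tabular physicochemical characterization of textile wastewater
(TW) samples and the synthetic control media used in bioassays.  Derived
quantities follow standard practice in wastewater engineering:

* free ammonia (NH3-N) from the Anthonisen ammonium/ammonia equilibrium,
* a three-wavelength colour index (sum of optical densities at 445, 540
  and 660 nm of a filtered sample in a 1 cm cuvette),
* the soluble-COD to total-nitrogen ratio used to judge anammox
  suitability.

Below-detection measurements ("ND") are kept distinct from missing ones
("NA"): both are excluded from summary statistics, but only ND carries
the information that the analyte was sought and not found.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ND",
    "BelowDetection",
    "WastewaterSample",
    "read_sample_table",
    "summarize",
    "free_ammonia",
    "colour_index",
    "scod_n_ratio",
]


class BelowDetection:
    """Sentinel for a measurement below the instrument detection limit."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "ND"


#: module-level below-detection marker
ND = BelowDetection()

# Core physicochemical columns with their reporting units.  Element
# symbols are routed into the ``elements`` map; anything else raises a
# warning and is passed through as an element-like extra.
CORE_COLUMNS: dict[str, str] = {
    "pH": "unitless",
    "conductivity": "mS cm^-1",
    "turbidity": "FAU",
    "tn_n": "mg N L^-1",
    "nh4_n": "mg N L^-1",
    "nh3_n": "mg N L^-1",
    "no2_n": "mg N L^-1",
    "no3_n": "mg N L^-1",
    "po4_p": "mg P L^-1",
    "cod": "mg L^-1",
    "scod": "mg L^-1",
    "scod_n": "unitless",
    "tss": "mg L^-1",
    "vss": "mg L^-1",
    "colour_index": "OD sum (1 cm)",
}

#: elements reported in mg L^-1; the heavy metals below are in ug L^-1
ELEMENT_SYMBOLS = (
    "K", "Mg", "Ca", "Si", "Fe", "Na", "Zn", "Mn", "Mo", "Al",
    "Cr", "Ni", "Pb", "Cu", "Cd",
)
ELEMENT_UNITS: dict[str, str] = {
    sym: ("ug L^-1" if sym in ("Cr", "Ni", "Pb", "Cu", "Cd") else "mg L^-1")
    for sym in ELEMENT_SYMBOLS
}

#: non-numeric descriptor columns carried as metadata, never parsed
METADATA_COLUMNS = ("colour_note",)


@dataclass
class WastewaterSample:
    """One characterized effluent (or synthetic control medium).

    Concentrations are mg L^-1 unless noted; heavy-metal entries in
    ``elements`` (Cr, Ni, Pb, Cu, Cd) are ug L^-1.  Any field may be
    ``None`` (not measured) or :data:`ND` (below detection).
    """

    id: str
    pH: float | None = None
    conductivity: float | None = None
    turbidity: float | None = None
    tn_n: float | None = None
    nh4_n: float | None = None
    nh3_n: float | None = None
    no2_n: float | None = None
    no3_n: float | None = None
    po4_p: float | None = None
    cod: float | None = None
    scod: float | None = None
    scod_n: float | None = None
    tss: float | None = None
    vss: float | None = None
    colour_index: float | None = None
    colour_note: str | None = None
    elements: dict[str, float | BelowDetection | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pH is not None and not 0.0 <= self.pH <= 14.0:
            raise ValueError(f"sample {self.id!r}: pH {self.pH} outside [0, 14]")
        for name in ("conductivity", "turbidity", "tn_n", "nh4_n", "nh3_n",
                     "no2_n", "no3_n", "po4_p", "cod", "scod", "tss", "vss",
                     "colour_index"):
            value = getattr(self, name)
            if value is not None and not isinstance(value, BelowDetection) and value < 0:
                raise ValueError(
                    f"sample {self.id!r}: negative concentration in column {name!r}"
                )
        for sym, value in self.elements.items():
            if isinstance(value, (int, float)) and value < 0:
                raise ValueError(
                    f"sample {self.id!r}: negative concentration for element {sym!r}"
                )
        if _both_numbers(self.vss, self.tss) and self.vss > self.tss:
            raise ValueError(f"sample {self.id!r}: VSS ({self.vss}) exceeds TSS ({self.tss})")
        if _both_numbers(self.scod, self.cod) and self.scod > self.cod:
            raise ValueError(f"sample {self.id!r}: sCOD ({self.scod}) exceeds COD ({self.cod})")
        if _both_numbers(self.nh4_n, self.tn_n) and self.nh4_n > self.tn_n:
            raise ValueError(
                f"sample {self.id!r}: NH4-N ({self.nh4_n}) exceeds TN-N ({self.tn_n})"
            )

    def get(self, column: str) -> float | BelowDetection | None:
        """Look up a core column or an element by name."""
        if column in CORE_COLUMNS or column in METADATA_COLUMNS:
            return getattr(self, column)
        return self.elements.get(column)


def _both_numbers(a, b) -> bool:
    return isinstance(a, (int, float)) and isinstance(b, (int, float))


def _parse_cell(token) -> float | BelowDetection | None:
    if token is None or (isinstance(token, float) and math.isnan(token)):
        return None
    if isinstance(token, str):
        stripped = token.strip()
        if stripped in ("", "NA", "na", "n/a"):
            return None
        if stripped in ("ND", "nd") or stripped.startswith("<"):
            return ND
        return float(stripped)
    return float(token)


def read_sample_table(path) -> list[WastewaterSample]:
    """Read a CSV/TSV characterization table into sample records.

    One row per sample; the header names recognized columns (see
    ``CORE_COLUMNS``) and element symbols.  ``ND`` marks below-detection,
    ``NA`` or an empty cell marks not-measured.  Unknown columns raise a
    warning and are passed through into the ``elements`` map; negative
    concentrations raise a validation error naming row and column.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str,
                     keep_default_na=False)
    if "id" not in df.columns:
        raise ValueError("sample table must have an 'id' column")
    samples: list[WastewaterSample] = []
    for _, row in df.iterrows():
        kwargs: dict = {"id": str(row["id"])}
        elements: dict[str, float | BelowDetection | None] = {}
        for col in df.columns:
            if col == "id":
                continue
            if col in METADATA_COLUMNS:
                value = row[col].strip() if isinstance(row[col], str) else row[col]
                kwargs[col] = value or None
                continue
            parsed = _parse_cell(row[col])
            if col in CORE_COLUMNS:
                kwargs[col] = parsed
            elif col in ELEMENT_SYMBOLS:
                elements[col] = parsed
            else:
                warnings.warn(
                    f"unknown column {col!r}; carried in the elements map",
                    stacklevel=2,
                )
                elements[col] = parsed
        samples.append(WastewaterSample(elements=elements, **kwargs))
    return samples


def summarize(
    samples: Sequence[WastewaterSample],
    columns: Iterable[str],
) -> pd.DataFrame:
    """Per-column mean, sample SD (n-1 denominator) and CV (%).

    NA and below-detection entries are dropped before computing; the
    ``n`` column reports how many values each statistic used.  Columns
    with fewer than two values report SD and CV as NaN.  Statistics are
    meant to be taken over the wastewater samples only — exclude control
    media before calling.
    """
    if len(samples) == 0:
        raise ValueError("summarize requires at least one sample")
    rows = {}
    for col in columns:
        values = np.array(
            [s.get(col) for s in samples
             if isinstance(s.get(col), (int, float))],
            dtype=float,
        )
        n = len(values)
        mean = float(values.mean()) if n else math.nan
        sd = float(values.std(ddof=1)) if n >= 2 else math.nan
        if n >= 2 and mean != 0:
            cv = 100.0 * sd / mean
        elif n >= 2 and sd == 0:
            cv = 0.0
        else:
            cv = math.nan
        rows[col] = {"mean": mean, "sd": sd, "cv": cv, "n": n}
    return pd.DataFrame(rows).T[["mean", "sd", "cv", "n"]]


def free_ammonia(nh4_n: float, pH: float, temperature_c: float = 20.0) -> float:
    """Free ammonia nitrogen (mg NH3-N L^-1) from total ammoniacal N.

    Anthonisen equilibrium::

        NH3-N = NH4-N * 10**pH / (exp(6344 / (273 + T)) + 10**pH)

    with T in degrees Celsius.  The un-ionized fraction increases with
    both pH and temperature.  The default 20 degC reflects ambient
    sample-characterization conditions.
    """
    if not 0.0 <= pH <= 14.0:
        raise ValueError(f"pH {pH} outside [0, 14]")
    if not 0.0 < temperature_c < 60.0:
        raise ValueError(f"temperature {temperature_c} degC outside (0, 60)")
    if nh4_n < 0:
        raise ValueError("nh4_n must be non-negative")
    ka = math.exp(6344.0 / (273.0 + temperature_c))
    return nh4_n * 10.0 ** pH / (ka + 10.0 ** pH)


def colour_index(od445: float, od540: float, od660: float) -> float:
    """Total colour of a filtered sample: sum of OD at 445/540/660 nm."""
    for od in (od445, od540, od660):
        if od < 0:
            raise ValueError("optical densities must be non-negative")
    return od445 + od540 + od660


def scod_n_ratio(sample: WastewaterSample) -> float:
    """Soluble COD to total nitrogen ratio, rounded to one decimal.

    A high sCOD/N favours heterotrophic denitrifiers over anammox, so
    this ratio is the standard first screen for anammox suitability.
    """
    if not isinstance(sample.tn_n, (int, float)) or sample.tn_n <= 0:
        raise ValueError(f"sample {sample.id!r}: sCOD/N undefined (TN-N not positive)")
    if not isinstance(sample.scod, (int, float)):
        raise ValueError(f"sample {sample.id!r}: sCOD not available")
    return round(sample.scod / sample.tn_n, 1)
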