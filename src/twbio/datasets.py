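"""Bundled study tables: wastewater characterization, element
distribution, microalgal outcomes and fungal summaries.

These small CSVs transcribe the monitoring-campaign tables for seven
weekly textile-wastewater samples (TW1-TW7) plus the two synthetic
control media (SM for the anammox assay, MBBM for the microalgae).
Loaders return pandas DataFrames with below-detection entries ('ND',
'<limit') as NaN unless noted; :func:`tw_samples` merges the two
characterization tables into validated sample records.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .characterization import WastewaterSample, read_sample_table
from .fungi import parse_censored

__all__ = [
    "load_characterization",
    "load_elements",
    "load_algae_outcomes",
    "load_fungal_summary",
    "tw_samples",
    "TW_IDS",
]

TW_IDS = tuple(f"TW{i}" for i in range(1, 8))


def _data_path(name: str):
    return resources.files("twbio.data").joinpath(name)


def load_characterization() -> pd.DataFrame:
    """Physicochemical characterization (pH ... colour index), all media."""
    df = pd.read_csv(_data_path("characterization.csv"), na_values=["NA", "ND"])
    return df.set_index("id")


def load_elements() -> pd.DataFrame:
    """Element concentrations; majors in mg/L, Cr/Ni/Pb/Cu/Cd in ug/L."""
    df = pd.read_csv(_data_path("elements.csv"), na_values=["NA", "ND"])
    return df.set_index("id")


def load_algae_outcomes() -> pd.DataFrame:
    """End-of-test VSS (mg/L, day 15) and ammonium removal (%) per culture."""
    return pd.read_csv(_data_path("algae_outcomes.csv")).set_index("culture_id")


def load_fungal_summary(strain: str = "pleurotus", censored_as_nan: bool = True) -> pd.DataFrame:
    """Per-sample fungal outcomes: biomass, pH, laccase and colour removal
    at 5/10/14 days (mean and sd columns).

    ``strain`` is 'pleurotus' or 'phanerochaete'.  Laccase cells below
    the 0.5 IU/L detection limit are NaN by default; with
    ``censored_as_nan=False`` they are :class:`~twbio.fungi.Censored`
    objects displaying verbatim.
    """
    if strain not in ("pleurotus", "phanerochaete"):
        raise ValueError(f"unknown strain {strain!r}")
    df = pd.read_csv(_data_path(f"{strain}.csv"), dtype=str).set_index("sample_id")
    out = {}
    for col in df.columns:
        parsed = [parse_censored(v) for v in df[col]]
        if censored_as_nan:
            parsed = [v if isinstance(v, (int, float)) else np.nan for v in parsed]
        out[col] = parsed
    result = pd.DataFrame(out, index=df.index)
    if censored_as_nan:
        result = result.astype(float)
    return result


def tw_samples(include_controls: bool = False) -> list[WastewaterSample]:
    """Validated sample records merging characterization and elements."""
    with resources.as_file(_data_path("characterization.csv")) as p:
        samples = read_sample_table(p)
    elements = load_elements()
    by_id = {s.id: s for s in samples}
    for sid, row in elements.iterrows():
        if sid in by_id:
            by_id[sid].elements.update(
                {sym: (None if pd.isna(v) else float(v)) for sym, v in row.items()}
            )
    if not include_controls:
        samples = [s for s in samples if s.id in TW_IDS]
    return samples
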