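"""Manometric anammox activity: pressure traces to SAA^max.

Sealed-bottle respirometry (OxiTop-style) measures anammox activity as
headspace overpressure from N2 release after a nitrite spike.  The
reduction chain is:

1. overpressure P(t) -> cumulative moles of N2 via the ideal gas law,
2. a continuous two-phase (one-breakpoint) linear fit separating the
   early slope m1 (anammox + denitrification, nitrite present) from the
   late slope m2 (denitrification only, nitrite exhausted),
3. the maximum specific anammox activity

       SAA^max [g N2-N / gVS / d] = (m1 - m2) * 28 * 24 / M_VS

   where 28 g/mol is the nitrogen mass per mole of N2, 24 converts
   per-hour slopes to per-day, and M_VS is the volatile-solids mass of
   the granular inoculum.

A two-way ANOVA helper tests sample and spike effects across replicate
bottles.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "R_ATM",
    "HPA_PER_ATM",
    "Spike",
    "PressureTrace",
    "GasProductionCurve",
    "TwoPhaseFit",
    "SAAResult",
    "pressure_to_moles",
    "fit_two_phase",
    "saa_max",
    "spike_comparison",
]

#: ideal gas constant, atm L mol^-1 K^-1
R_ATM = 0.08206
HPA_PER_ATM = 1013.25

#: grams of nitrogen per mole of N2
G_N_PER_MOL_N2 = 28.0
HOURS_PER_DAY = 24.0


@dataclass(frozen=True)
class Spike:
    """A nitrite injection event starting a new activity window."""

    time_h: float
    nitrite_mg_n: float


@dataclass
class PressureTrace:
    """Per-bottle manometric record.

    ``pressures`` are overpressures relative to the sealed baseline, in
    the declared ``unit`` ('hPa' or 'atm').  Defaults reflect a 335 mL
    bottle with 220 mL liquid (headspace 0.115 L), 30 degC incubation and
    0.3 g volatile solids of granular inoculum.
    """

    bottle_id: str
    sample_id: str
    times: np.ndarray
    pressures: np.ndarray
    unit: str
    v_hs: float = 0.115
    temperature_k: float = 303.15
    m_vs: float = 0.3
    spikes: list[Spike] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.pressures = np.asarray(self.pressures, dtype=float)
        if self.unit not in ("hPa", "atm"):
            raise ValueError(f"pressure unit must be 'hPa' or 'atm', got {self.unit!r}")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError(f"bottle {self.bottle_id!r}: times must be strictly increasing")
        if self.v_hs <= 0:
            raise ValueError("headspace volume must be positive")
        if self.temperature_k <= 273:
            raise ValueError("temperature must be above 273 K")
        if self.m_vs <= 0:
            raise ValueError("inoculum volatile solids must be positive")

    def window_mask(self, window: int) -> np.ndarray:
        """Boolean mask of points in the given spike window (0-based)."""
        if not self.spikes:
            raise ValueError("trace has no spikes")
        if not 0 <= window < len(self.spikes):
            raise IndexError(f"spike window {window} out of range")
        start = self.spikes[window].time_h
        end = self.spikes[window + 1].time_h if window + 1 < len(self.spikes) else math.inf
        return (self.times >= start) & (self.times < end)


@dataclass
class GasProductionCurve:
    """Cumulative moles of N2 in one spike window, zeroed at the start."""

    times: np.ndarray
    n_moles: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.n_moles = np.asarray(self.n_moles, dtype=float)
        if not np.all(np.isfinite(self.n_moles)):
            raise ValueError("gas production values must be finite")


@dataclass
class TwoPhaseFit:
    """Continuous piecewise-linear fit with one breakpoint."""

    m1: float
    m2: float
    breakpoint: float
    sse: float
    n_pre: int
    n_post: int
    no_breakpoint: bool = False


@dataclass
class SAAResult:
    """Specific anammox activity for one sample/spike, over replicate bottles."""

    sample_id: str
    spike_index: int
    per_bottle: list[float]
    negative_flag: bool = False

    @property
    def mean(self) -> float:
        return float(np.mean(self.per_bottle))

    @property
    def range(self) -> float:
        return float(np.max(self.per_bottle) - np.min(self.per_bottle))


def pressure_to_moles(trace: PressureTrace, window: int = 0) -> GasProductionCurve:
    """Convert one spike window of a pressure trace to moles of N2.

    n(t) = P(t) * V_HS / (R * T), with hPa converted to atm first; the
    curve is re-baselined so the first in-window reading is zero (the
    bottle is assumed vented to baseline at each spike).
    """
    mask = trace.window_mask(window)
    if mask.sum() < 4:
        raise ValueError(
            f"bottle {trace.bottle_id!r}: spike window {window} has fewer than 4 points"
        )
    p = trace.pressures[mask]
    if trace.unit == "hPa":
        p = p / HPA_PER_ATM
    n = p * trace.v_hs / (R_ATM * trace.temperature_k)
    return GasProductionCurve(times=trace.times[mask], n_moles=n - n[0])


def _segmented_sse(t: np.ndarray, y: np.ndarray, c: float):
    """Least-squares fit of y = b0 + m1*t + (m2-m1)*max(t-c, 0)."""
    hinge = np.maximum(t - c, 0.0)
    design = np.column_stack([np.ones_like(t), t, hinge])
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return float(resid @ resid), coef


def fit_two_phase(
    curve: GasProductionCurve,
    improvement_factor: float = 0.5,
    sse_atol: float = 1e-18,
) -> TwoPhaseFit:
    """Fit a continuous one-breakpoint piecewise line to a gas curve.

    The breakpoint is chosen by exhaustive search over interior
    candidate positions (observation times and midpoints, keeping at
    least two points strictly on each side), minimizing total SSE.  If
    the best two-phase fit does not shrink the SSE below
    ``improvement_factor`` times the single-line SSE — or the data are
    already perfectly linear — the fit degenerates to a single slope
    with ``no_breakpoint`` set.
    """
    t = curve.times
    y = curve.n_moles
    n = len(t)
    if n < 5:
        raise ValueError(f"two-phase fit needs at least 5 points, got {n}")

    design1 = np.column_stack([np.ones_like(t), t])
    coef1, _, _, _ = np.linalg.lstsq(design1, y, rcond=None)
    resid1 = y - design1 @ coef1
    sse1 = float(resid1 @ resid1)
    single = TwoPhaseFit(
        m1=float(coef1[1]), m2=float(coef1[1]), breakpoint=math.nan,
        sse=sse1, n_pre=n, n_post=0, no_breakpoint=True,
    )
    if sse1 < sse_atol:
        return single

    # candidate breakpoints: interior sample times and inter-sample
    # midpoints with >=2 points strictly on each side
    interior = t[2:-2]
    midpoints = 0.5 * (t[1:-2] + t[2:-1])
    candidates = np.unique(np.concatenate([interior, midpoints]))
    candidates = candidates[(candidates > t[1]) & (candidates < t[-2])]
    if candidates.size == 0:
        return single

    sses = np.array([_segmented_sse(t, y, c)[0] for c in candidates])
    i_best = int(np.argmin(sses))
    c = float(candidates[i_best])
    # continuous refinement between the neighbouring candidates: the true
    # kink rarely falls on an observation time
    lo = float(candidates[i_best - 1]) if i_best > 0 else float(t[1]) + 1e-12
    hi = float(candidates[i_best + 1]) if i_best + 1 < len(candidates) else float(t[-2]) - 1e-12
    if hi > lo:
        from scipy.optimize import minimize_scalar

        res = minimize_scalar(
            lambda cc: _segmented_sse(t, y, cc)[0],
            bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-10 * (t[-1] - t[0])},
        )
        if res.fun < sses[i_best]:
            c = float(res.x)
    sse2, coef2 = _segmented_sse(t, y, c)
    if sse2 >= improvement_factor * sse1:
        return single
    m1 = float(coef2[1])
    m2 = float(coef2[1] + coef2[2])
    return TwoPhaseFit(
        m1=m1, m2=m2, breakpoint=float(c), sse=sse2,
        n_pre=int(np.sum(t <= c)), n_post=int(np.sum(t > c)),
        no_breakpoint=False,
    )


def saa_max(fit: TwoPhaseFit, m_vs: float) -> float:
    """Maximum specific anammox activity, g N2-N per gVS per day.

    SAA = (m1 - m2) * 28 * 24 / M_VS.  A non-positive result (m1 <= m2)
    means no detectable anammox activity and is returned as-is for the
    caller to flag.
    """
    if m_vs <= 0:
        raise ValueError("volatile solids mass must be positive")
    return (fit.m1 - fit.m2) * G_N_PER_MOL_N2 * HOURS_PER_DAY / m_vs


def bottle_saa(trace: PressureTrace, window: int = 0, **fit_kwargs) -> float:
    """Full reduction for one bottle and spike window: trace -> SAA."""
    curve = pressure_to_moles(trace, window)
    fit = fit_two_phase(curve, **fit_kwargs)
    return saa_max(fit, trace.m_vs)


def spike_comparison(results: list[SAAResult]) -> pd.DataFrame:
    """Two-way ANOVA of SAA on sample and spike (replicates: bottles).

    Returns the statsmodels ANOVA table (sum_sq, df, F, PR(>F)) with
    rows for the sample factor, the spike factor and — when replication
    permits — their interaction.  With one bottle per cell the
    interaction is dropped with a warning (it would leave no residual
    degrees of freedom).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    rows = [
        {"sample": r.sample_id, "spike": str(r.spike_index), "saa": v}
        for r in results
        for v in r.per_bottle
    ]
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("no SAA results to compare")
    cells = df.groupby(["sample", "spike"]).size()
    n_cells = len(cells)
    formula = "saa ~ C(sample) + C(spike) + C(sample):C(spike)"
    if len(df) - 1 <= (n_cells - 1):
        warnings.warn(
            "single replicate per cell: interaction term dropped",
            stacklevel=2,
        )
        formula = "saa ~ C(sample) + C(spike)"
    model = smf.ols(formula, data=df).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        table = sm.stats.anova_lm(model, typ=2)
    if df["saa"].nunique() == 1:
        # a constant response carries no evidence for any effect: the F
        # ratio is 0/0 (undefined); report it as NaN with p = 1
        effects = table.index != "Residual"
        table.loc[effects, "F"] = math.nan
        table.loc[effects, "PR(>F)"] = 1.0
    return table
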