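"""Synthetic-data generators with known ground truth.

Every analysis stage in this package has a generator here that is its
measurable inverse: noiseless round-trips through the corresponding
reduction recover the configured truth exactly, and noisy round-trips
satisfy documented tolerance bounds.  The defaults emulate the study
conditions of the bioassays:

* characterization tables calibrated to the per-column mean/CV of the
  seven textile wastewater samples (log-normal draws for high-CV trace
  elements, zero-truncated normal elsewhere),
* two-phase N2-production pressure traces (anammox + denitrification
  slope until nitrite exhaustion, denitrification-only slope after),
* stress-dip-then-recovery Fv/Fm trajectories against a plateau control,
* first-order-like colour-decay records with an ABTS kinetics series
  tuned to a target laccase activity.

A single global seed fans out to per-stream substreams (SeedSequence
spawning), so adding a simulator never perturbs existing draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .algae import PhotoTrajectory
from .anammox import (
    G_N_PER_MOL_N2,
    HOURS_PER_DAY,
    HPA_PER_ATM,
    R_ATM,
    PressureTrace,
    Spike,
)
from .characterization import WastewaterSample, free_ammonia
from .fungi import AbtsKinetics, Censored, DecolorizationRecord

__all__ = [
    "CHARACTERIZATION_TARGETS",
    "TraceConfig",
    "FvfmConfig",
    "DecolorConfig",
    "SimulationConfig",
    "generate_characterization",
    "simulate_pressure_trace",
    "simulate_fvfm",
    "simulate_decolorization",
]

# per-column (mean, CV %, distribution) targets for the characterization
# generator, taken from the summary rows of the wastewater monitoring
# campaign; 'lognormal' for trace elements whose CVs reach 46-107%.
CHARACTERIZATION_TARGETS: dict[str, tuple[float, float, str]] = {
    "pH": (8.5, 2.0, "normal"),
    "conductivity": (2.61, 17.0, "normal"),
    "turbidity": (110.0, 53.0, "normal"),
    "tn_n": (196.0, 27.0, "normal"),
    "nh4_n": (161.0, 9.0, "normal"),
    "po4_p": (1.9, 5.0, "normal"),
    "cod": (799.0, 9.0, "normal"),
    "scod": (524.0, 10.0, "normal"),
    "tss": (122.0, 36.0, "normal"),
    "vss": (99.0, 34.0, "normal"),
    "colour_index": (0.214, 24.2, "normal"),
    "K": (3.9, 19.2, "normal"),
    "Mg": (6.7, 19.1, "normal"),
    "Ca": (30.9, 20.3, "normal"),
    "Si": (2.79, 107.48, "lognormal"),
    "Fe": (0.08, 45.96, "lognormal"),
    "Na": (258.0, 12.0, "normal"),
    "Zn": (0.08, 22.78, "normal"),
    "Mn": (0.012, 24.95, "normal"),
    "Al": (0.03, 7.35, "normal"),
    "Cr": (33.9, 84.4, "lognormal"),
    "Ni": (6.0, 76.3, "lognormal"),
    "Cu": (30.4, 55.7, "lognormal"),
}

_ELEMENT_COLUMNS = ("K", "Mg", "Ca", "Si", "Fe", "Na", "Zn", "Mn", "Al",
                    "Cr", "Ni", "Cu")


@dataclass(frozen=True)
class TraceConfig:
    """Ground truth for a manometric pressure trace.

    The nitrite dose (50 mg NO2-N L^-1 into 0.22 L of medium = 11 mg N)
    bounds the N2 the anammox phase can produce; the breakpoint falls
    where that yield is exhausted.  Per mole of N2 the anammox reaction
    consumes roughly 1.32/1.02 mol of nitrite-N.
    """

    saa_true: tuple[float, ...] = (0.1,)   # g N2-N gVS^-1 d^-1, per spike
    m2_mol_h: float = 1.0e-5               # denitrification-only slope
    nitrite_mg_n: float = 11.0             # per spike
    m_vs: float = 0.3                      # g volatile solids
    v_hs: float = 0.115                    # L headspace
    temperature_k: float = 303.15
    spike_times_h: tuple[float, ...] = (1.0,)
    window_h: float = 48.0                 # monitored span after the last spike;
                                           # two days covers nitrite exhaustion
                                           # at the lowest activities assayed
    interval_h: float = 0.5
    noise_sd_hpa: float = 0.0

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.saa_true) or self.m2_mol_h < 0:
            raise ValueError("true SAA and m2 must be non-negative")
        if len(self.saa_true) != len(self.spike_times_h):
            raise ValueError("one true SAA per spike required")

    @property
    def n2_yield_mol(self) -> float:
        """Moles of N2 the dosed nitrite supports in one spike window."""
        return self.nitrite_mg_n / 14.0 / 1000.0 * (1.02 / 1.32)

    def amx_rate_mol_h(self, spike: int = 0) -> float:
        return self.saa_true[spike] * self.m_vs / (G_N_PER_MOL_N2 * HOURS_PER_DAY)

    def breakpoint_h(self, spike: int = 0) -> float:
        """Time after the spike at which nitrite runs out (inf if SAA=0)."""
        rate = self.amx_rate_mol_h(spike)
        return self.n2_yield_mol / rate if rate > 0 else math.inf


@dataclass(frozen=True)
class FvfmConfig:
    """Shape of the stress-dip-then-recovery relative efficiency curve.

    Relative efficiency starts at 100%, falls linearly to ``trough_pct``
    at ``dip_time_h``, then rises linearly back to 100% at
    ``full_recovery_h`` (infinity = never recovers).  The closed-form
    crossing of a threshold is available via :meth:`true_recovery_time`.
    """

    control_level: float = 0.65
    trough_pct: float = 50.0
    dip_time_h: float = 24.0
    full_recovery_h: float = 72.0
    times_h: tuple[float, ...] = (0.0, 1.0, 24.0, 48.0, 72.0, 168.0, 336.0)
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.trough_pct <= 100.0:
            raise ValueError("trough must be in (0, 100]")
        if not 0.0 < self.control_level <= 1.0:
            raise ValueError("control Fv/Fm must be in (0, 1]")

    def relative_curve(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        rel = np.full_like(t, 100.0)
        dipping = t <= self.dip_time_h
        rel[dipping] = 100.0 + (self.trough_pct - 100.0) * t[dipping] / self.dip_time_h
        after = ~dipping
        if math.isinf(self.full_recovery_h):
            rel[after] = self.trough_pct
        else:
            frac = np.clip(
                (t[after] - self.dip_time_h)
                / (self.full_recovery_h - self.dip_time_h),
                0.0, 1.0,
            )
            rel[after] = self.trough_pct + (100.0 - self.trough_pct) * frac
        return rel

    def true_recovery_time(self, threshold: float = 75.0) -> float:
        if self.trough_pct >= threshold:
            return 0.0
        if math.isinf(self.full_recovery_h):
            return math.inf
        frac = (threshold - self.trough_pct) / (100.0 - self.trough_pct)
        return self.dip_time_h + frac * (self.full_recovery_h - self.dip_time_h)


@dataclass(frozen=True)
class DecolorConfig:
    """First-order-like colour decay with a laccase pulse that collapses."""

    strain: str = "P. ostreatus"
    sample_id: str = "SIM"
    initial_ods: tuple[float, float, float] = (0.10, 0.10, 0.09)
    removal_fraction: float = 0.62        # of the colour index, at the final day
    days: tuple[float, ...] = (0.0, 5.0, 10.0, 14.0)
    laccase_peak_iu: float = 350.0
    collapse_day: float = 14.0            # laccase below detection from here on
    detection_limit: float = 0.5
    biomass_dw: float = 9.5
    sample_dilution: float = 1.0
    path_cm: float = 0.5

    def __post_init__(self) -> None:
        if not -1.0 <= self.removal_fraction <= 1.0:
            raise ValueError("removal fraction must be in [-1, 1]")


@dataclass(frozen=True)
class SimulationConfig:
    """Master configuration fanning one seed out to every generator."""

    seed: int
    n_samples: int = 7
    trace: TraceConfig = field(default_factory=TraceConfig)
    fvfm: FvfmConfig = field(default_factory=FvfmConfig)
    decolor: DecolorConfig = field(default_factory=DecolorConfig)

    def substream(self, index: int) -> np.random.Generator:
        children = np.random.SeedSequence(self.seed).spawn(4)
        return np.random.default_rng(children[index])


def _draw_column(rng: np.random.Generator, mean: float, cv_pct: float,
                 dist: str, n: int) -> np.ndarray:
    if cv_pct < 0:
        raise ValueError("CV must be non-negative")
    if cv_pct == 0:
        return np.full(n, mean)
    sd = mean * cv_pct / 100.0
    if dist == "lognormal":
        sigma2 = math.log(1.0 + (cv_pct / 100.0) ** 2)
        mu = math.log(mean) - sigma2 / 2.0
        return rng.lognormal(mu, math.sqrt(sigma2), size=n)
    draws = rng.normal(mean, sd, size=n)
    while np.any(draws < 0):  # zero-truncation by rejection; mass is tiny here
        bad = draws < 0
        draws[bad] = rng.normal(mean, sd, size=bad.sum())
    return draws


def generate_characterization(
    seed: int | np.random.Generator,
    n_samples: int = 7,
    targets: dict[str, tuple[float, float, str]] | None = None,
    temperature_c: float = 20.0,
) -> list[WastewaterSample]:
    """Draw synthetic wastewater samples matching per-column mean/CV targets.

    Columns are drawn independently, then the physical order constraints
    (NH4-N <= TN-N, VSS <= TSS, sCOD <= COD) are enforced by clipping
    the dependent column; free ammonia is derived from the drawn NH4-N
    and pH via the Anthonisen formula.  Column means and CVs of a large
    draw converge to the targets (the clipped columns only within the
    constraint-violation mass, which is small at the defaults).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    targets = dict(CHARACTERIZATION_TARGETS if targets is None else targets)
    draws = {
        col: _draw_column(rng, mean, cv, dist, n_samples)
        for col, (mean, cv, dist) in targets.items()
    }
    samples = []
    for i in range(n_samples):
        row = {col: float(vals[i]) for col, vals in draws.items()}
        ph = min(max(row.get("pH", 7.0), 0.0), 14.0)
        tn = max(row.get("tn_n", 0.0), row.get("nh4_n", 0.0))
        tss = row.get("tss")
        vss = row.get("vss")
        if tss is not None and vss is not None:
            vss = min(vss, tss)
        cod = row.get("cod")
        scod = row.get("scod")
        if cod is not None and scod is not None:
            scod = min(scod, cod)
        nh4 = row.get("nh4_n", 0.0)
        samples.append(WastewaterSample(
            id=f"SIM_{i + 1}",
            pH=ph,
            conductivity=row.get("conductivity"),
            turbidity=row.get("turbidity"),
            tn_n=tn,
            nh4_n=nh4,
            nh3_n=free_ammonia(nh4, ph, temperature_c),
            po4_p=row.get("po4_p"),
            cod=cod,
            scod=scod,
            scod_n=round(scod / tn, 1) if scod is not None and tn > 0 else None,
            tss=tss,
            vss=vss,
            colour_index=row.get("colour_index"),
            elements={sym: row[sym] for sym in _ELEMENT_COLUMNS if sym in row},
        ))
    return samples


def simulate_pressure_trace(
    cfg: TraceConfig,
    seed: int | np.random.Generator = 0,
    bottle_id: str = "SIM-bottle",
    sample_id: str = "SIM",
) -> PressureTrace:
    """Generate a manometric trace from ground-truth kinetics.

    Within each spike window the cumulative N2 rises at
    ``SAA * M_VS / (28*24) + m2`` mol/h until the nitrite-limited yield
    is exhausted, then at ``m2`` alone; the inverse ideal-gas relation
    converts moles to overpressure (hPa), the bottle being vented to
    zero overpressure at each spike.  Gaussian noise is added per
    reading.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    spike_times = list(cfg.spike_times_h)
    all_t: list[np.ndarray] = []
    all_p: list[np.ndarray] = []
    for w, t_spike in enumerate(spike_times):
        end = spike_times[w + 1] if w + 1 < len(spike_times) else t_spike + cfg.window_h
        t_local = np.arange(0.0, end - t_spike - 1e-9, cfg.interval_h)
        rate1 = cfg.amx_rate_mol_h(w) + cfg.m2_mol_h
        t_break = cfg.breakpoint_h(w)
        n = np.where(
            t_local <= t_break,
            rate1 * t_local,
            rate1 * t_break + cfg.m2_mol_h * (t_local - t_break)
            if math.isfinite(t_break) else rate1 * t_local,
        )
        p_hpa = n * R_ATM * cfg.temperature_k / cfg.v_hs * HPA_PER_ATM
        if cfg.noise_sd_hpa > 0:
            p_hpa = p_hpa + rng.normal(0.0, cfg.noise_sd_hpa, size=p_hpa.shape)
        all_t.append(t_spike + t_local)
        all_p.append(p_hpa)
    return PressureTrace(
        bottle_id=bottle_id,
        sample_id=sample_id,
        times=np.concatenate(all_t),
        pressures=np.concatenate(all_p),
        unit="hPa",
        v_hs=cfg.v_hs,
        temperature_k=cfg.temperature_k,
        m_vs=cfg.m_vs,
        spikes=[Spike(t, cfg.nitrite_mg_n) for t in spike_times],
    )


def simulate_fvfm(
    cfg: FvfmConfig,
    seed: int | np.random.Generator = 0,
    culture_id: str = "SIM",
) -> tuple[PhotoTrajectory, PhotoTrajectory]:
    """Generate a (control, wastewater) Fv/Fm trajectory pair."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = np.asarray(cfg.times_h, dtype=float)
    control = np.full_like(t, cfg.control_level)
    tw = control * cfg.relative_curve(t) / 100.0
    if cfg.noise_sd > 0:
        tw = np.clip(tw + rng.normal(0.0, cfg.noise_sd, size=tw.shape), 0.0, 1.0)
    return (
        PhotoTrajectory(culture_id="control", times=t, fvfm=control),
        PhotoTrajectory(culture_id=culture_id, times=t, fvfm=tw),
    )


def simulate_decolorization(
    cfg: DecolorConfig,
    seed: int | np.random.Generator = 0,
) -> tuple[list[DecolorizationRecord], AbtsKinetics]:
    """Generate decolorization records plus an ABTS kinetics series.

    The colour index decays as initial * (1 - removal)**(t / t_final),
    hitting exactly (1 - removal) * initial at the final monitored day;
    all three OD channels share the decay factor.  The ABTS absorbance
    slope is set so that the laccase quantification returns the
    configured peak activity.
    """
    final_day = max(cfg.days)
    factor_base = 1.0 - cfg.removal_fraction
    records = []
    for day in cfg.days:
        decay = factor_base ** (day / final_day) if final_day > 0 else 1.0
        if day == 0:
            laccase = None
        elif day >= cfg.collapse_day:
            laccase = Censored(cfg.detection_limit)
        else:
            laccase = cfg.laccase_peak_iu
        records.append(DecolorizationRecord(
            strain=cfg.strain,
            sample_id=cfg.sample_id,
            day=day,
            od445=cfg.initial_ods[0] * decay,
            od540=cfg.initial_ods[1] * decay,
            od660=cfg.initial_ods[2] * decay,
            biomass_dw=cfg.biomass_dw if day == final_day else None,
            laccase=laccase,
        ))
    slope = (cfg.laccase_peak_iu / (1e6 * 3.0 * cfg.sample_dilution)
             * 36000.0 * cfg.path_cm)
    t_min = np.arange(0.0, 10.5, 1.0)
    kinetics = AbtsKinetics(
        t_min=t_min,
        a420=0.05 + slope * t_min,
        sample_dilution=cfg.sample_dilution,
        path_cm=cfg.path_cm,
    )
    return records, kinetics
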