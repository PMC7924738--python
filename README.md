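# twbio

Data reduction and statistical screening for textile-wastewater
treatability bioassays: anammox granular sludge (nitrogen removal),
*Chlorella vulgaris* (nutrient uptake and biomass production) and
white-rot fungi (*Pleurotus ostreatus*, *Phanerochaete chrysosporium*;
decolorization and laccase synthesis).

It is written for environmental bioprocess engineers who run desk-scale
batch assays against variable industrial effluents — here, seven weekly
composite samples (TW1–TW7) from a digital textile-printing plant — and
need the raw instrument traces reduced to comparable activity metrics and
screened against the effluent's physicochemical characteristics.

## What it computes

**Manometric anammox activity.** Sealed-bottle overpressure after a
nitrite spike is converted to cumulative N₂ via the ideal gas law,
n(t) = P(t)·V_HS / (R·T), and fitted with a continuous one-breakpoint
piecewise line separating the early slope m₁ (anammox + denitrification)
from the late slope m₂ (denitrification only, nitrite exhausted). The
maximum specific anammox activity is

    SAA^max [g N₂-N gVS⁻¹ d⁻¹] = (m₁ − m₂) · 28 · 24 / M_VS

**Microalgal photosynthetic recovery.** Fv/Fm (PSII quantum efficiency)
of wastewater cultures relative to a control, Fv/Fm% = 100·(Fv/Fm)_TW /
(Fv/Fm)_C; the recovery time is the smallest time at which the linearly
interpolated Fv/Fm% reaches 75%. Removal/production efficiencies
(ηNH₄-N, ηVSS, …) come from first and last observations.

**Fungal decolorization and laccase.** Colour is the OD sum at
445/540/660 nm (1 cm path, filtered sample); removal is relative to the
day-0 index. Laccase activity from ABTS oxidation kinetics at 420 nm:
IU L⁻¹ = (ΔA₄₂₀/min)/(ε₄₂₀·path) · 10⁶ · 3 · dilution, with
ε₄₂₀ = 36,000 M⁻¹ cm⁻¹ and the ×3 from the 1:1:1 reaction mix.

**Statistics for n = 7.** Free ammonia by the Anthonisen equilibrium
NH₃-N = NH₄-N·10^pH/(e^(6344/(273+T)) + 10^pH); per-column mean/SD
(n−1)/CV summaries; PCA on the standardized characterization table;
Spearman rank correlations with *exact* permutation p-values (all 5040
rank permutations at n = 7); and the AICc comparison of second-order
time-trend regressions (time-only vs sample-identity vs
characteristic-interaction models), a covariate being *relevant* when
its model beats the time-only model and sits within 4 AICc units of the
best.

**Synthetic data.** `twbio.simulate` generates every input with known
ground truth — two-phase pressure traces, dip-and-recover Fv/Fm pairs,
first-order colour decay with ABTS kinetics, and characterization tables
matching the campaign's per-column mean/CV — so the whole pipeline is
testable without instrument data.

## Worked example

```python
from twbio.simulate import TraceConfig, simulate_pressure_trace
from twbio.anammox import pressure_to_moles, fit_two_phase, saa_max

cfg = TraceConfig(saa_true=(0.1,), m2_mol_h=1e-5, noise_sd_hpa=2.0)
trace = simulate_pressure_trace(cfg, seed=42)
curve = pressure_to_moles(trace, window=0)
fit = fit_two_phase(curve)
print(f"m1 = {fit.m1:.3e} mol/h, m2 = {fit.m2:.3e} mol/h, "
      f"breakpoint = {fit.breakpoint:.1f} h")
print(f"SAA^max = {saa_max(fit, trace.m_vs):.4f} g N2-N/gVS/d")
```

prints

```
m1 = 5.489e-05 mol/h, m2 = 9.837e-06 mol/h, breakpoint = 14.6 h
SAA^max = 0.1009 g N2-N/gVS/d
```

— a bottle with 0.3 g VS of granules and a true activity of
0.1 g N₂-N gVS⁻¹ d⁻¹ produces N₂ at 5.5×10⁻⁵ mol h⁻¹ until the 11 mg of
spiked nitrite-N runs out near 14 h, after which only denitrification
(1×10⁻⁵ mol h⁻¹) continues; the slope difference recovers the activity
to within 1% despite 2 hPa reading noise.

The numbered scripts under `analysis/` run the full study:
characterization summaries and PCA (`01`), the anammox assay and its
parameter-recovery study (`02`), algal recovery times and efficiencies
(`03`), fungal decolorization/laccase (`04`) and the Spearman/AICc
screening battery (`05`). Each prints what it found and writes tidy CSVs
under `results/`.

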