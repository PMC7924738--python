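# Methods

## Scope and data model

The package reduces four desk-scale bioassay data streams to comparable
treatability metrics and screens them against effluent characteristics.
The study design it serves is small by construction: seven weekly
composite wastewater samples, duplicate bottles/flasks, and a handful of
monitoring times. All statistical choices below follow from that scale.

Characterized effluents are `WastewaterSample` records validated at
construction (pH in [0, 14], non-negative concentrations, VSS ≤ TSS,
sCOD ≤ COD, NH₄-N ≤ TN-N). Two kinds of missingness are kept distinct:
"not measured" (`None`/NA) and "sought but below the detection limit"
(`ND`, or `Censored(limit)` for values like laccase `<0.5` IU/L). Both
are excluded from summary statistics rather than substituted at half the
detection limit — the bundled tables' own summary rows are consistent
with exclusion, and at n = 7 any imputation rule would dominate the CV
of the censored columns.

## Wastewater chemistry

Free ammonia uses the Anthonisen ammonium/ammonia equilibrium,
NH₃-N = NH₄-N · 10^pH / (e^(6344/(273+T)) + 10^pH). The temperature at
which the bundled NH₃-N column was computed is not recorded with the
data; 20 °C reproduces the tabulated values for the samples checked
(e.g. 163 mg NH₄-N/L at pH 8.7 → 27 mg NH₃-N/L) where 25 °C does not,
so 20 °C is the default and the parameter is exposed.

Summary statistics use the sample standard deviation (n−1). This was
verified against the bundled turbidity column, whose printed SD (58) is
reproduced only with the n−1 denominator (the population form gives 53).
Not every printed summary cell recomputes exactly from the printed
per-sample rows (the originals were evidently computed from unrounded
instrument values, and the printed sCOD mean is inconsistent with its own
rows); the tests therefore assert the cells that do reproduce, at half
the last printed digit, and treat the rest at a documented looser bound.

The colour index is the plain sum of optical densities at 445, 540 and
660 nm of a filtered sample in a 1 cm cuvette — a ratio-scale quantity,
so colour *removal* is invariant to common rescaling of the three
channels but not to channel-wise recalibration.

## Anammox kinetics

`pressure_to_moles` applies the ideal gas law with
R = 0.08206 atm L mol⁻¹ K⁻¹ (hPa inputs divided by 1013.25), re-baselined
to zero at the first in-window reading: the bottles are assumed vented to
ambient at each nitrite spike, so each spike window is analysed
independently. Defaults describe the assay geometry: 0.115 L headspace
(335 mL bottle − 220 mL liquid), 303.15 K, 0.3 g VS of granular inoculum.

The two-phase decomposition is a continuous one-breakpoint least-squares
fit, y = b₀ + m₁t + (m₂−m₁)·max(t−c, 0). The breakpoint c is found by
exhaustive search over interior candidates (observation times and
midpoints, ≥2 points strictly on each side) followed by bounded
continuous refinement between the best candidate's neighbours — the true
kink generically falls between readings, and without refinement a
noiseless trace would not round-trip exactly. If the best two-phase fit
does not reduce the SSE below 0.5× the single-line SSE (configurable),
or the data are already exactly linear, the fit degenerates to a single
slope with a `no_breakpoint` flag; `saa_max` then returns 0, read as "no
detectable anammox activity". Negative SAA (m₁ < m₂) is returned as-is
for the caller to flag rather than clipped.

SAA^max = (m₁−m₂)·28·24/M_VS, the 28 g/mol being the nitrogen mass per
mole of N₂ (the activity is expressed as N₂-N).

The two-way ANOVA (`spike_comparison`) is an ordinary statsmodels
type-II table on sample and spike factors with bottles as replicates;
with one bottle per cell the interaction is dropped (no residual df) with
a warning, and an exactly constant response reports F = NaN, p = 1.

## Microalgal physiology

The relative efficiency defaults to the "percent of control" ratio
100·(Fv/Fm)_TW/(Fv/Fm)_C. The complementary deficit form
100·(C−TW)/C is retained as `mode="deficit"`; only the ratio convention
is consistent with a ">75% means recovered" rule, which is why it is the
default. Control trajectories are linearly interpolated onto the
culture's time grid when the grids differ; a zero control value yields
NaN at that point rather than an exception.

`recovery_time` interpolates linearly between measurements and returns
the smallest time at which the series reaches the threshold (≥ rather
than >, a measure-zero distinction under continuous interpolation), 0 if
the first observation already qualifies, and +inf if never. Because a
culture starts unstressed at ~100% of control before the shock sets in,
`from_minimum=True` restricts the search to times at or after the
observed trough; the default stays literal so the operator is exact on
already-windowed series. The threshold default is 75%.

Removal and production efficiencies use first/last observations only
(η = 100·(x₀−x_e)/x₀ for removal, sign-flipped for production so growth
is positive), not fitted trends — with two or three solids measurements
per flask a trend fit would be noise.

## Fungal decolorization and laccase

Laccase: IU L⁻¹ = (ΔA₄₂₀/min)/(ε₄₂₀·l) · 10⁶ · 3 · d, with
ε₄₂₀ = 36,000 M⁻¹ cm⁻¹ (the standard ABTS value), optical path l
defaulting to 0.5 cm — the microplate path is geometry-dependent and
activities scale inversely with it, so the parameter is mandatory in
reports — the fixed ×3 from the 1:1:1 sample:buffer:ABTS mix, and any
explicit pre-dilution d. The slope comes from OLS over the linear region;
readings at or above a configurable absorbance threshold (default 3.5)
are excluded as saturated, and a negative slope reports zero activity
with a warning.

## Statistical screening

*Spearman.* Mid-rank ties; ρ is the Pearson correlation of ranks. For
n ≤ 9 the two-sided p-value is exact: all n! permutations of the ranks
are enumerated (vectorised; 5040 at the study's n = 7) and compared at
|ρ_perm| ≥ |ρ_obs| − 1e−12, the tolerance guarding against ties in the
discrete null. Beyond n = 9 the usual t approximation applies. Each
metric/characteristic pair is tested separately with no multiplicity
correction — the screen is exploratory and every p-value is reported; a
Benjamini–Hochberg helper exists but is off by default.

*PCA.* Always on column-standardized data by default (the variables span
five orders of magnitude across units), i.e. the correlation matrix; SVD
implementation; constant columns dropped with a warning; deterministic
sign convention (largest-magnitude loading positive per component).
Variance explained sums to 100% over all components by construction.

*AICc.* AICc = n·ln(SSE/n) + 2k + 2k(k+1)/(n−k−1), k counting
coefficients plus the error variance; Gaussian constants are omitted as
they cancel in differences. The model family for a response y observed
over time across the seven samples: (1) y ~ a·y_tw + poly(t, 2);
(2) adds poly(t, 2):sample-identity; (3) adds poly(t, 2):x for one
continuous characteristic x. Time is centred and scaled before squaring
for conditioning; SSE and AICc are invariant to that basis change (and
to affine rescaling of x), which the tests assert. A characteristic is
*relevant* when its model's AICc is below the time-only model's and
within 4 units of the best; models leaving no residual df are excluded
with an `overfit` flag.

## Synthetic-data generators

Each generator is the measurable inverse of its analysis stage.

*Characterization* draws columns independently at the campaign's
mean/CV targets — log-normal (moment-matched: σ² = ln(1+CV²)) for trace
elements whose CVs reach 46–107%, zero-truncated normal (rejection)
elsewhere — then enforces the physical order constraints (NH₄ ≤ TN,
VSS ≤ TSS, sCOD ≤ COD) by clipping the dependent column. Clipping
slightly biases the clipped columns' marginals; the unclipped columns
converge to their targets (NH₄-N mean within 1% at n = 10,000, asserted).

*Pressure traces* rise at SAA·M_VS/(28·24) + m₂ mol h⁻¹ until the
nitrite-limited N₂ yield is exhausted, then at m₂; the yield takes
1.32/1.02 mol of NO₂-N per mole of N₂ (anammox stoichiometry) from the
11 mg N dose (50 mg N/L into 0.22 L). Moles convert back to hPa through
the same gas law; Gaussian noise (default studies use 2 hPa, the
instrument's resolution scale) is added per reading. Each spike window is
monitored for 48 h at 0.5 h intervals — two days covers nitrite
exhaustion at the lowest activities studied (0.05 g N gVS⁻¹ d⁻¹ breaks
at ≈27 h).

*Fv/Fm pairs* hold the control at a plateau (0.65) and shape the
wastewater culture's relative efficiency as piecewise-linear: 100% at
t = 0, trough at the dip time (defaults 50% at 24 h), linear return to
100% at the full-recovery time (inf = never). The threshold crossing is
then available in closed form for round-trip tests. This phenomenological
shape reproduces the recovery-time observable; it does not model
photophysiology.

*Decolorization* decays the colour index as
initial·(1−removal)^(t/t_final), exact at the final day, identical factor
on all three OD channels; the ABTS series is a straight line whose slope
inverts the laccase formula at the configured activity, with laccase
below detection from the configured collapse day.

A master `SimulationConfig` fans one seed into per-stream substreams via
`SeedSequence.spawn`, so adding a generator never perturbs existing
draws.

## Problem sizes and determinism

The simulation studies use 100 seeds/replicates for the SAA recovery and
AICc selection rates and 20 random pairs for the permutation-exactness
check — large enough for stable medians and rates at the configured
noise, small enough that the whole battery runs in well under a minute.
All stochastic entry points take either an integer seed or a
`numpy.random.Generator`; fixed seeds give bit-identical outputs.

## Limitations

- The two-phase fit assumes exactly one slope change per spike window; a
  gradual nitrite limitation (soft knee) biases the breakpoint but
  affects the slope difference only weakly.
- The generators are phenomenological: no Monod/Haldane kinetics, no
  inhibition, no CO₂ partitioning, no pigment-specific optics. Passing
  round-trip tests demonstrates the *reduction chain* is correct, not
  that real cultures follow these shapes.
- Exact permutation p-values are enumerated only to n = 9 (9! ≈ 3.6×10⁵
  permutations); larger screens fall back to the t approximation.
- With n = 7 samples the screening battery has low power and inflated
  discovery risk across many tests; it ranks hypotheses, it does not
  confirm them.
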