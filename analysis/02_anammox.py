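#!/usr/bin/env python
"""Manometric anammox assay in silico: duplicate bottles for seven
wastewater samples plus a control, two nitrite spikes each, reduced to
SAA^max and screened with a two-way ANOVA; then a parameter-recovery
study at instrument-level pressure noise.

Writes:
    results/saa.csv           per sample/spike SAA (replicate mean and range)
    results/saa_anova.csv     two-way ANOVA table (sample, spike)
    results/saa_recovery.csv  median relative error vs true SAA and noise
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from twbio.anammox import SAAResult, bottle_saa, spike_comparison
from twbio.simulate import TraceConfig, simulate_pressure_trace

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
args = parser.parse_args()
rng = np.random.default_rng(args.seed)

OUT = Path("results")
OUT.mkdir(exist_ok=True)

# ground truth: first-spike activities 0.06-0.09, roughly doubling at the
# second spike — the recovery pattern the assay is designed to detect
sample_ids = ["C"] + [f"TW{i}" for i in range(1, 8)]
truths = {sid: (0.06 + 0.03 * rng.random(),) for sid in sample_ids}
truths = {sid: (s1, 2.0 * s1 * (0.8 + 0.4 * rng.random()))
          for sid, (s1,) in truths.items()}

results = []
for sid, (s1, s2) in truths.items():
    for spike in (0, 1):
        per_bottle = []
        for bottle in range(2):
            cfg = TraceConfig(saa_true=(s1, s2), spike_times_h=(1.0, 49.0),
                              m2_mol_h=1e-5, noise_sd_hpa=2.0)
            trace = simulate_pressure_trace(
                cfg, seed=rng, bottle_id=f"{sid}-b{bottle}", sample_id=sid)
            per_bottle.append(bottle_saa(trace, spike))
        results.append(SAAResult(sid, spike + 1, per_bottle))

saa = pd.DataFrame([
    {"sample": r.sample_id, "spike": r.spike_index,
     "saa_mean": r.mean, "saa_range": r.range,
     "saa_true": truths[r.sample_id][r.spike_index - 1]}
    for r in results
])
saa.to_csv(OUT / "saa.csv", index=False)
lo, hi = saa.query("spike == 1").saa_mean.agg(["min", "max"])
lo2, hi2 = saa.query("spike == 2").saa_mean.agg(["min", "max"])
print(f"SAA^max spike 1: {lo:.3f}-{hi:.3f}; spike 2: {lo2:.3f}-{hi2:.3f} "
      "g N2-N/gVS/d (activity roughly doubles after the second spike).")

anova = spike_comparison(results)
anova.to_csv(OUT / "saa_anova.csv")
p_spike = anova.loc["C(spike)", "PR(>F)"]
print(f"Two-way ANOVA: spike effect p = {p_spike:.2e} "
      f"({'significant' if p_spike < 0.05 else 'not significant'} at 0.05).")

rows = []
for saa_true in (0.05, 0.1, 0.2):
    for noise in (0.0, 2.0):
        errs = []
        for _ in range(100):
            cfg = TraceConfig(saa_true=(saa_true,), m2_mol_h=1e-5,
                              noise_sd_hpa=noise)
            est = bottle_saa(simulate_pressure_trace(cfg, seed=rng), 0)
            errs.append(abs(est - saa_true) / saa_true)
        rows.append({"saa_true": saa_true, "noise_sd_hpa": noise,
                     "median_rel_error_pct": 100 * float(np.median(errs))})
recovery = pd.DataFrame(rows)
recovery.to_csv(OUT / "saa_recovery.csv", index=False)
print("\nParameter recovery (median relative error, %):")
print(recovery.pivot(index="saa_true", columns="noise_sd_hpa",
                     values="median_rel_error_pct").round(3))
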