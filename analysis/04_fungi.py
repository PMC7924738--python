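#!/usr/bin/env python
"""Fungal bioassay reduction: colour removal and laccase activity from
the bundled strain outcome tables, plus a simulated decolorization
round-trip validating the reduction chain.

Writes:
    results/fungi_colour_removal.csv  14-day colour removal per strain/sample
    results/fungi_laccase.csv         laccase by day (NaN = below detection)
    results/fungi_roundtrip.csv       generator -> reduction consistency
"""

from pathlib import Path

import pandas as pd

from twbio.datasets import load_fungal_summary
from twbio.fungi import colour_removal, laccase_activity, strain_summary
from twbio.simulate import DecolorConfig, simulate_decolorization

OUT = Path("results")
OUT.mkdir(exist_ok=True)

strains = {"P. ostreatus": "pleurotus", "P. chrysosporium": "phanerochaete"}
removal = pd.DataFrame({
    name: load_fungal_summary(key)["colour_removal_14d"]
    for name, key in strains.items()
})
removal.to_csv(OUT / "fungi_colour_removal.csv")
po = removal["P. ostreatus"]
pc = removal["P. chrysosporium"]
print(f"P. ostreatus removes {po.min():.0f}-{po.max():.0f}% of the colour "
      f"in 14 d (best: {po.idxmax()}); P. chrysosporium only "
      f"{pc.min():.0f}-{pc.max():.0f}%.")

laccase = pd.concat({
    name: load_fungal_summary(key)[["laccase_5d", "laccase_10d", "laccase_14d"]]
    for name, key in strains.items()
}, names=["strain"])
laccase.to_csv(OUT / "fungi_laccase.csv")
peak = laccase.loc["P. ostreatus", "laccase_5d"]
print(f"P. ostreatus laccase peaks at {peak.max():.0f} IU/L ({peak.idxmax()}) "
      "by day 5 and collapses by day 14; "
      "P. chrysosporium stays below the 0.5 IU/L detection limit.")

cfg = DecolorConfig(removal_fraction=0.62, initial_ods=(0.10, 0.10, 0.09),
                    laccase_peak_iu=396.0)
records, kinetics = simulate_decolorization(cfg, seed=1)
summary = strain_summary(records)
summary["laccase_from_kinetics"] = laccase_activity(kinetics)
summary.to_csv(OUT / "fungi_roundtrip.csv", index=False)
final = summary.set_index("day").loc[14.0]
print(f"\nRound-trip: configured 62% removal -> measured "
      f"{final.colour_removal_mean:.1f}%; configured 396 IU/L -> "
      f"quantified {laccase_activity(kinetics):.1f} IU/L.")
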