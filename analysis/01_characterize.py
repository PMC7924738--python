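#!/usr/bin/env python
"""Characterize the wastewater samples: summary statistics, derived
chemistry (free ammonia, sCOD/N) and a PCA of the physicochemical table.

Writes:
    results/characterization_summary.csv  per-column mean/SD/CV over TW1-7
    results/derived_chemistry.csv         NH3-N at 20 degC and sCOD/N per sample
    results/pca_variance.csv              percent variance per component
    results/pca_loadings.csv              variable loadings, first two components
"""

from pathlib import Path

import pandas as pd

from twbio.characterization import free_ammonia, scod_n_ratio, summarize
from twbio.datasets import TW_IDS, load_characterization, load_elements, tw_samples
from twbio.stats import pca

OUT = Path("results")
OUT.mkdir(exist_ok=True)

samples = tw_samples()

columns = ["pH", "conductivity", "turbidity", "tn_n", "nh4_n", "nh3_n",
           "po4_p", "cod", "scod", "scod_n", "tss", "vss",
           "K", "Mg", "Ca", "Si", "Fe", "Na", "Zn", "Mn", "Al", "Cr", "Ni", "Cu"]
summary = summarize(samples, columns)
summary.to_csv(OUT / "characterization_summary.csv")
print("Summary over the seven samples (excerpt):")
print(summary.loc[["nh4_n", "tn_n", "turbidity", "Si", "Na"]].round(2))

derived = pd.DataFrame({
    "nh3_n_20C": {s.id: free_ammonia(s.nh4_n, s.pH, 20.0) for s in samples},
    "scod_n": {s.id: scod_n_ratio(s) for s in samples},
})
derived.to_csv(OUT / "derived_chemistry.csv")
print(f"\nFree ammonia spans {derived.nh3_n_20C.min():.0f}-"
      f"{derived.nh3_n_20C.max():.0f} mg NH3-N/L; "
      f"sCOD/N spans {derived.scod_n.min()}-{derived.scod_n.max()} "
      "(unfavourably high for anammox in some weeks).")

ch = load_characterization().loc[list(TW_IDS)]
el = load_elements().loc[list(TW_IDS)]
table = pd.concat(
    [ch[["cod", "scod", "turbidity", "colour_index", "tss", "tn_n",
         "nh4_n", "po4_p"]],
     el[["Mg", "Ca", "Na", "Si", "Fe", "Zn", "Cr", "Ni"]]],
    axis=1,
)
res = pca(table)
pd.Series(res.variance_explained,
          index=res.loadings.columns, name="variance_pct").to_csv(
    OUT / "pca_variance.csv")
res.loadings.iloc[:, :2].to_csv(OUT / "pca_loadings.csv")
print(f"\nPCA: PC1 explains {res.variance_explained[0]:.1f}%, "
      f"PC2 {res.variance_explained[1]:.1f}% "
      f"(first two components: {res.variance_explained[:2].sum():.1f}%).")
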