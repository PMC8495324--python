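#!/usr/bin/env python
"""Build the pure-stand selection index for mixed-stand pea yield.

Forward stepwise regression of MS-yield line values (averaged across the
two years) on PS-measured traits, with the entry rules P < 0.05 and
delta-R2 >= 0.02.  Writes the fitted index (weights, entry order, R2) to
results/index/selection_index.json and the per-year heritability and
genetic correlation of the index criterion to results/index/index_quality.tsv.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from peamix import corr, selection, simulate as sim, trial
from peamix.trial import MS, PS

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=0)
ap.add_argument("--out", type=Path, default=Path("results/index"))
args = ap.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

scen = sim.generate_scenario(sim.SimulationConfig(seed=args.seed))
table = trial.derive_mixture_traits(scen.trial)

ps = table[table["condition"] == PS]
candidates = ps.groupby("line")[
    ["pea_yield", "onset_flowering", "height_flowering", "seed_weight",
     "maturity", "height_maturity"]
].mean()
target = table[table["condition"] == MS].groupby("line")["pea_yield"].mean()

model = selection.fit_selection_index(target, candidates)
(args.out / "selection_index.json").write_text(json.dumps(model.to_dict(), indent=2))

table = selection.add_index_column(table, model)
rows = []
for year in scen.config.years:
    vc = trial.variance_components(table, "selection_index", "line_block",
                                   condition=PS, year=year)
    h2 = trial.heritability(vc)
    vc_ms = trial.variance_components(table, "pea_yield", "line_block",
                                      condition=MS, year=year)
    h2_ms = trial.heritability(vc_ms)
    rg = corr.genetic_correlation_cross_condition(
        table, "selection_index", PS, "pea_yield", MS, year)
    eff = selection.predicted_efficiency_heritability(h2.H2, h2_ms.H2, rg.r)
    rows.append({"year": year, "H2_index": round(h2.H2, 2),
                 "r_g_with_ms_yield": round(rg.r, 2), "E_R": eff.e_r_rounded})
quality = pd.DataFrame(rows)
quality.to_csv(args.out / "index_quality.tsv", sep="\t", index=False)

print("stepwise index:", " + ".join(
    f"{w:+.4f}*{t}" for t, w in model.weights.items()),
    f"{model.intercept:+.4f}")
print(f"entry order: {model.entry_order}, R2 = {model.r2:.3f}")
print(quality.to_string(index=False))
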