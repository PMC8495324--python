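#!/usr/bin/env python
"""Phenotypic analysis of the synthetic trials: trait summaries, ANOVAs,
variance components, heritabilities and genetic correlations.

Reproduces the study's per-year comparison of selection criteria: for
each year and criterion (pea yield in MS, pea yield in PS) it estimates
line-mean broad-sense heritability and the Robertson cross-condition
genetic correlation with yield in MS, then the Falconer predicted
efficiency of indirect selection.  Also runs the across-years analysis
(Itoh-Yamada genetic correlation, over-years heritability) and the
four-way variance-component decomposition of pea yield.

Writes results/pheno/*.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from peamix import corr, selection, simulate as sim, trial
from peamix.trial import MS, PS

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=0)
ap.add_argument("--out", type=Path, default=Path("results/pheno"))
args = ap.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

scen = sim.generate_scenario(sim.SimulationConfig(seed=args.seed))
table = trial.ms_ps_yield_ratio(trial.derive_mixture_traits(scen.trial))

# trait summary (means and ranges of line means)
rows = []
for trait in ("pea_yield", "cereal_yield", "total_yield", "pea_proportion", "ms_ps_ratio"):
    for year in scen.config.years:
        for cond in (PS, MS):
            sub = table[(table["year"] == year) & (table["condition"] == cond)]
            lm = sub.groupby("line")[trait].mean().dropna()
            if lm.empty:
                continue
            rows.append({"trait": trait, "condition": cond, "year": year,
                         "mean": lm.mean(), "min": lm.min(), "max": lm.max()})
summary = pd.DataFrame(rows)
summary.to_csv(args.out / "trait_summary.tsv", sep="\t", index=False)

# per-year heritability and Falconer efficiency of PS-yield indirect selection
herit = []
for year in scen.config.years:
    ests = {}
    for cond in (MS, PS):
        vc = trial.variance_components(table, "pea_yield", "line_block",
                                       condition=cond, year=year)
        tab = trial.anova(table, "pea_yield", "line_block", condition=cond, year=year)
        ests[cond] = trial.heritability(vc)
        cv_g = 100 * vc.sigma2_g**0.5 / vc.grand_mean
        cv_e = 100 * vc.sigma2_e**0.5 / vc.grand_mean
        herit.append({"year": year, "criterion": f"pea_yield@{cond}",
                      "CVg": round(cv_g, 1), "CVe": round(cv_e, 1),
                      "H2": round(ests[cond].H2, 2), "H2_se": round(ests[cond].se, 2),
                      "line_P": tab.loc["line", "p"]})
    rg = corr.genetic_correlation_cross_condition(
        table, "pea_yield", PS, "pea_yield", MS, year)
    eff = selection.predicted_efficiency_heritability(ests[PS].H2, ests[MS].H2, rg.r)
    herit[-1].update({"r_g": round(rg.r, 2), "E_R": eff.e_r_rounded})
herit = pd.DataFrame(herit)
herit.to_csv(args.out / "heritability_efficiency.tsv", sep="\t", index=False)

# across-years components and the four-way decomposition
xy = []
for cond in (MS, PS):
    vc = trial.variance_components(table, "pea_yield", "line_year", condition=cond)
    xy.append({"condition": cond,
               "r_g_years": round(corr.genetic_correlation_cross_year(vc).r, 2),
               "H2_over_years": round(trial.heritability(vc, "over-years").H2, 3)})
pd.DataFrame(xy).to_csv(args.out / "cross_year.tsv", sep="\t", index=False)

vc4 = trial.variance_components(table, "pea_yield", "full")
pd.DataFrame([{"sigma2_g": vc4.sigma2_g, "sigma2_gc": vc4.sigma2_gc,
               "sigma2_gy": vc4.sigma2_gy, "sigma2_gcy": vc4.sigma2_gcy,
               "sigma2_e": vc4.sigma2_e}]).to_csv(
    args.out / "variance_components_full.tsv", sep="\t", index=False)

print("trait summary (pea yield):")
print(summary[summary["trait"] == "pea_yield"].to_string(index=False))
print("\nper-year heritability and indirect-selection efficiency:")
print(herit.to_string(index=False))
print(f"\nG x condition vs genotypic variance: "
      f"{vc4.sigma2_gc:.4f} vs {vc4.sigma2_g:.4f} "
      f"(ratio {vc4.sigma2_gc / vc4.sigma2_g:.2f})")
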