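"""End-to-end orchestration: simulate → phenotypic analysis → selection
index → efficiency comparisons → genomic prediction → GWAS → report.

Each stage draws its randomness from a named substream of one master
seed, so stages are independently reproducible; every output table is
written as TSV next to a JSON manifest recording seeds and thresholds.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import corr, gs, gwas as gwas_mod, selection, simulate, trial
from .genomatrix import FilterConfig, filter_markers_and_genotypes, kinship_astle_balding, knni_impute
from .trial import MS, PS

log = logging.getLogger("peamix")


class PipelineError(RuntimeError):
    pass


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed (< 2^31)."""
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str | Path = "results/run"
    simulation: simulate.SimulationConfig | None = None
    cv_repetitions: int = 20
    gain_repetitions: int = 20
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    knni_k: int = 5
    gwas_alpha: float = 0.05
    cycles_ratio_genomic: float = 2.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        sim = raw.pop("simulation", None)
        cfg = cls(**raw)
        if sim:
            cfg.simulation = simulate.SimulationConfig(**sim)
        return cfg

    def validate(self) -> None:
        sim = self.simulation or simulate.SimulationConfig()
        if len(sim.years) < 2:
            raise PipelineError("year-swap protocols need at least two cropping years")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full comparison of selection strategies on one synthetic
    scenario; returns a dict of result tables (also written as TSV)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim_cfg = config.simulation or simulate.SimulationConfig(
        seed=stage_seed(config.seed, "simulate")
    )
    log.info("simulating scenario (seed %d)", sim_cfg.seed)
    scen = simulate.generate_scenario(sim_cfg)
    table = trial.derive_mixture_traits(scen.trial)
    table = trial.ms_ps_yield_ratio(table)
    years = list(sim_cfg.years)

    results: dict[str, pd.DataFrame] = {}

    # trait summaries (means and ranges of line means per condition/year)
    rows = []
    for trait in ("pea_yield", "cereal_yield", "total_yield", "pea_proportion", "ms_ps_ratio"):
        if trait not in table.columns:
            continue
        for year in years:
            for cond in (MS, PS):
                sub = table[(table["year"] == year) & (table["condition"] == cond)]
                if sub[trait].dropna().empty:
                    continue
                lm = sub.groupby("line", observed=True)[trait].mean()
                rows.append(
                    {"trait": trait, "condition": cond, "year": year,
                     "mean": lm.mean(), "min": lm.min(), "max": lm.max()}
                )
    results["trait_summary"] = pd.DataFrame(rows)

    # selection index on PS line values averaged across years
    ps = table[table["condition"] == PS]
    ps_lines = ps.groupby("line", observed=True)[
        ["pea_yield", "onset_flowering", "height_flowering", "seed_weight",
         "maturity", "height_maturity"]
    ].mean()
    ms_target = (
        table[table["condition"] == MS].groupby("line", observed=True)["pea_yield"].mean()
    )
    index_model = selection.fit_selection_index(
        ms_target, ps_lines.dropna(axis=1, how="all")
    )
    table = selection.add_index_column(table, index_model)
    (out / "selection_index.json").write_text(json.dumps(index_model.to_dict(), indent=2))

    # per-year heritability / genetic-correlation table (printed-table layout)
    herit_rows = []
    for year in years:
        crits = [("pea_yield", MS), ("pea_yield", PS), ("selection_index", PS)]
        h2 = {}
        for trait_name, cond in crits:
            vc = trial.variance_components(table, trait_name, "line_block",
                                           condition=cond, year=year)
            est = trial.heritability(vc)
            h2[(trait_name, cond)] = (est, vc)
        for trait_name, cond in crits:
            est, vc = h2[(trait_name, cond)]
            row = {"year": year, "criterion": f"{trait_name}@{cond}",
                   "H2": est.H2, "H2_se": est.se}
            if (trait_name, cond) != ("pea_yield", MS):
                rg = corr.genetic_correlation_cross_condition(
                    table, trait_name, cond, "pea_yield", MS, year)
                eff = selection.predicted_efficiency_heritability(
                    est.H2, h2[("pea_yield", MS)][0].H2, rg.r)
                row.update({"r_g": rg.r, "r_g_se": rg.se, "E_R": eff.e_r_rounded})
            else:
                row.update({"r_g": np.nan, "r_g_se": np.nan, "E_R": 100})
            herit_rows.append(row)
    results["heritability"] = pd.DataFrame(herit_rows)

    # cross-year genetic correlations and over-years heritability
    xy_rows = []
    for trait_name, cond in [("pea_yield", MS), ("pea_yield", PS), ("selection_index", PS)]:
        vc = trial.variance_components(table, trait_name, "line_year", condition=cond)
        rg = corr.genetic_correlation_cross_year(vc)
        h2 = trial.heritability(vc, basis="over-years")
        xy_rows.append({"criterion": f"{trait_name}@{cond}", "r_g_years": rg.r,
                        "H2_over_years": h2.H2})
    results["cross_year"] = pd.DataFrame(xy_rows)

    # correlation-based efficiency (year-swap phenotypic correlations)
    def year_swap_corrs(trait_name: str, cond: str) -> dict:
        vals = {}
        for sel_year in years:
            tgt_year = [y for y in years if y != sel_year][0]
            sel = trial.line_means(table, trait_name, condition=cond, year=sel_year)["mean"]
            tgt = trial.line_means(table, "pea_yield", condition=MS, year=tgt_year)["mean"]
            vals[sel_year] = corr.phenotypic_correlation(
                sel.reindex(tgt.index), tgt).r
        return vals

    r_ms = year_swap_corrs("pea_yield", MS)
    corr_rows = []
    for trait_name, cond in [("pea_yield", MS), ("pea_yield", PS), ("selection_index", PS)]:
        r_crit = year_swap_corrs(trait_name, cond)
        eff = selection.predicted_efficiency_correlation(
            list(r_crit.values()), list(r_ms.values()))
        corr_rows.append({"criterion": f"{trait_name}@{cond}", **r_crit,
                          "r_mean": eff.components["r_indirect"],
                          "E_R": selection.round_half_up(eff.e_r)})
    results["correlation_efficiency"] = pd.DataFrame(corr_rows)

    # genomic data processing
    gm_f, filter_report = filter_markers_and_genotypes(scen.genotypes, config.filter_config)
    gm_i = knni_impute(gm_f, k=config.knni_k)
    kin = kinship_astle_balding(gm_i)

    # genomic prediction (three schemes, both training years)
    gs_rows = []
    per_line_gebv = {}
    for scheme in ("intra_population", "inter_population", "all_genotypes"):
        for train_year in years:
            valid_year = [y for y in years if y != train_year][0]
            plan = gs.make_cv_plan(
                scen.line_table, scheme,
                n_repetitions=config.cv_repetitions,
                seed=stage_seed(config.seed, f"cv:{scheme}:{train_year}"),
            )
            res = gs.run_inter_environment_cv(
                gm_i, table, plan, train_year, valid_year, scen.line_table)
            gs_rows.append({"scheme": scheme, "train_year": train_year,
                            "ability": res.ability,
                            "ability_on_averaged": res.ability_on_averaged})
            if scheme == "intra_population":
                per_line_gebv[train_year] = res.per_line_pred
    gs_tab = pd.DataFrame(gs_rows)
    gs_tab = pd.concat(
        [gs_tab, gs_tab.groupby("scheme", as_index=False)["ability"].mean()
         .assign(train_year="average")], ignore_index=True)
    results["predictive_ability"] = gs_tab

    # realized year-swap gains for all four criteria
    gain_rows = []
    gains_by_crit: dict[str, dict] = {}
    for sel_year in years:
        eval_year = [y for y in years if y != sel_year][0]
        crit_scores = {
            "phenotypic_MS": trial.line_means(table, "pea_yield", MS, sel_year)["mean"],
            "phenotypic_PS": trial.line_means(table, "pea_yield", PS, sel_year)["mean"],
            "index_PS": trial.line_means(table, "selection_index", PS, sel_year)["mean"],
            "genomic_MS": per_line_gebv[sel_year],
        }
        for crit, scores in crit_scores.items():
            rep = selection.year_swap_gain(
                table, scores, sel_year, eval_year, criterion=crit)
            gain_rows.append({"criterion": crit, "selection_year": sel_year,
                              "mean_yield": rep.mean_selected_yield,
                              "parent_mean": rep.parent_mean, "gain": rep.gain})
            gains_by_crit.setdefault(crit, {})[sel_year] = rep.gain
    eff_rows = []
    for crit in gains_by_crit:
        pairs = {y: (gains_by_crit[crit][y], gains_by_crit["phenotypic_MS"][y])
                 for y in years}
        try:
            eff = selection.relative_efficiency_from_gains(pairs)
            eff_rows.append({"criterion": crit, "E_R": eff.e_r,
                             **{f"E_R_{y}": v for y, v in
                                eff.components["per_year_rounded"].items()}})
        except selection.SelectionError:
            eff_rows.append({"criterion": crit, "E_R": np.nan})
    results["gains"] = pd.DataFrame(gain_rows)
    results["gain_efficiency"] = pd.DataFrame(eff_rows)

    # GWAS on line values averaged across years
    pops = scen.line_table["population"]
    for cond, tag in ((MS, "ms"), (PS, "ps")):
        pheno = table[table["condition"] == cond].groupby("line", observed=True)[
            "pea_yield"].mean()
        res = gwas_mod.run_gwas(gm_i, pheno, covariates=pops, alpha=config.gwas_alpha)
        results[f"gwas_{tag}"] = gwas_mod.manhattan_table(res)
        results[f"gwas_{tag}"].attrs["lambda_gc"] = res.lambda_gc

    for name, tab in results.items():
        tab.to_csv(out / f"{name}.tsv", sep="\t", index=False)
    manifest = {
        "seed": config.seed,
        "stage_seeds": {s: stage_seed(config.seed, s) for s in ("simulate",)},
        "filter": filter_report,
        "cv_repetitions": config.cv_repetitions,
        "tables": sorted(results),
        "index_model": index_model.to_dict(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    results["_manifest"] = manifest
    return results


def ps_indirect_efficiency_recovery(
    n_replicates: int = 200,
    seed: int = 0,
    n_markers: int = 150,
    year: str = simulate.YEAR1,
) -> dict:
    """Recovery study for the predicted efficiency of PS-yield indirect
    selection.

    Generates ``n_replicates`` single-year studies (144 lines, 2
    conditions, 3 blocks) with the first-year yield targets (MS CVg 33 /
    CVe 44, PS CVg 24 / CVe 27, cross-condition genetic correlation
    0.42), runs the full estimation chain on each — per-condition
    variance components, line-mean heritabilities, Robertson genetic
    correlation, Falconer formula — and returns the mean relative
    efficiency with its replicate distribution.
    """
    rng = np.random.default_rng(seed)
    e_rs, h2_ms, h2_ps, r_gs = [], [], [], []
    for _ in range(n_replicates):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        cfg = simulate.yield_only_config(seed=rep_seed, n_markers=n_markers, years=(year,))
        scen = simulate.generate_scenario(cfg)
        vc_ms = trial.variance_components(
            scen.trial, "pea_yield", "line_block", condition=MS, year=year
        )
        vc_ps = trial.variance_components(
            scen.trial, "pea_yield", "line_block", condition=PS, year=year
        )
        est_ms = trial.heritability(vc_ms)
        est_ps = trial.heritability(vc_ps)
        rg = corr.genetic_correlation_cross_condition(
            scen.trial, "pea_yield", PS, "pea_yield", MS, year
        )
        eff = selection.predicted_efficiency_heritability(est_ps.H2, est_ms.H2, rg.r)
        e_rs.append(eff.e_r)
        h2_ms.append(est_ms.H2)
        h2_ps.append(est_ps.H2)
        r_gs.append(rg.r)
    return {
        "mean_e_r": float(np.mean(e_rs)),
        "e_r": e_rs,
        "mean_h2_ms": float(np.mean(h2_ms)),
        "mean_h2_ps": float(np.mean(h2_ps)),
        "mean_r_g": float(np.mean(r_gs)),
        "n_replicates": n_replicates,
    }


def report_efficiency_summary(
    heritability_components: dict | None = None,
    correlation_components: dict | None = None,
    gain_components: dict | None = None,
    cycles_ratio: float = 2.0,
) -> pd.DataFrame:
    """One row per strategy × comparison method, from printed or computed
    components.

    ``heritability_components``: {strategy: (H2_ind, H2_dir, r_g)};
    ``correlation_components``: {strategy: (r_by_year_ind, r_by_year_dir)};
    ``gain_components``: {strategy: {year: (G_crit, G_dir)}}.  Genomic
    strategies additionally get the per-unit-time value at
    ``cycles_ratio`` selection cycles per year.
    """
    rows = []
    for name, args in (heritability_components or {}).items():
        eff = selection.predicted_efficiency_heritability(*args)
        rows.append({"strategy": name, "method": eff.method,
                     "E_R": eff.e_r_rounded, **eff.components})
    for name, (r_ind, r_dir) in (correlation_components or {}).items():
        eff = selection.predicted_efficiency_correlation(r_ind, r_dir)
        rows.append({"strategy": name, "method": eff.method,
                     "E_R": selection.round_half_up(eff.e_r), **eff.components})
        if name.startswith("genomic"):
            t = selection.per_unit_time_adjustment(
                selection.round_half_up(eff.e_r), cycles_ratio)
            rows.append({"strategy": name, "method": t.method,
                         "E_R": t.e_r_rounded, **t.components})
    for name, pairs in (gain_components or {}).items():
        eff = selection.relative_efficiency_from_gains(pairs)
        rows.append({"strategy": name, "method": eff.method, "E_R": eff.e_r,
                     **{f"E_R_{y}": v for y, v in
                        eff.components["per_year_rounded"].items()}})
        if name.startswith("genomic"):
            t = selection.per_unit_time_adjustment(eff.e_r, cycles_ratio)
            rows.append({"strategy": name, "method": t.method,
                         "E_R": t.e_r_rounded, **t.components})
    cols = ["strategy", "method", "E_R"]
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(columns=cols)
    return df[cols + [c for c in df.columns if c not in cols]]
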