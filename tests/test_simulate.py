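"""Generator: founder genomes, RIL meiosis, genotyping noise, genetic
architecture and trial phenotypes."""

import numpy as np
import pandas as pd
import pytest

from peamix import simulate as sim
from peamix import trial
from peamix.simulate import MS, PS, YEAR1, YIELD_MS, YIELD_PS, ConfigError


def small_cfg(**kw):
    kw.setdefault("seed", 1)
    kw.setdefault("n_markers", 120)
    return sim.SimulationConfig(**kw)


class TestFounderGenomes:
    def test_parents_fully_homozygous(self):
        g = sim.simulate_founder_genomes(small_cfg(n_markers=100))
        assert g.values.shape == (6, 100)
        assert set(np.unique(g.values)) <= {0.0, 2.0}

    def test_same_seed_identical(self):
        a = sim.simulate_founder_genomes(small_cfg())
        b = sim.simulate_founder_genomes(small_cfg())
        assert np.array_equal(a.values, b.values)

    def test_polymorphic_fraction_bounded_over_seeds(self):
        for seed in range(50):
            cfg = small_cfg(seed=seed, n_markers=80)
            g = sim.simulate_founder_genomes(cfg)
            poly = (g.values != g.values[0]).any(axis=0).mean()
            assert poly >= cfg.min_polymorphic_fraction

    def test_zero_markers_rejected(self):
        with pytest.raises(ConfigError):
            sim.simulate_founder_genomes(small_cfg(n_markers=0))

    def test_marker_map_sorted_within_chromosome(self):
        g = sim.simulate_founder_genomes(small_cfg())
        for _, grp in g.marker_map.groupby("chrom"):
            assert grp["pos"].is_monotonic_increasing


class TestRilSimulation:
    def test_identical_parents_give_identical_rils(self):
        cfg = small_cfg()
        founders = sim.simulate_founder_genomes(cfg)
        founders.values[1] = founders.values[0]
        ril = sim.simulate_ril_population(founders, ("Attika", "Isard"), 20, cfg)
        assert np.array_equal(ril.values, np.tile(founders.values[0], (20, 1)))

    def test_heterozygous_parent_rejected(self):
        cfg = small_cfg()
        founders = sim.simulate_founder_genomes(cfg)
        founders.values[0, 0] = 1.0
        with pytest.raises(ConfigError):
            sim.simulate_ril_population(founders, ("Attika", "Isard"), 5, cfg)

    def test_zero_distance_no_recombinants(self):
        # two markers at the same map position on one chromosome
        cfg = small_cfg(n_chromosomes=1, n_markers=2)
        founders = sim.simulate_founder_genomes(cfg)
        founders.marker_map["pos"] = [10.0, 10.0]
        founders.values[:] = 0.0
        founders.values[0] = [0.0, 0.0]
        founders.values[1] = [2.0, 2.0]
        ril = sim.simulate_ril_population(founders, ("Attika", "Isard"), 500, cfg)
        assert (ril.values[:, 0] == ril.values[:, 1]).all()

    def test_recombination_fraction_matches_selfing_formula(self):
        # adjacent markers 20 cM apart: r from Haldane, R = 2r/(1+2r)
        cfg = small_cfg(n_chromosomes=1, n_markers=2, seed=9)
        founders = sim.simulate_founder_genomes(cfg)
        founders.marker_map["pos"] = [0.0, 20.0]
        founders.values[0] = [0.0, 0.0]
        founders.values[1] = [2.0, 2.0]
        n = 2000
        ril = sim.simulate_ril_population(founders, ("Attika", "Isard"), n, cfg)
        observed = (ril.values[:, 0] != ril.values[:, 1]).mean()
        r = 0.5 * (1 - np.exp(-0.4))
        R = 2 * r / (1 + 2 * r)
        assert observed == pytest.approx(R, abs=3 * np.sqrt(R * (1 - R) / n))

    def test_rils_homozygous_before_noise(self, tiny_scenario):
        assert not np.any(tiny_scenario.genotypes_true.values == 1)


class TestGenotypingNoise:
    def test_zero_rates_identity(self):
        cfg = small_cfg(marker_missing_rate=0, genotype_missing_rate=0, residual_het_rate=0)
        g = sim.simulate_founder_genomes(cfg)
        noisy = sim.apply_genotyping_noise(g, cfg)
        assert np.array_equal(noisy.values, g.values)

    def test_realized_missing_rate_near_target(self):
        cfg = small_cfg(
            n_markers=100, marker_missing_rate=0.1, genotype_missing_rate=0.0,
            residual_het_rate=0.0, seed=3,
        )
        gm, _ = sim.assemble_genotypes(cfg, np.random.default_rng(3))
        noisy = sim.apply_genotyping_noise(gm, cfg)
        assert noisy.marker_missing_rate().mean() == pytest.approx(0.1, abs=0.01)

    def test_residual_het_rate(self):
        cfg = small_cfg(
            n_markers=200, marker_missing_rate=0.0, genotype_missing_rate=0.0,
            residual_het_rate=0.02, seed=4,
        )
        gm, _ = sim.assemble_genotypes(cfg, np.random.default_rng(4))
        noisy = sim.apply_genotyping_noise(gm, cfg)
        assert (noisy.values == 1).mean() == pytest.approx(0.02, abs=0.004)

    def test_bad_rate_rejected(self):
        with pytest.raises(ConfigError):
            small_cfg(marker_missing_rate=1.5).validate()


class TestGeneticValues:
    def test_reconstruction_from_effects_and_polygenic(self, default_scenario):
        arch = default_scenario.architecture
        rec = arch.reconstruct(default_scenario.genotypes_true)
        assert np.allclose(rec.to_numpy(), arch.genetic_values.to_numpy(), atol=1e-10)

    def test_perfect_cross_condition_correlation(self):
        # a unit MS/PS correlation requires the other traits to relate to
        # both yield columns identically; identity elsewhere is consistent
        C = pd.DataFrame(
            np.eye(len(sim.ARCH_TRAITS)),
            index=sim.ARCH_TRAITS, columns=sim.ARCH_TRAITS,
        )
        C.loc[YIELD_MS, YIELD_PS] = C.loc[YIELD_PS, YIELD_MS] = 1.0
        cfg = small_cfg(genetic_corr_ms_ps=1.0, trait_corr_matrix=C)
        rng = np.random.default_rng(0)
        gm, lt = sim.assemble_genotypes(cfg, rng)
        arch = sim.simulate_genetic_values(gm, lt, cfg, rng)
        r = np.corrcoef(arch.genetic_values[YIELD_MS], arch.genetic_values[YIELD_PS])[0, 1]
        assert r == pytest.approx(1.0, abs=1e-8)

    def test_realized_correlation_matches_target(self):
        # whitening makes the empirical line-level correlation exact
        cfg = small_cfg(genetic_corr_ms_ps=0.42)
        rng = np.random.default_rng(5)
        gm, lt = sim.assemble_genotypes(cfg, rng)
        arch = sim.simulate_genetic_values(gm, lt, cfg, rng)
        assert arch.realized_corr_ms_ps == pytest.approx(0.42, abs=1e-6)
        target = sim.nearest_psd_correlation(
            cfg.trait_corr_matrix.to_numpy()
        )
        assert np.allclose(arch.realized_corr.to_numpy(), target, atol=0.02)

    def test_zero_qtl_purely_polygenic(self):
        cfg = small_cfg(n_qtl_per_trait=0)
        rng = np.random.default_rng(6)
        gm, lt = sim.assemble_genotypes(cfg, rng)
        arch = sim.simulate_genetic_values(gm, lt, cfg, rng)
        assert np.all(arch.marker_effects.to_numpy() == 0)
        rec = arch.reconstruct(gm)
        assert np.allclose(rec.to_numpy(), arch.genetic_values.to_numpy())


class TestTrialPhenotypes:
    def test_noise_free_plots_equal_genetic_values(self):
        targets = {
            ("pea_yield", MS, YEAR1): sim.TraitTarget(1.0, 30.0, 0.0),
            ("pea_yield", PS, YEAR1): sim.TraitTarget(6.0, 20.0, 0.0),
        }
        cfg = small_cfg(
            trait_targets=targets, years=(YEAR1,), block_cv=0.0, main_plot_cv=0.0,
            variance_ratios={"gc_over_g": 2.0, "gy_over_g": 0.0, "gcy_over_g": 0.0},
        )
        scen = sim.generate_scenario(cfg)
        z = scen.architecture.genetic_values[YIELD_MS]
        ms = scen.trial[scen.trial["condition"] == MS]
        for _, grp in ms.groupby("line"):
            # all blocks identical, equal to mean*(1 + cvg*z)
            assert grp["pea_yield"].std() == pytest.approx(0.0, abs=1e-12)
        got = ms.groupby("line")["pea_yield"].mean().loc[z.index]
        assert np.allclose(got, 1.0 * (1 + 0.30 * z), atol=1e-10)

    def test_line_variation_detected_by_anova(self, default_table):
        for cond in (MS, PS):
            tab = trial.anova(
                default_table, "pea_yield", "line_block", condition=cond, year=YEAR1
            )
            assert tab.loc["line", "p"] < 0.01

    def test_year1_only_traits(self, default_scenario):
        t = default_scenario.trial
        y2 = t[t["year"] == "2019-20"]
        assert y2["ascochyta"].isna().all()
        assert y2["winter_survival"].isna().all()
        y1 = t[(t["year"] == YEAR1) & (t["condition"] == PS)]
        assert y1["ascochyta"].notna().all()

    def test_cereal_yield_negatively_related_to_pea_competitive_value(
        self, default_scenario
    ):
        t = default_scenario.trial
        ms = t[t["condition"] == MS]
        lm = ms.groupby("line")[["pea_yield", "cereal_yield"]].mean()
        r = np.corrcoef(lm["pea_yield"], lm["cereal_yield"])[0, 1]
        assert -0.6 < r < -0.1  # low inverse correlation

    def test_sigma2_g_recovery_on_average(self):
        # method-of-moments genotypic variance vs the configured target
        truth = (0.33 * 1.0) ** 2
        ests = []
        for seed in range(60):
            cfg = sim.yield_only_config(seed=seed, n_markers=60, years=(YEAR1,))
            scen = sim.generate_scenario(cfg)
            vc = trial.variance_components(
                scen.trial, "pea_yield", "line_block", condition=MS, year=YEAR1
            )
            ests.append(vc.sigma2_g)
        assert np.mean(ests) == pytest.approx(truth, rel=0.10)


class TestScenario:
    def test_default_design_constants(self, default_scenario):
        lt = default_scenario.line_table
        assert len(lt) == 144
        assert lt["is_parent"].sum() == 6
        assert lt.loc[~lt["is_parent"], "population"].nunique() == 6
        assert default_scenario.trial.groupby(["year", "condition", "block"]).size().eq(144).all()

    def test_seeded_bundle_byte_identical(self, tmp_path):
        cfg = small_cfg(n_populations=2, lines_per_population=5, n_markers=50, seed=8)
        for d in ("a", "b"):
            sim.generate_scenario(cfg).write(tmp_path / d)
        for f in ("trial.tsv", "genotypes.012.tsv", "architecture.json"):
            assert (tmp_path / "a" / f).read_bytes() == (tmp_path / "b" / f).read_bytes()

    def test_tiny_config_invariants(self, tiny_scenario):
        assert tiny_scenario.genotypes.values.shape == (16, 50)
        assert not np.isnan(tiny_scenario.genotypes_true.values).any()
        mm = tiny_scenario.genotypes.marker_map
        for _, grp in mm.groupby("chrom"):
            assert grp["pos"].is_monotonic_increasing
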