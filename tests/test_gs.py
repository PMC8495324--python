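"""Genomic prediction: rrBLUP, GBLUP equivalence, CV plans,
inter-environment cross-validation, tuning and the gain protocol."""

import numpy as np
import pandas as pd
import pytest

from peamix import gs, simulate as sim, trial
from peamix.genomatrix import FilterConfig, GenotypeMatrix012, kinship_astle_balding
from peamix.gs import (
    GSError,
    gblup_fit_predict,
    genomic_gain_protocol,
    make_cv_plan,
    rrblup_fit,
    run_inter_environment_cv,
    tune_thresholds,
)


def random_gm(rng, n, m):
    return GenotypeMatrix012(
        lines=[f"L{i}" for i in range(n)],
        markers=[f"M{j}" for j in range(m)],
        values=rng.choice([0.0, 1.0, 2.0], size=(n, m)),
    )


class TestRrblup:
    def test_constant_phenotype_zero_effects(self):
        rng = np.random.default_rng(0)
        gm = random_gm(rng, 12, 30)
        y = pd.Series(3.0, index=gm.lines)
        model = rrblup_fit(gm, y, lambda_=1.0)
        assert np.allclose(model.beta, 0.0)
        assert np.allclose(model.predict(gm), 3.0)

    def test_infinite_shrinkage_limit(self):
        rng = np.random.default_rng(1)
        gm = random_gm(rng, 15, 40)
        y = pd.Series(rng.normal(5, 1, 15), index=gm.lines)
        model = rrblup_fit(gm, y, lambda_=1e12)
        preds = model.predict(gm)
        assert preds.std() < 1e-4
        assert preds.mean() == pytest.approx(y.mean(), abs=0.01)

    def test_two_line_one_marker_closed_form(self):
        # beta = (x1-x2)(y1-y2)/2 / ((x1-x2)^2/2 + lambda)
        gm = GenotypeMatrix012(lines=["A", "B"], markers=["m"], values=[[0.0], [2.0]])
        y = pd.Series({"A": 1.0, "B": 3.0})
        lam = 0.7
        model = rrblup_fit(gm, y, lambda_=lam)
        x_diff, y_diff = -2.0, -2.0
        expected = (x_diff * y_diff / 2) / (x_diff**2 / 2 + lam)
        assert model.beta[0] == pytest.approx(expected)

    def test_missing_genotypes_rejected(self):
        gm = GenotypeMatrix012(
            lines=["A", "B", "C"], markers=["m"], values=[[0.0], [np.nan], [2.0]]
        )
        with pytest.raises(GSError):
            rrblup_fit(gm, pd.Series({"A": 1.0, "B": 2.0, "C": 3.0}))


class TestGblupEquivalence:
    @pytest.mark.parametrize("seed", range(5))
    def test_rrblup_equals_gblup_on_random_instances(self, seed):
        # K = Xc Xc' makes the two parametrizations algebraically equal
        rng = np.random.default_rng(seed)
        n, m = 25, 60
        gm = random_gm(rng, n, m)
        y = pd.Series(rng.normal(size=n), index=gm.lines)
        train, target = gm.lines[:18], gm.lines[18:]
        model = rrblup_fit(gm.subset(lines=train), y.loc[train])
        pr = model.predict(gm, lines=target)
        Xc = gm.values - model.center
        K = pd.DataFrame(Xc @ Xc.T, index=gm.lines, columns=gm.lines)
        # algebraic identity at the shared variance ratio
        pg = gblup_fit_predict(K, y, train, target, lambda_=model.lambda_)
        scale = np.abs(pr).max() or 1.0
        assert np.allclose(pr, pg, rtol=1e-8, atol=1e-8 * scale)
        # independently REML-estimated ratios agree up to optimizer noise
        from peamix.gs import _reml_lambda_kernel

        lam2 = _reml_lambda_kernel(
            K.loc[train, train].to_numpy(), y.loc[train].to_numpy()
        )
        assert lam2 == pytest.approx(model.lambda_, rel=1e-3)

    def test_duplicate_kinship_profile_same_prediction(self):
        rng = np.random.default_rng(9)
        gm = random_gm(rng, 10, 40)
        Xc = gm.values - gm.values.mean(axis=0)
        K = pd.DataFrame(Xc @ Xc.T, index=gm.lines, columns=gm.lines)
        # target L9 given the K-profile of training line L0
        K.loc["L9"] = K.loc["L0"]
        K.loc[:, "L9"] = K.loc[:, "L0"]
        K.loc["L9", "L9"] = K.loc["L0", "L0"]
        y = pd.Series(rng.normal(size=9), index=gm.lines[:9])
        preds = gblup_fit_predict(K, y, gm.lines[:9], ["L0", "L9"], lambda_=1.0)
        assert preds["L9"] == pytest.approx(preds["L0"])

    def test_constant_phenotype_constant_predictions(self):
        rng = np.random.default_rng(3)
        gm = random_gm(rng, 10, 20)
        K = kinship_astle_balding(gm)
        y = pd.Series(2.0, index=gm.lines[:8])
        preds = gblup_fit_predict(K, y, gm.lines[:8], gm.lines[8:], lambda_=1.0)
        assert np.allclose(preds, 2.0)


class TestCvPlan:
    @pytest.fixture
    def line_table(self):
        lines, pops, parent = [], [], []
        for p in range(6):
            for i in range(23):
                lines.append(f"pop{p}_l{i:02d}")
                pops.append(f"pop{p}")
                parent.append(False)
        for i in range(6):
            lines.append(f"par{i}")
            pops.append("parents")
            parent.append(True)
        return pd.DataFrame(
            {"population": pops, "is_parent": parent},
            index=pd.Index(lines, name="line"),
        )

    def test_parents_never_validated(self, line_table):
        plan = make_cv_plan(line_table, "intra_population", n_repetitions=30, seed=0)
        for rep in plan.repetitions:
            assert not any(l.startswith("par") for l in rep["valid"])
            assert set(rep["train"]) & set(rep["valid"]) == set()
            assert all(f"par{i}" in rep["train"] for i in range(6))

    def test_validation_counts_balanced_100_reps(self, line_table):
        # 100 reps x 5 slots over 23 lines: 500/23 is not an integer, so
        # counts must be 21 or 22
        plan = make_cv_plan(line_table, "all_genotypes", n_repetitions=100, seed=1)
        counts = plan.validation_counts()
        assert set(counts.unique()) == {21, 22}

    def test_exact_balance_when_divisible(self, line_table):
        # 92 reps x 5 slots = 460 = 20 x 23: exactly 20 each
        plan = make_cv_plan(line_table, "intra_population", n_repetitions=92, seed=2)
        assert (plan.validation_counts() == 20).all()

    def test_inter_population_deterministic_splits(self, line_table):
        plan = make_cv_plan(line_table, "inter_population", n_repetitions=999, seed=3)
        assert len(plan.repetitions) == 6
        for rep in plan.repetitions:
            assert len(rep["train"]) == 5 * 23 + 6 == 121
            assert len(rep["valid"]) == 23

    def test_reproducible_under_seed(self, line_table):
        a = make_cv_plan(line_table, "intra_population", n_repetitions=10, seed=5)
        b = make_cv_plan(line_table, "intra_population", n_repetitions=10, seed=5)
        assert a.repetitions == b.repetitions

    def test_too_small_population_rejected(self):
        lt = pd.DataFrame(
            {"population": ["p"] * 4, "is_parent": [False] * 4},
            index=["a", "b", "c", "d"],
        )
        with pytest.raises(GSError):
            make_cv_plan(lt, "intra_population", n_validation=5)


class TestInterEnvironmentCv:
    def test_marker_determined_trait_is_highly_predictable(self):
        # a fully marker-determined, year-stable architecture approaches
        # perfect prediction
        cfg = sim.yield_only_config(
            seed=3, n_markers=300, qtl_variance_fraction=1.0, n_qtl_per_trait=60,
            variance_ratios={"gc_over_g": 2.0, "gy_over_g": 0.0, "gcy_over_g": 0.0},
        )
        cfg.trait_targets = {
            k: sim.TraitTarget(v.mean, v.cv_g, 1.0) for k, v in cfg.trait_targets.items()
        }
        scen = sim.generate_scenario(cfg)
        plan = make_cv_plan(scen.line_table, "all_genotypes", n_repetitions=10, seed=0)
        res = run_inter_environment_cv(
            scen.genotypes_true, scen.trial, plan, "2018-19", "2019-20",
            scen.line_table,
        )
        assert res.ability >= 0.9

    def test_pure_noise_trait_near_zero_ability(self):
        cfg = sim.yield_only_config(seed=4, n_markers=100)
        scen = sim.generate_scenario(cfg)
        rng = np.random.default_rng(0)
        table = scen.trial.copy()
        table["pea_yield"] = rng.normal(size=len(table))
        plan = make_cv_plan(scen.line_table, "all_genotypes", n_repetitions=50, seed=0)
        res = run_inter_environment_cv(
            scen.genotypes_true, table, plan, "2018-19", "2019-20", scen.line_table
        )
        assert abs(res.ability) < 0.1

    def test_ability_invariant_to_affine_phenotype_transform(self, default_scenario,
                                                             imputed_genotypes):
        table = default_scenario.trial
        plan = make_cv_plan(default_scenario.line_table, "all_genotypes",
                            n_repetitions=5, seed=1)
        res = run_inter_environment_cv(
            imputed_genotypes, table, plan, "2018-19", "2019-20",
            default_scenario.line_table,
        )
        scaled = table.copy()
        scaled["pea_yield"] = 4.0 * scaled["pea_yield"] + 2.0
        res2 = run_inter_environment_cv(
            imputed_genotypes, scaled, plan, "2018-19", "2019-20",
            default_scenario.line_table,
        )
        assert res2.ability == pytest.approx(res.ability, abs=1e-6)

    def test_unknown_line_in_plan_errors(self, default_scenario, imputed_genotypes):
        plan = make_cv_plan(default_scenario.line_table, "all_genotypes",
                            n_repetitions=2, seed=0)
        plan.repetitions[0]["valid"] = plan.repetitions[0]["valid"][:-1] + ["ghost"]
        with pytest.raises(GSError, match="ghost"):
            run_inter_environment_cv(
                imputed_genotypes, default_scenario.trial, plan,
                "2018-19", "2019-20", default_scenario.line_table,
            )


class TestTuning:
    def test_single_configuration_returned(self, default_scenario):
        cfg = FilterConfig()
        best, table = tune_thresholds(
            default_scenario.genotypes, default_scenario.trial,
            default_scenario.line_table, [cfg], "2018-19", "2019-20",
            n_repetitions=2,
        )
        assert best is cfg
        assert len(table) == 1

    def test_line_dropping_configurations_excluded(self, default_scenario):
        # an aggressive per-genotype threshold that drops lines must lose
        # to an admissible cell even if its ability is higher
        lenient = FilterConfig(max_missing_per_genotype=0.50)
        harsh = FilterConfig(max_missing_per_genotype=0.0)
        best, table = tune_thresholds(
            default_scenario.genotypes, default_scenario.trial,
            default_scenario.line_table, [lenient, harsh], "2018-19", "2019-20",
            n_repetitions=2,
        )
        assert best is lenient
        assert not table.loc[table["max_missing_per_genotype"] == 0.0,
                             "no_line_loss"].any()


class TestGainProtocol:
    def test_genomic_selection_ids_match_gebv_ranking(self):
        cfg = sim.yield_only_config(seed=6, n_markers=150)
        scen = sim.generate_scenario(
            sim.SimulationConfig(
                seed=6, n_markers=150,
                n_populations=2, lines_per_population=8,
            )
        )
        table = scen.trial
        plan = make_cv_plan(scen.line_table, "intra_population",
                            n_repetitions=16, n_validation=2, seed=0)
        res = run_inter_environment_cv(
            scen.genotypes_true, table, plan, "2018-19", "2019-20", scen.line_table
        )
        rep = genomic_gain_protocol(
            scen.genotypes_true, table, scen.line_table, "2018-19", "2019-20",
            k=2, n_repetitions=16, n_validation=2, seed=0,
        )
        # brute-force ranking from the averaged GEBVs
        for pop, chosen in rep.selected.items():
            pop_lines = scen.line_table.index[
                (scen.line_table["population"] == pop)
                & (~scen.line_table["is_parent"])
            ]
            expected = (
                res.per_line_pred.reindex(pop_lines)
                .sort_index()
                .sort_values(ascending=False, kind="stable")
                .index[:2]
                .tolist()
            )
            assert chosen == expected
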