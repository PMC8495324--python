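"""Trial model: derived traits, balanced ANOVA, variance components,
heritability and shrunken line values."""

import numpy as np
import pandas as pd
import pytest

from peamix import trial
from peamix.trial import (
    MS,
    PS,
    DesignError,
    HeritabilityEstimate,
    VarianceComponents,
    anova,
    blup_line_values,
    derive_mixture_traits,
    heritability,
    heritability_from_cv,
    line_means,
    ms_ps_yield_ratio,
    variance_components,
)


def _plot_table(values_by_line, condition=MS, year="Y1", cereal=None):
    rows = []
    for block, vals in enumerate(values_by_line, start=1):
        for i, v in enumerate(vals):
            rows.append(
                {
                    "year": year, "condition": condition, "block": block,
                    "population": "p", "line": f"L{i}", "is_parent": False,
                    "pea_yield": v,
                    "cereal_yield": cereal[block - 1][i] if cereal else np.nan,
                }
            )
    return pd.DataFrame(rows)


class TestDerivedTraits:
    @pytest.mark.parametrize(
        "pea, cereal, total, prop",
        [(1.2, 4.8, 6.0, 0.2), (0.0, 4.0, 4.0, 0.0), (2.5, 2.5, 5.0, 0.5)],
    )
    def test_total_and_proportion(self, pea, cereal, total, prop):
        t = _plot_table([[pea]], cereal=[[cereal]])
        out = derive_mixture_traits(t)
        assert out["total_yield"].iloc[0] == pytest.approx(total)
        assert out["pea_proportion"].iloc[0] == pytest.approx(prop)

    def test_zero_total_flagged_missing(self):
        out = derive_mixture_traits(_plot_table([[0.0]], cereal=[[0.0]]))
        assert np.isnan(out["pea_proportion"].iloc[0])

    def test_ps_rows_untouched(self, toy_trial_table):
        out = derive_mixture_traits(toy_trial_table)
        assert out.loc[out["condition"] == PS, "total_yield"].isna().all()


class TestMsPsRatio:
    def test_ratio_arithmetic(self):
        ms = _plot_table([[2.0, 1.0]], condition=MS)
        ps = _plot_table([[4.0, 4.0]], condition=PS)
        out = ms_ps_yield_ratio(pd.concat([ms, ps], ignore_index=True))
        got = out.loc[out["condition"] == MS, "ms_ps_ratio"].to_numpy()
        assert got == pytest.approx([1.0, 0.5])

    def test_zero_ps_mean_missing_with_warning(self):
        ms = _plot_table([[2.0]], condition=MS)
        ps = _plot_table([[0.0]], condition=PS)
        with pytest.warns(UserWarning):
            out = ms_ps_yield_ratio(pd.concat([ms, ps], ignore_index=True))
        assert out["ms_ps_ratio"].dropna().empty

    def test_line_absent_from_ps(self):
        ms = _plot_table([[2.0, 1.0]], condition=MS)
        ps = _plot_table([[4.0]], condition=PS)  # only L0 present in PS
        with pytest.warns(UserWarning):
            out = ms_ps_yield_ratio(pd.concat([ms, ps], ignore_index=True))
        ratios = out.loc[out["condition"] == MS].set_index("line")["ms_ps_ratio"]
        assert ratios["L0"] == pytest.approx(1.0)
        assert np.isnan(ratios["L1"])


class TestLineMeans:
    def test_mean_of_three_plots(self):
        t = _plot_table([[1.0], [2.0], [3.0]])
        lm = line_means(t, "pea_yield")
        assert lm.loc["L0", "mean"] == pytest.approx(2.0)
        assert lm.loc["L0", "n"] == 3

    def test_empty_scope_errors(self, toy_trial_table):
        with pytest.raises(DesignError):
            line_means(toy_trial_table, "pea_yield", year="no-such-year")


class TestAnova:
    def test_matches_statsmodels_oracle_on_balanced_toy(self, toy_trial_table):
        import statsmodels.api as smapi
        import statsmodels.formula.api as smf

        tab = anova(toy_trial_table, "pea_yield", "full")
        fit = smf.ols(
            "pea_yield ~ C(year)*C(condition)*C(line) + C(year):C(block)"
            " + C(condition):C(year):C(block)",
            data=toy_trial_table,
        ).fit()
        oracle = smapi.stats.anova_lm(fit, typ=1)
        pairs = {
            "year": "C(year)",
            "condition": "C(condition)",
            "line": "C(line)",
            "line:condition": "C(condition):C(line)",
            "line:year": "C(year):C(line)",
            "line:condition:year": "C(year):C(condition):C(line)",
            "block(year)": "C(year):C(block)",
            "condition:block(year)": "C(condition):C(year):C(block)",
            "residual": "Residual",
        }
        for mine, theirs in pairs.items():
            assert tab.loc[mine, "ss"] == pytest.approx(
                oracle.loc[theirs, "sum_sq"], rel=1e-9
            )
        assert tab.loc["residual", "df"] == oracle.loc["Residual", "df"]

    def test_ss_sums_to_total(self, toy_trial_table):
        for model, kw in [
            ("full", {}),
            ("split_plot", {"year": "Y1"}),
            ("line_year", {"condition": MS}),
            ("line_block", {"condition": MS, "year": "Y1"}),
        ]:
            sub = toy_trial_table
            if "condition" in kw:
                sub = sub[sub["condition"] == kw["condition"]]
            if "year" in kw:
                sub = sub[sub["year"] == kw["year"]]
            total = ((sub["pea_yield"] - sub["pea_yield"].mean()) ** 2).sum()
            tab = anova(toy_trial_table, "pea_yield", model, **kw)
            assert tab["ss"].sum() == pytest.approx(total, rel=1e-9)

    def test_f_invariant_to_affine_shift_and_scale(self, toy_trial_table):
        base = anova(toy_trial_table, "pea_yield", "split_plot", year="Y1")
        shifted = toy_trial_table.copy()
        shifted["pea_yield"] = 3.0 * shifted["pea_yield"] + 11.0
        other = anova(shifted, "pea_yield", "split_plot", year="Y1")
        assert np.allclose(
            base["F"].dropna(), other["F"].dropna(), rtol=1e-9
        )

    def test_type_one_error_calibration_under_null(self):
        # no line variance: the line effect should reject at ~5%
        rng = np.random.default_rng(11)
        hits = 0
        n_rep = 1000
        for _ in range(n_rep):
            t = _plot_table(rng.normal(5, 1, size=(3, 10)))
            tab = anova(t, "pea_yield", "line_block")
            hits += tab.loc["line", "p"] < 0.05
        assert hits / n_rep == pytest.approx(0.05, abs=0.022)

    def test_unbalanced_rejected_with_reml_hint(self, toy_trial_table):
        broken = toy_trial_table.drop(index=[0])
        with pytest.raises(DesignError, match="reml"):
            anova(broken, "pea_yield", "full")


class TestVarianceComponents:
    def test_noise_free_construction(self):
        # plots exactly equal to line values: sigma2_e == 0
        t = _plot_table([[1.0, 2.0, 3.0]] * 3)
        vc = variance_components(t, "pea_yield", "line_block")
        assert vc.sigma2_e == pytest.approx(0.0, abs=1e-12)
        assert vc.sigma2_g == pytest.approx(1.0)  # var of (1,2,3)

    def test_negative_estimate_truncated(self):
        rng = np.random.default_rng(0)
        # pure noise, tiny design: negative MoM solutions happen
        seen = False
        for seed in range(20):
            rng = np.random.default_rng(seed)
            t = _plot_table(rng.normal(0, 1, size=(3, 4)))
            vc = variance_components(t, "pea_yield", "line_block")
            assert vc.sigma2_g >= 0
            seen = seen or "sigma2_g" in vc.truncated
        assert seen

    def test_moments_equal_reml_on_balanced_data(self):
        # interior solution (all components clearly positive): EMS method
        # of moments coincides with REML on balanced data
        rng = np.random.default_rng(3)
        g = rng.normal(0, 1.0, 8)
        rows = []
        for year in ("Y1", "Y2"):
            gy = rng.normal(0, 0.7, 8)
            for block in (1, 2, 3):
                for i in range(8):
                    rows.append(
                        {
                            "year": year, "condition": MS, "block": block,
                            "population": "p", "line": f"L{i}", "is_parent": False,
                            "pea_yield": 5 + g[i] + gy[i] + rng.normal(0, 0.5),
                        }
                    )
        t = pd.DataFrame(rows)
        mom = variance_components(t, "pea_yield", "line_year")
        assert not mom.truncated
        reml = variance_components(t, "pea_yield", "line_year", method="reml")
        assert reml.sigma2_e == pytest.approx(mom.sigma2_e, rel=0.02)
        assert reml.sigma2_g == pytest.approx(mom.sigma2_g, rel=0.02)
        assert reml.sigma2_gy == pytest.approx(mom.sigma2_gy, rel=0.02)

    def test_gxc_ratio_recovered_on_default_scenario(self, default_table):
        # genotype x condition variance well above genotypic variance for
        # yield, consistent with the strong MS/PS specific adaptation
        vc = variance_components(default_table, "pea_yield", "full")
        assert vc.sigma2_gc > vc.sigma2_g


class TestHeritability:
    def test_printed_cv_worked_example(self):
        # CVg=46, CVe=51, n=3 gives the printed 0.71
        assert heritability_from_cv(46, 51, 3) == pytest.approx(0.71, abs=0.005)

    def test_zero_error_gives_one(self):
        vc = VarianceComponents(sigma2_g=2.0, sigma2_e=0.0, n=3)
        assert heritability(vc).H2 == pytest.approx(1.0)

    def test_over_years_arithmetic(self):
        vc = VarianceComponents(sigma2_g=1.0, sigma2_e=1.0, sigma2_gy=1.0, n=3, y=2)
        est = heritability(vc, basis="over-years")
        assert est.H2 == pytest.approx(1.0 / (1 + 0.5 + 1.0 / 6.0))

    def test_monotone_in_sigma2_g_and_n(self):
        h = [
            heritability(VarianceComponents(sigma2_g=g, sigma2_e=1.0, n=3)).H2
            for g in (0.1, 0.5, 2.0)
        ]
        assert h == sorted(h)
        hn = [
            heritability(VarianceComponents(sigma2_g=1.0, sigma2_e=1.0, n=n)).H2
            for n in (1, 3, 9)
        ]
        assert hn == sorted(hn)
        assert all(0 <= x <= 1 for x in h + hn)

    def test_all_zero_components_undefined(self):
        with pytest.raises(DesignError):
            heritability(VarianceComponents(sigma2_g=0.0, sigma2_e=0.0, n=3))

    def test_se_matches_delta_method_scale(self, default_table):
        vc = variance_components(
            default_table, "pea_yield", "line_block", condition=MS, year="2018-19"
        )
        est = heritability(vc)
        assert est.se == pytest.approx(
            (1 - est.H2) * np.sqrt(2 / vc.dfs["line"] + 2 / vc.dfs["residual"])
        )


class TestBlup:
    @pytest.mark.parametrize("h2, expected", [(1.0, 2.0), (0.0, 1.0), (0.7, 1.7)])
    def test_shrinkage_arithmetic(self, h2, expected):
        # mu = 1.0 over two lines with means 0.0 and 2.0
        t = _plot_table([[0.0, 2.0]] * 3)
        b = blup_line_values(t, "pea_yield", "Y1", MS, h2=h2)
        assert b["L1"] == pytest.approx(expected)

    def test_ranking_preserved(self, default_table):
        means = line_means(default_table, "pea_yield", MS, "2018-19")["mean"]
        blups = blup_line_values(default_table, "pea_yield", "2018-19", MS)
        assert (
            means.sort_values().index == blups.loc[means.index].sort_values().index
        ).all()
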