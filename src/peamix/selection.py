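"""Selection strategies: index construction, relative-efficiency formulas,
and the year-swap realized-gain protocol.

Three ways of expressing the efficiency of an alternative selection
criterion relative to direct phenotypic selection for pea yield in
mixture (MS), all in percent of the direct strategy:

* heritability-based (Falconer): ``E_R = (H_ind / H_dir) · r_g · 100``
  with H the square root of line-mean H²;
* correlation-based: ``E_R = (r̄_ind / r̄_dir) · 100`` using phenotypic
  correlations between criterion values in a selection year and MS yield
  in the other (target) year, averaged over the two year assignments;
* gain-based: ``E_R = (G_crit / G_dir) · 100`` from realized year-swap
  gains (select top-2 lines per RIL population in one year, measure
  their MS yield against the parent mean in the other year).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .trial import MS, line_means


class SelectionError(ValueError):
    pass


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


# -- selection index ---------------------------------------------------------


@dataclass
class SelectionIndexModel:
    """Forward-stepwise multiple-regression index of PS-measured traits.

    Weights are the partial regression coefficients of the included
    traits in the final joint fit; ``steps`` records, per entry, the
    trait, its entry p value and the R² increment.
    """

    intercept: float
    weights: dict[str, float]
    entry_order: list[str]
    steps: list[dict] = field(default_factory=list)
    r2: float = 0.0

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "weights": self.weights,
            "entry_order": self.entry_order,
            "r2": self.r2,
            "steps": self.steps,
        }


def fit_selection_index(
    target: pd.Series,
    candidates: pd.DataFrame,
    entry_p: float = 0.05,
    min_delta_r2: float = 0.02,
    collinearity_r: float = 0.95,
) -> SelectionIndexModel:
    """Build the index by forward stepwise OLS on line values.

    At each step the candidate with the smallest coefficient p value
    (when added to the current model) enters if that p value is below
    ``entry_p`` and the R² increment is at least ``min_delta_r2``.
    Candidate traits correlated above ``collinearity_r`` in absolute
    value are rejected up front.  Line values are expected to be
    averaged across cropping years beforehand.
    """
    data = pd.concat([target.rename("_target_"), candidates], axis=1).dropna()
    y = data["_target_"]
    X = data[candidates.columns]
    corr = X.corr().abs()
    np.fill_diagonal(corr.values, 0.0)
    if (corr.values >= collinearity_r).any():
        a, b = np.unravel_index(np.argmax(corr.values), corr.shape)
        raise SelectionError(
            f"candidates {corr.index[a]!r} and {corr.columns[b]!r} are collinear "
            f"(|r| = {corr.values[a, b]:.2f} >= {collinearity_r})"
        )

    included: list[str] = []
    steps: list[dict] = []
    r2_prev = 0.0
    while True:
        best = None
        for cand in X.columns:
            if cand in included:
                continue
            Xc = sm.add_constant(X[included + [cand]])
            fit = sm.OLS(y, Xc).fit()
            p = float(fit.pvalues[cand])
            if best is None or p < best[1]:
                best = (cand, p, float(fit.rsquared))
        if best is None:
            break
        cand, p, r2 = best
        if p >= entry_p or (r2 - r2_prev) < min_delta_r2:
            break
        included.append(cand)
        steps.append({"trait": cand, "p": p, "delta_r2": r2 - r2_prev})
        r2_prev = r2

    if not included:
        return SelectionIndexModel(
            intercept=float(y.mean()), weights={}, entry_order=[], steps=steps, r2=0.0
        )
    final = sm.OLS(y, sm.add_constant(X[included])).fit()
    weights = {t: float(final.params[t]) for t in included}
    if not all(np.isfinite(list(weights.values()))):
        raise SelectionError("non-finite index weights")
    return SelectionIndexModel(
        intercept=float(final.params["const"]),
        weights=weights,
        entry_order=list(included),
        steps=steps,
        r2=float(final.rsquared),
    )


def index_score(model: SelectionIndexModel, traits) -> float | pd.Series | np.ndarray:
    """Evaluate the index: intercept + Σ weight × trait value.

    ``traits`` may be a mapping of scalars, a DataFrame of line values,
    or anything indexable by trait name.
    """
    missing = [t for t in model.weights if t not in traits]
    if missing:
        raise SelectionError(f"missing traits for index evaluation: {missing}")
    score = model.intercept
    for t, w in model.weights.items():
        score = score + w * traits[t]
    return score


def printed_index_model() -> SelectionIndexModel:
    """The published index equation for pea yield in MS from PS traits
    (height in cm, yield in t/ha, flowering onset in days from April 1)."""
    return SelectionIndexModel(
        intercept=-1.413,
        weights={
            "height_flowering": 0.0184,
            "pea_yield": 0.0962,
            "onset_flowering": 0.0476,
        },
        entry_order=["height_flowering", "pea_yield", "onset_flowering"],
    )


def add_index_column(
    table: pd.DataFrame, model: SelectionIndexModel, column: str = "selection_index"
) -> pd.DataFrame:
    """Apply the index to plot-level PS trait values (MS rows get NaN).

    The index is computed per plot with the across-year weights so it can
    be analysed like any other trait (ANOVA across years, variance
    components, heritability).
    """
    out = table.copy()
    is_ps = out["condition"] == "PS"
    score = np.full(len(out), np.nan)
    sub = out.loc[is_ps]
    vals = model.intercept + sum(
        w * sub[t].to_numpy(dtype=float) for t, w in model.weights.items()
    )
    score[is_ps.to_numpy()] = vals
    out[column] = score
    return out


# -- predicted efficiencies --------------------------------------------------


@dataclass
class EfficiencyResult:
    e_r: float  # raw, percent
    method: str
    components: dict = field(default_factory=dict)

    @property
    def e_r_rounded(self) -> int:
        return round_half_up(self.e_r)


def predicted_efficiency_heritability(
    h2_indirect: float, h2_direct: float, r_g: float
) -> EfficiencyResult:
    """Falconer relative efficiency of indirect selection:
    ``E_R = (sqrt(H²_ind)/sqrt(H²_dir)) · r_g · 100``."""
    if not (0 < h2_indirect <= 1) or not (0 < h2_direct <= 1):
        raise SelectionError("heritabilities must lie in (0, 1]")
    if not -1 <= r_g <= 1:
        raise SelectionError("r_g outside [-1, 1]")
    e_r = math.sqrt(h2_indirect) / math.sqrt(h2_direct) * r_g * 100.0
    return EfficiencyResult(
        e_r=e_r,
        method="heritability_based",
        components={"H2_indirect": h2_indirect, "H2_direct": h2_direct, "r_g": r_g},
    )


def predicted_efficiency_correlation(
    r_indirect_by_year, r_direct_by_year
) -> EfficiencyResult:
    """Correlation-based efficiency from year-swap phenotypic correlations.

    Each criterion's correlations (selection-year value vs target-year MS
    yield, one per year assignment) are averaged first, then
    ``E_R = (r̄_ind / r̄_dir) · 100``.
    """
    r_ind = float(np.mean(list(r_indirect_by_year)))
    r_dir = float(np.mean(list(r_direct_by_year)))
    if r_dir == 0:
        raise SelectionError("direct-criterion mean correlation is zero")
    return EfficiencyResult(
        e_r=r_ind / r_dir * 100.0,
        method="correlation_based",
        components={"r_indirect": r_ind, "r_direct": r_dir},
    )


# -- realized gains ----------------------------------------------------------


@dataclass
class GainReport:
    selection_year: str
    evaluation_year: str
    criterion: str
    selected: dict[str, list[str]]  # population -> selected line ids
    mean_selected_yield: float
    parent_mean: float
    gain: float


def year_swap_gain(
    table: pd.DataFrame,
    scores: pd.Series,
    selection_year: str,
    evaluation_year: str,
    criterion: str = "criterion",
    k: int = 2,
) -> GainReport:
    """Select top-k non-parent lines per population by ``scores`` (values
    observed in the selection year) and measure their mean MS yield in the
    evaluation year against the parent-line mean.

    Ties in the criterion break deterministically by ascending line id.
    """
    eval_means = line_means(table, "pea_yield", condition=MS, year=evaluation_year)["mean"]
    meta = table[["line", "population", "is_parent"]].drop_duplicates().set_index("line")
    parents = meta.index[meta["is_parent"]]
    if len(parents) == 0:
        raise SelectionError("no parent lines in the table")
    selected: dict[str, list[str]] = {}
    chosen: list[str] = []
    for pop, group in meta[~meta["is_parent"]].groupby("population", observed=True):
        pop_scores = scores.reindex(group.index).dropna()
        if len(pop_scores) < k:
            raise SelectionError(
                f"population {pop!r} has {len(pop_scores)} scored lines < k={k}"
            )
        order = pop_scores.sort_index().sort_values(ascending=False, kind="stable")
        top = list(order.index[:k])
        selected[pop] = top
        chosen.extend(top)
    mean_sel = float(eval_means.reindex(chosen).mean())
    parent_mean = float(eval_means.reindex(parents).mean())
    return GainReport(
        selection_year=selection_year,
        evaluation_year=evaluation_year,
        criterion=criterion,
        selected=selected,
        mean_selected_yield=mean_sel,
        parent_mean=parent_mean,
        gain=mean_sel - parent_mean,
    )


def relative_efficiency_from_gains(gains_by_year: dict) -> EfficiencyResult:
    """Gain-based efficiency, with the reporting rounding convention.

    ``gains_by_year`` maps selection year -> (G_criterion, G_directMS).
    Per year ``E_R = (G_crit/G_dir)·100`` is rounded half-up to an
    integer; the reported value is the half-up-rounded average of the
    per-year integers.  The raw (unrounded) average is retained in the
    result's components.
    """
    per_year_raw, per_year_int = {}, {}
    for year, (g_sc, g_ms) in gains_by_year.items():
        if g_ms <= 0:
            raise SelectionError(f"direct-selection gain non-positive in {year}")
        e = g_sc / g_ms * 100.0
        per_year_raw[year] = e
        per_year_int[year] = round_half_up(e)
    avg_int = float(np.mean(list(per_year_int.values())))
    return EfficiencyResult(
        e_r=float(round_half_up(avg_int)),
        method="gain_based",
        components={
            "per_year": per_year_raw,
            "per_year_rounded": per_year_int,
            "raw_average": float(np.mean(list(per_year_raw.values()))),
        },
    )


def per_unit_time_adjustment(e_r: float, cycles_ratio: float) -> EfficiencyResult:
    """Efficiency per unit time: multiply by the ratio of selection cycles
    per year (genomic selection can run two cycles where phenotypic
    selection runs one)."""
    if cycles_ratio <= 0:
        raise SelectionError("cycles_ratio must be positive")
    return EfficiencyResult(
        e_r=e_r * cycles_ratio,
        method="per_unit_time",
        components={"base_e_r": e_r, "cycles_ratio": cycles_ratio},
    )
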