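"""Plot-level trial model: derived mixture traits, ANOVA, variance components,
broad-sense heritability and shrunken line values (BLUPs).

The trial layout is a split plot repeated over cropping years: growing
condition (pure stand PS vs mixed stand MS) on main plots, pea lines on
subplots, blocks nested within year.  All classical analyses here assume
balanced data, where expected-mean-square (EMS) method-of-moments
estimates coincide with REML; an iterative EM-REML routine is provided
as a cross-check and as the fallback for unbalanced tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

MS = "MS"
PS = "PS"

#: columns every trial table must carry
DESIGN_COLUMNS = ("year", "condition", "block", "population", "line", "is_parent")


class DesignError(ValueError):
    """Raised when a table does not meet a balanced-design precondition."""


def validate_trial_table(table: pd.DataFrame, allow_negative_yields: bool = True) -> None:
    """Structural checks on a trial table.

    Negative yields are flagged only when ``allow_negative_yields`` is
    False (externally loaded field data); the Gaussian generator can
    legitimately produce small negative plot yields at high error CV.
    """
    missing = [c for c in DESIGN_COLUMNS if c not in table.columns]
    if missing:
        raise DesignError(f"trial table lacks design columns: {missing}")
    if not allow_negative_yields:
        for col in ("pea_yield", "cereal_yield", "total_yield"):
            if col in table.columns and (table[col].dropna() < 0).any():
                raise DesignError(f"negative values in {col}")
    if "pea_proportion" in table.columns:
        pp = table["pea_proportion"].dropna()
        if ((pp < 0) | (pp > 1)).any():
            raise DesignError("pea_proportion outside [0, 1]")


def check_balance(table: pd.DataFrame, trait: str) -> bool:
    """True when every (year, condition, block, line) cell has exactly one
    non-missing observation of ``trait``."""
    sub = table.dropna(subset=[trait])
    counts = sub.groupby(["year", "condition", "block"], observed=True)["line"].nunique()
    n_lines = sub["line"].nunique()
    per_cell = sub.groupby(["year", "condition", "block", "line"], observed=True)[trait].count()
    return bool((counts == n_lines).all() and (per_cell == 1).all())


# -- derived traits ----------------------------------------------------------


def derive_mixture_traits(table: pd.DataFrame) -> pd.DataFrame:
    """Add total mixture yield and pea proportion to MS records.

    ``total_yield = pea + cereal``; ``pea_proportion = pea / total``.
    Plots with zero total yield get a missing proportion.  PS records are
    untouched (NaN in the derived columns).
    """
    out = table.copy()
    is_ms = out["condition"] == MS
    pea = out.loc[is_ms, "pea_yield"]
    cereal = out.loc[is_ms, "cereal_yield"]
    total = pea + cereal
    out.loc[is_ms, "total_yield"] = total
    with np.errstate(invalid="ignore", divide="ignore"):
        prop = pea / total
    prop = prop.where(total != 0)
    out.loc[is_ms, "pea_proportion"] = prop
    return out


def ms_ps_yield_ratio(table: pd.DataFrame) -> pd.DataFrame:
    """Per-MS-plot ratio of (doubled) pea yield in MS to the line's mean
    PS yield in the same year.

    Pea occupies half the area in mixture, so its MS plot yield is
    doubled to put the ratio on an equal-area basis; the PS term is the
    line's mean over blocks ("imputing the mean yield in PS").  Lines
    without PS records in a year, or with zero PS mean, get a missing
    ratio with a warning.
    """
    out = table.copy()
    ps_means = (
        table[table["condition"] == PS]
        .groupby(["year", "line"], observed=True)["pea_yield"]
        .mean()
    )
    is_ms = out["condition"] == MS
    keys = list(zip(out.loc[is_ms, "year"], out.loc[is_ms, "line"]))
    denom = np.array([ps_means.get(k, np.nan) for k in keys])
    n_absent = int(np.isnan(denom).sum())
    zero = denom == 0
    if n_absent or zero.any():
        warnings.warn(
            f"MS/PS ratio undefined for {n_absent} plots without PS records "
            f"and {int(zero.sum())} plots with zero PS mean"
        )
    denom = np.where(zero, np.nan, denom)
    out.loc[is_ms, "ms_ps_ratio"] = 2.0 * out.loc[is_ms, "pea_yield"].to_numpy() / denom
    return out


def line_means(
    table: pd.DataFrame,
    trait: str,
    condition: str | None = None,
    year: str | None = None,
) -> pd.DataFrame:
    """Per-line means of ``trait`` over the selected scope.

    Returns a DataFrame indexed by line with columns ``mean`` and ``n``
    (replicates averaged).
    """
    sub = table
    if condition is not None:
        sub = sub[sub["condition"] == condition]
    if year is not None:
        sub = sub[sub["year"] == year]
    sub = sub.dropna(subset=[trait])
    if len(sub) == 0:
        raise DesignError(f"no observations of {trait} in the requested scope")
    g = sub.groupby("line", observed=True)[trait]
    return pd.DataFrame({"mean": g.mean(), "n": g.count()})


# -- balanced ANOVA engine ---------------------------------------------------


def _classification_ss(df: pd.DataFrame, trait: str, factors: list[str]) -> float:
    """SS of the cell-mean classification on ``factors``, corrected for
    the grand mean (balanced data)."""
    grand = df[trait].mean()
    cells = df.groupby(factors, observed=True)[trait].agg(["mean", "count"])
    return float((cells["count"] * (cells["mean"] - grand) ** 2).sum())


def _require_balanced(table: pd.DataFrame, trait: str) -> pd.DataFrame:
    sub = table.dropna(subset=[trait]).copy()
    if not check_balance(sub, trait):
        raise DesignError(
            f"unbalanced data for {trait}: EMS-based ANOVA requires a complete "
            "layout; use variance_components(..., method='reml')"
        )
    return sub


def _anova_frame(rows: list[dict]) -> pd.DataFrame:
    out = pd.DataFrame(rows).set_index("source")
    out["ms"] = out["ss"] / out["df"]
    fs, ps = [], []
    for _, row in out.iterrows():
        err = row["error_term"]
        if err is None or err not in out.index:
            fs.append(np.nan)
            ps.append(np.nan)
            continue
        ms_err = out.loc[err, "ms"]
        F = row["ms"] / ms_err if ms_err > 0 else np.inf
        fs.append(F)
        ps.append(float(stats.f.sf(F, row["df"], out.loc[err, "df"])))
    out["F"] = fs
    out["p"] = ps
    return out[["df", "ss", "ms", "F", "p", "error_term"]]


def anova(
    table: pd.DataFrame,
    trait: str,
    model: str,
    condition: str | None = None,
    year: str | None = None,
) -> pd.DataFrame:
    """Balanced-design ANOVA with the error strata of the trial layout.

    ``model`` is one of:

    * ``"line_block"`` — lines + blocks within one condition × year;
    * ``"split_plot"`` — condition (main plot, tested against
      condition × block) and lines (subplots) within one year;
    * ``"line_year"`` — lines × years with blocks nested in years,
      within one condition; lines are tested against line × year
      (years regarded as a random sample of seasons);
    * ``"full"`` — line × condition × year; condition and
      condition × year are tested against condition × block within year.
    """
    sub = table
    if condition is not None:
        sub = sub[sub["condition"] == condition]
    if year is not None:
        sub = sub[sub["year"] == year]
    sub = _require_balanced(sub, trait)

    def S(*factors: str) -> float:
        return _classification_ss(sub, trait, list(factors))

    total_ss = float(((sub[trait] - sub[trait].mean()) ** 2).sum())
    g = sub["line"].nunique()
    n = sub["block"].nunique()
    Y = sub["year"].nunique()
    C = sub["condition"].nunique()

    if model == "line_block":
        if Y != 1 or C != 1:
            raise DesignError("line_block model needs a single condition and year")
        ss_l, ss_b = S("line"), S("block")
        rows = [
            {"source": "line", "df": g - 1, "ss": ss_l, "error_term": "residual"},
            {"source": "block", "df": n - 1, "ss": ss_b, "error_term": "residual"},
            {
                "source": "residual",
                "df": (g - 1) * (n - 1),
                "ss": total_ss - ss_l - ss_b,
                "error_term": None,
            },
        ]
    elif model == "split_plot":
        if Y != 1 or C != 2:
            raise DesignError("split_plot model needs both conditions in a single year")
        ss_c, ss_b, ss_l = S("condition"), S("block"), S("line")
        ss_cb = S("condition", "block") - ss_c - ss_b
        ss_lc = S("line", "condition") - ss_l - ss_c
        resid = total_ss - ss_c - ss_b - ss_cb - ss_l - ss_lc
        rows = [
            {"source": "block", "df": n - 1, "ss": ss_b, "error_term": "condition:block"},
            {"source": "condition", "df": C - 1, "ss": ss_c, "error_term": "condition:block"},
            {
                "source": "condition:block",
                "df": (C - 1) * (n - 1),
                "ss": ss_cb,
                "error_term": None,
            },
            {"source": "line", "df": g - 1, "ss": ss_l, "error_term": "residual"},
            {
                "source": "line:condition",
                "df": (g - 1) * (C - 1),
                "ss": ss_lc,
                "error_term": "residual",
            },
            {
                "source": "residual",
                "df": C * (g - 1) * (n - 1),
                "ss": resid,
                "error_term": None,
            },
        ]
    elif model == "line_year":
        if C != 1 or Y < 2:
            raise DesignError("line_year model needs one condition and >= 2 years")
        ss_y, ss_l = S("year"), S("line")
        ss_by = S("year", "block") - ss_y
        ss_ly = S("line", "year") - ss_l - ss_y
        resid = total_ss - ss_y - ss_by - ss_l - ss_ly
        rows = [
            {"source": "year", "df": Y - 1, "ss": ss_y, "error_term": "block(year)"},
            {"source": "block(year)", "df": Y * (n - 1), "ss": ss_by, "error_term": None},
            {"source": "line", "df": g - 1, "ss": ss_l, "error_term": "line:year"},
            {
                "source": "line:year",
                "df": (g - 1) * (Y - 1),
                "ss": ss_ly,
                "error_term": "residual",
            },
            {
                "source": "residual",
                "df": Y * (g - 1) * (n - 1),
                "ss": resid,
                "error_term": None,
            },
        ]
    elif model == "full":
        if C != 2 or Y < 2:
            raise DesignError("full model needs both conditions and >= 2 years")
        ss_y, ss_c, ss_l = S("year"), S("condition"), S("line")
        ss_by = S("year", "block") - ss_y
        ss_cy = S("condition", "year") - ss_c - ss_y
        ss_cby = S("condition", "year", "block") - S("year", "block") - ss_c - ss_cy
        ss_lc = S("line", "condition") - ss_l - ss_c
        ss_ly = S("line", "year") - ss_l - ss_y
        ss_lcy = (
            S("line", "condition", "year") - ss_l - ss_c - ss_y - ss_lc - ss_ly - ss_cy
        )
        resid = (
            total_ss - ss_y - ss_by - ss_c - ss_cy - ss_cby - ss_l - ss_lc - ss_ly - ss_lcy
        )
        rows = [
            {"source": "year", "df": Y - 1, "ss": ss_y, "error_term": "block(year)"},
            {"source": "block(year)", "df": Y * (n - 1), "ss": ss_by, "error_term": None},
            {
                "source": "condition",
                "df": C - 1,
                "ss": ss_c,
                "error_term": "condition:block(year)",
            },
            {
                "source": "condition:year",
                "df": (C - 1) * (Y - 1),
                "ss": ss_cy,
                "error_term": "condition:block(year)",
            },
            {
                "source": "condition:block(year)",
                "df": (C - 1) * Y * (n - 1),
                "ss": ss_cby,
                "error_term": None,
            },
            {"source": "line", "df": g - 1, "ss": ss_l, "error_term": "residual"},
            {
                "source": "line:condition",
                "df": (g - 1) * (C - 1),
                "ss": ss_lc,
                "error_term": "residual",
            },
            {
                "source": "line:year",
                "df": (g - 1) * (Y - 1),
                "ss": ss_ly,
                "error_term": "residual",
            },
            {
                "source": "line:condition:year",
                "df": (g - 1) * (C - 1) * (Y - 1),
                "ss": ss_lcy,
                "error_term": "residual",
            },
            {
                "source": "residual",
                "df": C * Y * (g - 1) * (n - 1),
                "ss": resid,
                "error_term": None,
            },
        ]
    else:
        raise DesignError(f"unknown ANOVA model: {model!r}")
    return _anova_frame(rows)


# -- variance components -----------------------------------------------------


@dataclass
class VarianceComponents:
    """REML/EMS variance components for the line (genotype) factor.

    Components that the fitted model does not contain stay at ``None``.
    Negative method-of-moments solutions are truncated at zero and the
    component name recorded in ``truncated``.
    """

    sigma2_g: float
    sigma2_e: float
    sigma2_gy: float | None = None
    sigma2_gc: float | None = None
    sigma2_gcy: float | None = None
    n: int = 3
    y: int = 1
    c: int = 1
    method: str = "moments"
    truncated: list = field(default_factory=list)
    mean_squares: dict = field(default_factory=dict)
    dfs: dict = field(default_factory=dict)
    grand_mean: float | None = None


def _truncate(name: str, value: float, truncated: list) -> float:
    if value < 0:
        truncated.append(name)
        return 0.0
    return value


def variance_components(
    table: pd.DataFrame,
    trait: str,
    model: str = "line_block",
    condition: str | None = None,
    year: str | None = None,
    method: str = "moments",
) -> VarianceComponents:
    """Variance components for the random line factor and its interactions.

    ``method="moments"`` equates observed to expected mean squares on
    balanced data (exact REML there); ``method="reml"`` runs EM-REML on
    the equivalent mixed model and accepts unbalanced data.
    """
    if method == "reml":
        return _reml_components(table, trait, model, condition, year)
    tab = anova(table, trait, model, condition=condition, year=year)
    sub = table
    if condition is not None:
        sub = sub[sub["condition"] == condition]
    if year is not None:
        sub = sub[sub["year"] == year]
    sub = sub.dropna(subset=[trait])
    n = sub["block"].nunique()
    Y = sub["year"].nunique()
    C = sub["condition"].nunique()
    ms = tab["ms"].to_dict()
    dfs = tab["df"].to_dict()
    truncated: list = []
    grand = float(sub[trait].mean())

    if model == "line_block":
        s2e = ms["residual"]
        s2g = _truncate("sigma2_g", (ms["line"] - ms["residual"]) / n, truncated)
        vc = VarianceComponents(s2g, s2e, n=n, truncated=truncated)
    elif model == "line_year":
        s2e = ms["residual"]
        s2gy = _truncate("sigma2_gy", (ms["line:year"] - ms["residual"]) / n, truncated)
        s2g = _truncate("sigma2_g", (ms["line"] - ms["line:year"]) / (n * Y), truncated)
        vc = VarianceComponents(s2g, s2e, sigma2_gy=s2gy, n=n, y=Y, truncated=truncated)
    elif model == "full":
        s2e = ms["residual"]
        s2gcy = _truncate(
            "sigma2_gcy", (ms["line:condition:year"] - ms["residual"]) / n, truncated
        )
        s2gc = _truncate(
            "sigma2_gc",
            (ms["line:condition"] - ms["line:condition:year"]) / (n * Y),
            truncated,
        )
        s2gy = _truncate(
            "sigma2_gy",
            (ms["line:year"] - ms["line:condition:year"]) / (n * C),
            truncated,
        )
        s2g = _truncate(
            "sigma2_g",
            (
                ms["line"]
                - ms["line:condition"]
                - ms["line:year"]
                + ms["line:condition:year"]
            )
            / (n * C * Y),
            truncated,
        )
        vc = VarianceComponents(
            s2g, s2e, sigma2_gy=s2gy, sigma2_gc=s2gc, sigma2_gcy=s2gcy,
            n=n, y=Y, c=C, truncated=truncated,
        )
    elif model == "split_plot":
        s2e = ms["residual"]
        s2gc = _truncate(
            "sigma2_gc", (ms["line:condition"] - ms["residual"]) / n, truncated
        )
        s2g = _truncate(
            "sigma2_g", (ms["line"] - ms["line:condition"]) / (n * C), truncated
        )
        vc = VarianceComponents(s2g, s2e, sigma2_gc=s2gc, n=n, c=C, truncated=truncated)
    else:
        raise DesignError(f"unknown model for variance components: {model!r}")
    vc.mean_squares = {k: float(v) for k, v in ms.items()}
    vc.dfs = {k: int(v) for k, v in dfs.items()}
    vc.grand_mean = grand
    return vc


def _reml_components(table, trait, model, condition, year) -> VarianceComponents:
    """EM-REML for the mixed model matching ``model``.

    Fixed effects: blocks (and year / condition structure); random
    effects: line and its interactions.  Used as a cross-check on
    balanced data and as the estimator for unbalanced tables.
    """
    sub = table
    if condition is not None:
        sub = sub[sub["condition"] == condition]
    if year is not None:
        sub = sub[sub["year"] == year]
    sub = sub.dropna(subset=[trait]).copy()
    yv = sub[trait].to_numpy(dtype=float)

    def dummies(keys: pd.Series) -> np.ndarray:
        return pd.get_dummies(keys.astype(str)).to_numpy(dtype=float)

    if model == "line_block":
        X = np.column_stack([np.ones(len(sub)), dummies(sub["block"])[:, 1:]])
        Zs = {"sigma2_g": dummies(sub["line"])}
    elif model == "line_year":
        fixed = pd.get_dummies(
            sub["year"].astype(str) + ":" + sub["block"].astype(str)
        ).to_numpy(dtype=float)
        X = np.column_stack([np.ones(len(sub)), fixed[:, 1:]])
        Zs = {
            "sigma2_g": dummies(sub["line"]),
            "sigma2_gy": dummies(sub["line"].astype(str) + ":" + sub["year"].astype(str)),
        }
    elif model == "full":
        fixed = pd.get_dummies(
            sub["condition"].astype(str)
            + ":"
            + sub["year"].astype(str)
            + ":"
            + sub["block"].astype(str)
        ).to_numpy(dtype=float)
        X = np.column_stack([np.ones(len(sub)), fixed[:, 1:]])
        Zs = {
            "sigma2_g": dummies(sub["line"]),
            "sigma2_gc": dummies(sub["line"].astype(str) + ":" + sub["condition"].astype(str)),
            "sigma2_gy": dummies(sub["line"].astype(str) + ":" + sub["year"].astype(str)),
            "sigma2_gcy": dummies(
                sub["line"].astype(str)
                + ":"
                + sub["condition"].astype(str)
                + ":"
                + sub["year"].astype(str)
            ),
        }
    else:
        raise DesignError(f"REML not implemented for model {model!r}")

    comps = _em_reml(yv, X, Zs)
    vc = VarianceComponents(
        sigma2_g=comps["sigma2_g"],
        sigma2_e=comps["sigma2_e"],
        sigma2_gy=comps.get("sigma2_gy"),
        sigma2_gc=comps.get("sigma2_gc"),
        sigma2_gcy=comps.get("sigma2_gcy"),
        n=sub["block"].nunique(),
        y=sub["year"].nunique(),
        c=sub["condition"].nunique(),
        method="reml",
    )
    vc.grand_mean = float(yv.mean())
    return vc


def _em_reml(y, X, Zs, max_iter=2000, tol=1e-10):
    """Plain EM-REML on the mixed-model equations.

    Convergence failures fall back to the last iterate with a warning
    (callers on balanced data cross-check against method of moments).
    """
    n = len(y)
    names = list(Zs)
    Z = np.column_stack([Zs[k] for k in names])
    qs = [Zs[k].shape[1] for k in names]
    offsets = np.cumsum([0] + qs)
    var = {k: float(np.var(y)) / (len(names) + 1) or 1.0 for k in names}
    s2e = float(np.var(y)) / (len(names) + 1) or 1.0
    p = X.shape[1]
    for it in range(max_iter):
        lam = np.concatenate(
            [np.full(q, s2e / max(var[k], 1e-12)) for k, q in zip(names, qs)]
        )
        # MME coefficient matrix
        XtX = X.T @ X
        XtZ = X.T @ Z
        ZtZ = Z.T @ Z + np.diag(lam)
        Cmat = np.block([[XtX, XtZ], [XtZ.T, ZtZ]])
        rhs = np.concatenate([X.T @ y, Z.T @ y])
        Cinv = np.linalg.pinv(Cmat)
        sol = Cinv @ rhs
        u = sol[p:]
        e = y - X @ sol[:p] - Z @ u
        new_var = {}
        for k, q, o in zip(names, qs, offsets):
            uk = u[o : o + q]
            Ckk = Cinv[p + o : p + o + q, p + o : p + o + q]
            new_var[k] = float((uk @ uk + s2e * np.trace(Ckk)) / q)
        new_s2e = float((e @ y) / (n - p))
        delta = abs(new_s2e - s2e) + sum(abs(new_var[k] - var[k]) for k in names)
        var, s2e = new_var, max(new_s2e, 1e-12)
        if delta < tol:
            break
    else:
        warnings.warn("EM-REML did not converge; returning last iterate")
    out = {k: max(v, 0.0) for k, v in var.items()}
    out["sigma2_e"] = s2e
    return out


# -- heritability ------------------------------------------------------------


@dataclass
class HeritabilityEstimate:
    """Broad-sense heritability on a line-mean basis."""

    H2: float
    se: float | None
    basis: str  # "single-environment" | "over-years"

    @property
    def H(self) -> float:
        return float(np.sqrt(self.H2))


def heritability_from_cv(cv_g: float, cv_e: float, n: int) -> float:
    """H² from genetic and error coefficients of variation: because the
    grand mean cancels, H² = CVg² / (CVg² + CVe²/n)."""
    return cv_g**2 / (cv_g**2 + cv_e**2 / n)


def heritability(
    components: VarianceComponents, basis: str = "single-environment"
) -> HeritabilityEstimate:
    """Line-mean broad-sense heritability.

    * single environment: ``H² = s2g / (s2g + s2e/n)``;
    * over years: ``H² = s2g / (s2g + s2gy/y + s2e/(y n))``.

    The approximate standard error is a delta-method result on the
    mean-square ratio: on balanced data H² = 1 − MS_err/MS_line (with
    MS_err the line × year mean square on the over-years basis), whose
    variance follows from the chi-square sampling variance of each mean
    square: ``se ≈ (1 − H²) sqrt(2/df_num + 2/df_den)``.
    """
    n, y = components.n, components.y
    s2g, s2e = components.sigma2_g, components.sigma2_e
    if basis == "single-environment":
        denom = s2g + s2e / n
        num_df, den_df = components.dfs.get("line"), components.dfs.get("residual")
    elif basis == "over-years":
        if components.sigma2_gy is None:
            raise DesignError("over-years H2 needs sigma2_gy (line_year model)")
        denom = s2g + components.sigma2_gy / y + s2e / (y * n)
        num_df, den_df = components.dfs.get("line"), components.dfs.get("line:year")
    else:
        raise DesignError(f"unknown heritability basis: {basis!r}")
    if denom <= 0:
        raise DesignError("all variance components are zero; H2 undefined")
    H2 = float(np.clip(s2g / denom, 0.0, 1.0))
    se = None
    if num_df and den_df:
        se = float((1.0 - H2) * np.sqrt(2.0 / num_df + 2.0 / den_df))
    return HeritabilityEstimate(H2=H2, se=se, basis=basis)


# -- shrunken line values ----------------------------------------------------


def blup_line_values(
    table: pd.DataFrame,
    trait: str,
    year: str,
    condition: str,
    h2: float | None = None,
) -> pd.Series:
    """Per-line BLUPs as heritability-shrunken line means.

    ``BLUP_i = mu + H² (ybar_i − mu)`` with H² the single-environment
    line-mean heritability for that year and condition (estimated from
    the data unless supplied).  Equivalent to the one-stage random-line
    prediction on balanced data; preserves the ranking of line means.
    """
    if h2 is None:
        vc = variance_components(table, trait, "line_block", condition=condition, year=year)
        h2 = heritability(vc).H2
    means = line_means(table, trait, condition=condition, year=year)["mean"]
    mu = float(means.mean())
    return mu + h2 * (means - mu)
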