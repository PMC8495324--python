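"""Phenotypic and genetic correlation estimators, and the u test for
comparing two correlation coefficients.

Genetic correlations come in two flavours here: across growing
conditions (traits measured on the same lines in different plots, so
plot errors are independent and the covariance of line means estimates
the genetic covariance — Robertson-style), and across years for one
trait (from the genotypic and genotype × year variance components —
Itoh–Yamada-style).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .trial import VarianceComponents, heritability, line_means, variance_components


class EstimationError(ValueError):
    pass


@dataclass
class CorrelationEstimate:
    r: float
    se: float | None
    kind: str  # phenotypic | genetic_cross_condition | genetic_cross_year
    n: int
    clamped: bool = False


def phenotypic_correlation(x, y) -> CorrelationEstimate:
    """Pearson correlation of paired line (genotype) values."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise EstimationError("need at least 3 paired lines")
    if np.std(x) == 0 or np.std(y) == 0:
        raise EstimationError("zero variance; correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    se = float(np.sqrt((1 - r**2) / (x.size - 2))) if abs(r) < 1 else 0.0
    return CorrelationEstimate(r=r, se=se, kind="phenotypic", n=x.size)


def robertson_genetic_correlation(
    means_a: pd.Series,
    means_b: pd.Series,
    sigma2_g_a: float,
    sigma2_g_b: float,
    h2_a=None,
    h2_b=None,
) -> CorrelationEstimate:
    """Cross-condition genetic correlation from line means.

    Because the two criteria are scored on different plots, their plot
    errors are independent and the covariance of line means is an
    unbiased estimate of the genetic covariance; dividing by the
    genotypic standard deviations (from per-condition variance
    components) gives r_g.  Estimates outside [−1, 1] — possible with
    noisy components — are clamped with a flag.  The approximate SE uses
    the heritability estimates of the two criteria when provided:
    ``SE ≈ ((1 − r_g²)/√2) · sqrt(SE(H²_A)·SE(H²_B)/(H²_A·H²_B))``.
    """
    joined = pd.concat([means_a.rename("a"), means_b.rename("b")], axis=1).dropna()
    if len(joined) < 3:
        raise EstimationError("need at least 3 lines with both criteria")
    if sigma2_g_a <= 0 or sigma2_g_b <= 0:
        raise EstimationError("non-positive genotypic variance; r_g undefined")
    cov = float(np.cov(joined["a"], joined["b"], ddof=1)[0, 1])
    r = cov / np.sqrt(sigma2_g_a * sigma2_g_b)
    clamped = abs(r) > 1
    if clamped:
        warnings.warn(f"genetic correlation {r:.3f} clamped to [-1, 1]")
        r = float(np.clip(r, -1.0, 1.0))
    se = None
    if h2_a is not None and h2_b is not None:
        h2a, sea = (h2_a.H2, h2_a.se) if hasattr(h2_a, "H2") else h2_a
        h2b, seb = (h2_b.H2, h2_b.se) if hasattr(h2_b, "H2") else h2_b
        if h2a > 0 and h2b > 0 and sea is not None and seb is not None:
            se = float((1 - r**2) / np.sqrt(2.0) * np.sqrt(sea * seb / (h2a * h2b)))
    return CorrelationEstimate(
        r=float(r), se=se, kind="genetic_cross_condition", n=len(joined), clamped=clamped
    )


def genetic_correlation_cross_condition(
    table: pd.DataFrame,
    trait_a: str,
    cond_a: str,
    trait_b: str,
    cond_b: str,
    year: str,
) -> CorrelationEstimate:
    """Robertson-style r_g between two criteria scored in different
    growing conditions of the same year."""
    ma = line_means(table, trait_a, condition=cond_a, year=year)["mean"]
    mb = line_means(table, trait_b, condition=cond_b, year=year)["mean"]
    vca = variance_components(table, trait_a, "line_block", condition=cond_a, year=year)
    vcb = variance_components(table, trait_b, "line_block", condition=cond_b, year=year)
    return robertson_genetic_correlation(
        ma, mb, vca.sigma2_g, vcb.sigma2_g,
        h2_a=heritability(vca), h2_b=heritability(vcb),
    )


def genetic_correlation_cross_year(components: VarianceComponents) -> CorrelationEstimate:
    """Itoh–Yamada r_g of one trait across years:
    ``r_g = s2g / (s2g + s2gy)`` from the two-year components within one
    condition."""
    if components.sigma2_gy is None:
        raise EstimationError("needs components from the line_year model")
    s2g, s2gy = components.sigma2_g, components.sigma2_gy
    if s2g + s2gy <= 0:
        raise EstimationError("both components zero; r_g undefined")
    r = s2g / (s2g + s2gy)
    # delta-method SE on the mean-square ratio (r = 1 - MS_gy/MS_g scaled)
    se = None
    if components.dfs:
        df_g = components.dfs.get("line")
        df_gy = components.dfs.get("line:year")
        if df_g and df_gy:
            se = float((1 - r) * np.sqrt(2.0 / df_g + 2.0 / df_gy)) or None
            se = abs(se) if se is not None else None
    return CorrelationEstimate(r=float(r), se=se, kind="genetic_cross_year", n=0)


def dagnelie_u_test(r1: float, n1: int, r2: float, n2: int) -> dict:
    """u test for the difference between two independent correlations.

    Fisher-z transforms each coefficient;
    ``u = (z1 − z2) / sqrt(1/(n1−3) + 1/(n2−3))`` is referred to the
    standard normal (two-sided).  The two samples are treated as
    independent even when they share genotypes — the classical form; see
    the methods note for this limitation.
    """
    for n in (n1, n2):
        if n <= 3:
            raise EstimationError("u test needs n > 3 in both samples")
    for r in (r1, r2):
        if abs(r) >= 1:
            raise EstimationError("|r| = 1 has infinite Fisher z")
    z1, z2 = np.arctanh(r1), np.arctanh(r2)
    u = (z1 - z2) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = 2.0 * stats.norm.sf(abs(u))
    return {"u": float(u), "p": float(p)}


def significance_code(p: float, alpha1: float = 0.05, alpha2: float = 0.01) -> str:
    """NS / * / ** convention used in the correlation tables."""
    if p < alpha2:
        return "**"
    if p < alpha1:
        return "*"
    return "NS"


def correlation_matrix_with_codes(values: pd.DataFrame, traits: list[str]) -> pd.DataFrame:
    """Pairwise phenotypic correlations of line values with NS/*/** codes,
    exported in a long table (trait_a, trait_b, r, p, code)."""
    rows = []
    for i, a in enumerate(traits):
        for b in traits[i + 1 :]:
            est = phenotypic_correlation(values[a], values[b])
            t = est.r * np.sqrt((est.n - 2) / max(1e-12, 1 - est.r**2))
            p = float(2 * stats.t.sf(abs(t), est.n - 2))
            rows.append(
                {"trait_a": a, "trait_b": b, "r": est.r, "n": est.n, "p": p,
                 "code": significance_code(p)}
            )
    return pd.DataFrame(rows)
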