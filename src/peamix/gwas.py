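"""Single-marker association scan with population covariates, genomic
control and Bonferroni thresholding.

The primary scan is ordinary least squares of the phenotype (line values
averaged across years) on marker dosage plus the RIL population
incidence matrix; the Frisch–Waugh residualisation makes the per-marker
loop a vectorised correlation.  Inflation of the test statistics from
residual structure is corrected by genomic control (median chi-square
inflation factor), and the multiple-testing threshold is Bonferroni.
An optional kinship mixed-model scan is provided for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .genomatrix import UNPLACED_CHROM, GenotypeMatrix012

CHI2_MEDIAN = 0.45493642311957283  # median of chi-square with 1 df


class GwasError(ValueError):
    pass


@dataclass
class GwasResult:
    table: pd.DataFrame  # marker, chrom, pos, p_raw, p_gc, score
    lambda_gc: float
    m_tested: int
    alpha: float
    p_threshold: float
    score_threshold: float


def marker_scan(
    gm: GenotypeMatrix012,
    phenotype: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-marker OLS scan: ``y ~ covariates + dosage``.

    ``covariates`` is typically the RIL population incidence matrix (one
    reference column is dropped automatically).  Returns a DataFrame
    (marker, chrom, pos, beta, p_raw); monomorphic markers are flagged
    with ``NaN`` p values.
    """
    lines = [l for l in gm.lines if l in phenotype.index]
    sub = gm.subset(lines=lines)
    y = phenotype.loc[lines].to_numpy(dtype=float)
    X = sub.values
    if np.isnan(X).any():
        raise GwasError("genotypes contain missing values; impute first")
    n = len(lines)
    if covariates is not None:
        C = pd.get_dummies(covariates.loc[lines], drop_first=True).to_numpy(dtype=float)
        C = np.column_stack([np.ones(n), C])
    else:
        C = np.ones((n, 1))
    rank = np.linalg.matrix_rank(C)
    if rank < C.shape[1]:
        raise GwasError("covariate matrix is rank deficient")
    # Frisch-Waugh: residualize phenotype and markers on the covariates
    Q, _ = np.linalg.qr(C)
    y_r = y - Q @ (Q.T @ y)
    X_r = X - Q @ (Q.T @ X)
    df = n - C.shape[1] - 1
    if df <= 0:
        raise GwasError("not enough lines for the covariate model")
    sxx = (X_r**2).sum(axis=0)
    poly = sxx > 1e-12
    beta = np.full(X.shape[1], np.nan)
    pvals = np.full(X.shape[1], np.nan)
    sxy = X_r.T @ y_r
    beta[poly] = sxy[poly] / sxx[poly]
    rss0 = float(y_r @ y_r)
    rss1 = rss0 - beta[poly] * sxy[poly]
    rss1 = np.clip(rss1, 1e-300, None)
    tstat = beta[poly] * np.sqrt(sxx[poly]) / np.sqrt(rss1 / df)
    pvals[poly] = 2.0 * stats.t.sf(np.abs(tstat), df)
    pvals[poly] = np.clip(pvals[poly], 1e-300, 1.0)  # underflow guard
    out = gm.marker_map.copy()
    out.insert(0, "marker", out.index)
    out["beta"] = beta
    out["p_raw"] = pvals
    return out.reset_index(drop=True)


def genomic_control(p_raw: np.ndarray | pd.Series) -> tuple[np.ndarray, float]:
    """Median-based genomic control.

    Raw p values are mapped to 1-df chi-square quantiles;
    ``lambda_GC = median(chi²) / 0.4549``.  When lambda exceeds 1 every
    statistic is deflated by it; lambda below 1 is reported but never
    used to inflate significance.
    """
    p = np.asarray(p_raw, dtype=float)
    ok = ~np.isnan(p)
    if ok.sum() < 10:
        warnings.warn("fewer than 10 markers: lambda_GC is unreliable")
    chi = stats.chi2.isf(p[ok], df=1)
    lam = float(np.median(chi) / CHI2_MEDIAN)
    adj = p.copy()
    if lam > 1:
        adj[ok] = stats.chi2.sf(chi / lam, df=1)
    return adj, lam


def bonferroni_threshold(m: int, alpha: float = 0.05) -> dict:
    """Family-wise threshold over ``m`` tested markers: ``p = alpha/m``
    and its −log10 score."""
    if m <= 0:
        raise GwasError("no markers tested")
    if alpha <= 0 or alpha > 1:
        raise GwasError("alpha must lie in (0, 1]")
    p_thr = alpha / m
    return {"p_threshold": p_thr, "score_threshold": float(-np.log10(p_thr))}


def run_gwas(
    gm: GenotypeMatrix012,
    phenotype: pd.Series,
    covariates: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> GwasResult:
    """Full scan: OLS + genomic control + Bonferroni."""
    scan = marker_scan(gm, phenotype, covariates)
    adj, lam = genomic_control(scan["p_raw"].to_numpy())
    scan["p_gc"] = adj
    with np.errstate(divide="ignore"):
        scan["score"] = -np.log10(scan["p_gc"])
    m = int(scan["p_raw"].notna().sum())
    thr = bonferroni_threshold(m, alpha)
    return GwasResult(
        table=scan,
        lambda_gc=lam,
        m_tested=m,
        alpha=alpha,
        p_threshold=thr["p_threshold"],
        score_threshold=thr["score_threshold"],
    )


def manhattan_table(result: GwasResult) -> pd.DataFrame:
    """Plot-ready table: markers sorted by (chromosome, position) with a
    strictly increasing cumulative coordinate; unplaced markers (the
    fictitious chromosome 99) are appended last."""
    tab = result.table.copy()
    placed = tab[tab["chrom"] != UNPLACED_CHROM].sort_values(["chrom", "pos"])
    unplaced = tab[tab["chrom"] == UNPLACED_CHROM].sort_values("pos")
    tab = pd.concat([placed, unplaced], ignore_index=True)
    offset, cum, prev_chrom, prev_end = 0.0, [], None, 0.0
    for _, row in tab.iterrows():
        if row["chrom"] != prev_chrom:
            offset = prev_end + 1.0
            prev_chrom = row["chrom"]
        coord = offset + float(row["pos"])
        cum.append(coord)
        prev_end = max(prev_end, coord)
    tab["cum_pos"] = cum
    # enforce strict monotonicity even for duplicate positions
    tab["cum_pos"] = tab["cum_pos"] + np.arange(len(tab)) * 1e-9
    return tab


def mixed_model_scan(
    gm: GenotypeMatrix012,
    phenotype: pd.Series,
    kinship: pd.DataFrame,
) -> pd.DataFrame:
    """Optional kinship mixed-model scan (EMMA-style two-step).

    The variance ratio is estimated once under the null on the kinship
    eigendecomposition; each marker is then tested by generalized least
    squares on the rotated data.
    """
    from .gs import _reml_lambda_kernel

    lines = [l for l in gm.lines if l in phenotype.index]
    sub = gm.subset(lines=lines)
    y = phenotype.loc[lines].to_numpy(dtype=float)
    K = kinship.loc[lines, lines].to_numpy()
    lam = _reml_lambda_kernel(K, y)
    w, U = np.linalg.eigh(K)
    d = np.clip(w, 0.0, None) + lam
    Ut = U.T
    y_t = Ut @ y / np.sqrt(d)
    ones_t = Ut @ np.ones(len(lines)) / np.sqrt(d)
    X_t = (Ut @ sub.values) / np.sqrt(d)[:, None]
    n = len(lines)
    pvals = np.full(sub.n_markers, np.nan)
    betas = np.full(sub.n_markers, np.nan)
    for j in range(sub.n_markers):
        Xj = np.column_stack([ones_t, X_t[:, j]])
        XtX = Xj.T @ Xj
        try:
            coef = np.linalg.solve(XtX, Xj.T @ y_t)
        except np.linalg.LinAlgError:
            continue
        resid = y_t - Xj @ coef
        df = n - 2
        s2 = float(resid @ resid) / df
        se = np.sqrt(s2 * np.linalg.inv(XtX)[1, 1])
        if se > 0:
            t = coef[1] / se
            betas[j] = coef[1]
            pvals[j] = 2.0 * stats.t.sf(abs(t), df)
    out = sub.marker_map.copy()
    out.insert(0, "marker", out.index)
    out["beta"] = betas
    out["p_raw"] = pvals
    return out.reset_index(drop=True)
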