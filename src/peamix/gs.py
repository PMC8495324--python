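"""Genomic prediction: ridge-regression BLUP, GBLUP, inter-environment
cross-validation schemes, filter-threshold tuning and the genomic
selection gain protocol.

The whole-genome regression ``y = 1·mu + X·beta`` with
``beta ~ N(0, s2_b I)`` is fitted on the spectral decomposition of
``X Xᵀ``; the variance ratio ``lambda = s2_e / s2_b`` maximizes the
restricted likelihood over a one-dimensional bounded search.  GBLUP is
the equivalent kinship formulation and serves as the algebraic
cross-check (identical predictions when K = X Xᵀ).

Cross-validation mirrors the study protocol: training on ~80% of the
lines of each RIL population (18 of 23) plus all six parents, model
training phenotypes from one year, validation on the held-out lines'
observed values in the other year.  Validation counts are balanced so
no line is validated more than one time oftener than any other; parents
are never validated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .genomatrix import GenotypeMatrix012
from .trial import MS, blup_line_values, line_means

LAMBDA_BOUNDS = (1e-5, 1e5)


class GSError(ValueError):
    pass


# -- rrBLUP ------------------------------------------------------------------


@dataclass
class GSModel:
    mu: float
    beta: np.ndarray  # marker effects
    lambda_: float
    center: np.ndarray  # 2 p-hat used to centre markers
    markers: list[str] = field(default_factory=list)
    train_lines: list[str] = field(default_factory=list)

    def predict(self, gm: GenotypeMatrix012, lines=None) -> pd.Series:
        sub = gm if lines is None else gm.subset(lines=lines)
        Xc = sub.values - self.center
        return pd.Series(self.mu + Xc @ self.beta, index=sub.lines)


def _reml_lambda(eigvals: np.ndarray, y_rot: np.ndarray) -> float:
    """Restricted-likelihood profile over the variance ratio.

    ``eigvals``/``y_rot`` come from the eigendecomposition of the
    (intercept-projected) covariance kernel; lambda = s2_e/s2_b.
    """
    n = len(y_rot)

    def neg_restricted_ll(log_lam: float) -> float:
        lam = np.exp(log_lam)
        d = eigvals + lam
        s2 = float(np.sum(y_rot**2 / d)) / n
        return 0.5 * (n * np.log(s2) + np.sum(np.log(d)))

    res = optimize.minimize_scalar(
        neg_restricted_ll,
        bounds=(np.log(LAMBDA_BOUNDS[0]), np.log(LAMBDA_BOUNDS[1])),
        method="bounded",
        options={"xatol": 1e-13},
    )
    if not res.success:  # pragma: no cover - bounded search always terminates
        raise GSError(f"lambda search failed in [{LAMBDA_BOUNDS[0]}, {LAMBDA_BOUNDS[1]}]")
    return float(np.exp(res.x))


def _reml_lambda_kernel(Kmat: np.ndarray, yv: np.ndarray) -> float:
    """REML variance ratio for ``y = 1 mu + g + e``, ``g ~ N(0, s2_b K)``.

    Works in the contrast space orthogonal to the intercept: the kernel
    is projected by ``P = I − 11ᵀ/n``, eigendecomposed, and the
    eigenvector spanned by the intercept (zero eigenvalue of the
    projected kernel) dropped before the one-dimensional profile search.
    """
    n = len(yv)
    sd = float(np.std(yv))
    if sd == 0:  # constant phenotype: any ratio fits, effects are zero
        return 1.0
    yv = (yv - yv.mean()) / sd  # exact affine invariance of the estimate
    P = np.eye(n) - np.ones((n, n)) / n
    B = P @ Kmat @ P
    w, U = np.linalg.eigh((B + B.T) / 2.0)
    ones = np.ones(n) / np.sqrt(n)
    drop = int(np.argmax(np.abs(U.T @ ones)))
    keep = np.ones(n, dtype=bool)
    keep[drop] = False
    return _reml_lambda(np.clip(w[keep], 0.0, None), U[:, keep].T @ yv)


def rrblup_fit(
    gm: GenotypeMatrix012,
    y: pd.Series,
    lambda_: float | None = None,
) -> GSModel:
    """Fit ridge-regression BLUP on training lines.

    Markers are centred by twice the training allele frequency and not
    variance-standardised.  ``beta = Xᵀ (X Xᵀ + lambda I)⁻¹ (y − mu)``;
    lambda is REML-estimated unless given.
    """
    train_lines = [l for l in y.index if l in gm.lines]
    if len(train_lines) < 2:
        raise GSError("need at least two training lines")
    sub = gm.subset(lines=train_lines)
    X = sub.values
    if np.isnan(X).any():
        raise GSError("genotype matrix has missing values; impute first")
    center = X.mean(axis=0)
    Xc = X - center
    if not np.any(Xc):
        raise GSError("rank-zero marker matrix (all markers monomorphic in training)")
    yv = y.loc[train_lines].to_numpy(dtype=float)
    G = Xc @ Xc.T
    lam = _reml_lambda_kernel(G, yv) if lambda_ is None else float(lambda_)
    A = G + lam * np.eye(len(yv))
    Ainv = np.linalg.inv(A)
    # GLS intercept under V = G + lam I (up to scale)
    one = np.ones(len(yv))
    mu = float((one @ Ainv @ yv) / (one @ Ainv @ one))
    beta = Xc.T @ (Ainv @ (yv - mu))
    return GSModel(
        mu=mu,
        beta=beta,
        lambda_=lam,
        center=center,
        markers=list(sub.markers),
        train_lines=train_lines,
    )


def gblup_fit_predict(
    K: pd.DataFrame,
    y: pd.Series,
    train_ids: list[str],
    target_ids: list[str],
    lambda_: float | None = None,
) -> pd.Series:
    """GBLUP on a kinship matrix: breeding values for target lines.

    ``g_target = K[target, train] (K[train, train] + lambda I)⁻¹ (y − mu)``
    with the same REML lambda machinery as rrBLUP.  Singular training
    kinship gets a small ridge jitter with a warning.
    """
    Ktt = K.loc[train_ids, train_ids].to_numpy()
    yv = y.loc[train_ids].to_numpy(dtype=float)
    n = len(train_ids)
    lam = _reml_lambda_kernel(Ktt, yv) if lambda_ is None else float(lambda_)
    A = Ktt + lam * np.eye(n)
    try:
        Ainv = np.linalg.inv(A)
    except np.linalg.LinAlgError:
        import warnings

        warnings.warn("singular GBLUP system; adding ridge jitter")
        Ainv = np.linalg.inv(A + 1e-8 * np.trace(A) / n * np.eye(n))
    one = np.ones(n)
    mu = float((one @ Ainv @ yv) / (one @ Ainv @ one))
    alpha = Ainv @ (yv - mu)
    g = K.loc[target_ids, train_ids].to_numpy() @ alpha
    return pd.Series(mu + g, index=target_ids)


# -- cross-validation plans --------------------------------------------------


@dataclass
class CVPlan:
    scheme: str  # intra_population | all_genotypes | inter_population
    repetitions: list[dict]  # {"train": [...], "valid": [...]}
    seed: int | None = None

    def validation_counts(self) -> pd.Series:
        counts: dict[str, int] = {}
        for rep in self.repetitions:
            for l in rep["valid"]:
                counts[l] = counts.get(l, 0) + 1
        return pd.Series(counts)


def make_cv_plan(
    line_table: pd.DataFrame,
    scheme: str,
    n_repetitions: int = 100,
    n_validation: int = 5,
    seed: int = 0,
) -> CVPlan:
    """Build the study's stratified inter-environment CV plan.

    ``line_table`` is indexed by line with columns ``population`` and
    ``is_parent``.  For the random schemes each repetition holds out
    ``n_validation`` lines per population (training keeps the rest plus
    every parent); a greedy balanced draw keeps every line's validation
    count within one of any other's — an exactly constant count is
    impossible whenever ``n_repetitions · n_validation`` is not a
    multiple of the population size.  The inter-population scheme is the
    deterministic leave-one-population-out rotation and ignores
    ``n_repetitions``.
    """
    rng = np.random.default_rng(seed)
    parents = list(line_table.index[line_table["is_parent"]])
    pops = {
        pop: list(group.index)
        for pop, group in line_table[~line_table["is_parent"]].groupby(
            "population", observed=True
        )
    }
    if scheme == "inter_population":
        reps = []
        for pop in sorted(pops):
            valid = sorted(pops[pop])
            train = sorted(
                [l for p, ls in pops.items() if p != pop for l in ls]
            ) + sorted(parents)
            reps.append({"train": train, "valid": valid, "target_population": pop})
        return CVPlan(scheme=scheme, repetitions=reps, seed=None)
    if scheme not in ("intra_population", "all_genotypes"):
        raise GSError(f"unknown CV scheme: {scheme!r}")
    for pop, ls in pops.items():
        if len(ls) <= n_validation:
            raise GSError(f"population {pop!r} too small for {n_validation} validation lines")
    counts = {pop: {l: 0 for l in ls} for pop, ls in pops.items()}
    reps = []
    for _ in range(n_repetitions):
        valid_all, train_all = [], list(parents)
        for pop in sorted(pops):
            ls = pops[pop]
            keys = {l: (counts[pop][l], rng.random()) for l in ls}
            order = sorted(ls, key=lambda l: keys[l])
            valid = sorted(order[:n_validation])
            for l in valid:
                counts[pop][l] += 1
            valid_all.extend(valid)
            train_all.extend(l for l in ls if l not in valid)
        reps.append({"train": sorted(train_all), "valid": valid_all})
    return CVPlan(scheme=scheme, repetitions=reps, seed=seed)


# -- inter-environment cross-validation --------------------------------------


@dataclass
class PredictionResult:
    ability: float  # mean predictive ability, the headline number
    per_repetition: list[float]
    per_line_pred: pd.Series  # averaged over validation appearances
    ability_on_averaged: float  # computed on repetition-averaged predictions
    scheme: str
    train_year: str
    validation_year: str


def run_inter_environment_cv(
    gm: GenotypeMatrix012,
    table: pd.DataFrame,
    plan: CVPlan,
    train_year: str,
    validation_year: str,
    line_table: pd.DataFrame | None = None,
) -> PredictionResult:
    """Train on one year's MS-yield BLUPs, validate on the other year.

    Per repetition an rrBLUP model is fitted on the training lines'
    BLUP values of pea yield in MS for ``train_year`` and the held-out
    lines' predictions are correlated with their observed
    ``validation_year`` line means.  For the intra-population scheme the
    correlation is computed within each population and repetition, then
    averaged; for all-genotypes over the pooled validation set per
    repetition; for inter-population within each left-out population.
    Per-line predicted values are additionally averaged across the
    repetitions in which the line was validated (``per_line_pred``), and
    the predictive ability of those averaged predictions is reported
    alongside.
    """
    train_pheno = blup_line_values(table, "pea_yield", year=train_year, condition=MS)
    observed = line_means(table, "pea_yield", condition=MS, year=validation_year)["mean"]
    missing = [
        l
        for rep in plan.repetitions
        for l in rep["train"] + rep["valid"]
        if l not in gm.lines or l not in train_pheno.index
    ]
    if missing:
        raise GSError(f"lines missing from genotypes/phenotypes: {sorted(set(missing))[:5]}")

    if line_table is None:
        line_table = table[["line", "population"]].drop_duplicates().set_index("line")

    per_rep: list[float] = []
    pred_sum: dict[str, float] = {}
    pred_n: dict[str, int] = {}
    for rep in plan.repetitions:
        model = rrblup_fit(gm, train_pheno.loc[rep["train"]])
        preds = model.predict(gm, lines=rep["valid"])
        for l, v in preds.items():
            pred_sum[l] = pred_sum.get(l, 0.0) + float(v)
            pred_n[l] = pred_n.get(l, 0) + 1
        if plan.scheme in ("intra_population", "inter_population"):
            rs = []
            pops = line_table.loc[rep["valid"], "population"]
            for _, idx in pops.groupby(pops, observed=True).groups.items():
                p, o = preds.loc[idx], observed.loc[idx]
                if p.std() > 0 and o.std() > 0:
                    rs.append(float(np.corrcoef(p, o)[0, 1]))
            if rs:
                per_rep.append(float(np.mean(rs)))
        else:
            p, o = preds, observed.loc[preds.index]
            if p.std() > 0 and o.std() > 0:
                per_rep.append(float(np.corrcoef(p, o)[0, 1]))

    per_line = pd.Series({l: pred_sum[l] / pred_n[l] for l in pred_sum}).sort_index()
    o = observed.reindex(per_line.index)
    ability_avg = float(np.corrcoef(per_line, o)[0, 1]) if per_line.std() > 0 else np.nan
    return PredictionResult(
        ability=float(np.mean(per_rep)),
        per_repetition=per_rep,
        per_line_pred=per_line,
        ability_on_averaged=ability_avg,
        scheme=plan.scheme,
        train_year=train_year,
        validation_year=validation_year,
    )


# -- threshold tuning --------------------------------------------------------


def tune_thresholds(
    gm_raw: GenotypeMatrix012,
    table: pd.DataFrame,
    line_table: pd.DataFrame,
    grid: list,
    train_year: str,
    validation_year: str,
    n_repetitions: int = 10,
    knni_k: int = 5,
    seed: int = 0,
) -> tuple:
    """First tuning stage: pick missing-rate thresholds by intra-population
    inter-environment predictive ability.

    Configurations that drop genotype samples are excluded from the
    admissible set (all lines must survive filtering); among admissible
    cells the highest mean ability wins, ties going to the cell that
    retains more markers.  If no cell is admissible the global maximizer
    is returned with a warning.
    """
    from .genomatrix import filter_markers_and_genotypes, knni_impute

    results = []
    for cfg in grid:
        try:
            gm_f, report = filter_markers_and_genotypes(gm_raw, cfg)
        except Exception:
            continue
        no_line_loss = gm_f.n_lines == gm_raw.n_lines
        gm_i = knni_impute(gm_f, k=knni_k)
        plan = make_cv_plan(
            line_table, "intra_population", n_repetitions=n_repetitions, seed=seed
        )
        res = run_inter_environment_cv(
            gm_i, table, plan, train_year, validation_year, line_table
        )
        results.append(
            {
                "config": cfg,
                "ability": res.ability,
                "n_markers": gm_f.n_markers,
                "no_line_loss": no_line_loss,
            }
        )
    if not results:
        raise GSError("no grid configuration could be evaluated")
    admissible = [r for r in results if r["no_line_loss"]]
    if not admissible:
        import warnings

        warnings.warn("every configuration drops genotypes; returning global maximizer")
        admissible = results
    best = max(admissible, key=lambda r: (r["ability"], r["n_markers"]))
    return best["config"], pd.DataFrame(
        [
            {
                "maf_min": r["config"].maf_min,
                "max_missing_per_marker": r["config"].max_missing_per_marker,
                "max_missing_per_genotype": r["config"].max_missing_per_genotype,
                "ability": r["ability"],
                "n_markers": r["n_markers"],
                "no_line_loss": r["no_line_loss"],
            }
            for r in results
        ]
    )


# -- genomic gain protocol ---------------------------------------------------


def genomic_gain_protocol(
    gm: GenotypeMatrix012,
    table: pd.DataFrame,
    line_table: pd.DataFrame,
    train_year: str,
    evaluation_year: str,
    k: int = 2,
    n_repetitions: int = 100,
    n_validation: int = 5,
    seed: int = 0,
):
    """Year-swap realized gain of genomic selection.

    Runs intra-population CV with training in ``train_year``, averages
    every line's genome-enabled breeding value over the repetitions in
    which it was validated, selects the top-k lines per population by
    that average, and scores the selection on evaluation-year MS yield
    against the parent mean.
    """
    from .selection import year_swap_gain

    plan = make_cv_plan(
        line_table, "intra_population", n_repetitions=n_repetitions,
        n_validation=n_validation, seed=seed,
    )
    res = run_inter_environment_cv(
        gm, table, plan, train_year, evaluation_year, line_table
    )
    return year_swap_gain(
        table,
        res.per_line_pred,
        selection_year=train_year,
        evaluation_year=evaluation_year,
        criterion="genomic",
        k=k,
    )
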