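"""Synthetic RIL populations and split-plot intercropping trials.

The generator emulates the study design that the downstream estimators
assume: six biparental recombinant inbred line (RIL) populations of 23
lines each plus their six parents (144 inbred lines), genotyped at
biallelic SNPs on seven chromosomes with GBS-like missingness, and
evaluated for pea grain yield and morphophysiological traits in
split-plot trials (growing condition — pure stand PS vs mixed stand MS —
on main plots, lines on subplots, three blocks) over two cropping years.

Key statistical targets, all configurable:

* per trait × condition × year means and genetic / error coefficients of
  variation (CVg, CVe);
* the genetic correlation of pea yield across MS and PS (default 0.42);
* the line-level correlation structure tying morphophysiological traits
  to yield genetic values in each condition;
* the relative size of genotype × year interaction, which sets the
  cross-year genetic correlation within a condition (default ≈ 0.73).

Every simulated truth (marker effects, per-line genetic values, realized
correlations) is kept in :class:`TrueArchitecture` so recovery tests can
compare downstream estimates against it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genomatrix import GenotypeMatrix012

MS = "MS"
PS = "PS"

DEFAULT_PARENTS = ("Attika", "Isard", "Kaspa", "Dove", "Guifilo", "Alliance")
DEFAULT_CROSSES = (
    ("Attika", "Isard"),
    ("Kaspa", "Attika"),
    ("Kaspa", "Isard"),
    ("Dove", "Attika"),
    ("Attika", "Guifilo"),
    ("Alliance", "Isard"),
)
PARENT_POPULATION = "parents"

YEAR1 = "2018-19"
YEAR2 = "2019-20"

#: architecture-level trait keys; pea yield is condition-specific because
#: yield expression in mixture vs pure stand is genetically distinct
YIELD_MS = "pea_yield:MS"
YIELD_PS = "pea_yield:PS"
MORPHO_TRAITS = (
    "onset_flowering",
    "height_flowering",
    "seed_weight",
    "maturity",
    "height_maturity",
    "winter_survival",
    "ascochyta",
)
ARCH_TRAITS = (YIELD_MS, YIELD_PS) + MORPHO_TRAITS


class ConfigError(ValueError):
    pass


@dataclass
class TraitTarget:
    """Target mean and variation for one trait in one condition and year."""

    mean: float
    cv_g: float  # genetic coefficient of variation, %
    cv_e: float  # plot-error coefficient of variation, %


def default_trait_targets() -> dict[tuple[str, str, str], TraitTarget]:
    """Trial targets calibrated to the study's printed trait summaries.

    Yield rows carry the printed CVg/CVe pairs; means are the printed
    trait means.  Morphophysiological CVs are set from the printed ranges
    (a range of roughly ±3 genetic SD around the mean).  Winter survival
    and ascochyta scores only varied in the first, colder and wetter year
    and are only generated there; flowering traits and seed weight were
    recorded in MS only in the second year.
    """
    t: dict[tuple[str, str, str], TraitTarget] = {}
    t[("pea_yield", MS, YEAR1)] = TraitTarget(1.000, 33.0, 44.0)
    t[("pea_yield", MS, YEAR2)] = TraitTarget(1.071, 46.0, 51.0)
    t[("pea_yield", PS, YEAR1)] = TraitTarget(6.223, 24.0, 27.0)
    t[("pea_yield", PS, YEAR2)] = TraitTarget(4.686, 17.0, 18.0)
    t[("cereal_yield", MS, YEAR1)] = TraitTarget(5.494, 8.0, 9.0)
    t[("cereal_yield", MS, YEAR2)] = TraitTarget(3.719, 10.0, 12.0)
    t[("onset_flowering", PS, YEAR1)] = TraitTarget(12.7, 35.0, 12.0)
    t[("onset_flowering", PS, YEAR2)] = TraitTarget(27.0, 6.0, 3.0)
    t[("onset_flowering", MS, YEAR2)] = TraitTarget(27.8, 6.0, 3.0)
    t[("height_flowering", PS, YEAR1)] = TraitTarget(62.0, 20.0, 9.0)
    t[("height_flowering", PS, YEAR2)] = TraitTarget(46.1, 11.0, 7.0)
    t[("height_flowering", MS, YEAR2)] = TraitTarget(50.1, 12.0, 8.0)
    t[("seed_weight", PS, YEAR1)] = TraitTarget(0.146, 13.0, 6.0)
    t[("seed_weight", PS, YEAR2)] = TraitTarget(0.198, 12.0, 6.0)
    t[("seed_weight", MS, YEAR2)] = TraitTarget(0.194, 12.0, 6.0)
    t[("maturity", PS, YEAR1)] = TraitTarget(64.5, 2.5, 1.2)
    t[("maturity", PS, YEAR2)] = TraitTarget(61.9, 1.8, 1.2)
    t[("height_maturity", PS, YEAR1)] = TraitTarget(120.4, 12.0, 7.0)
    t[("height_maturity", PS, YEAR2)] = TraitTarget(54.8, 14.0, 8.0)
    t[("winter_survival", PS, YEAR1)] = TraitTarget(0.978, 2.3, 1.5)
    t[("ascochyta", PS, YEAR1)] = TraitTarget(4.1, 10.0, 9.0)
    return t


def default_trait_corr_matrix() -> pd.DataFrame:
    """Target line-level correlations of genetic values.

    Yield columns carry the printed cross-condition genetic correlation
    (0.42) and genetic-scale associations of morphophysiological traits
    (measured in PS) with yield in each condition: later flowering and
    taller plants at flowering favour yield in mixture but not in pure
    stand, while ascochyta susceptibility depresses yield in pure stand
    only.  Because plot error and genotype × year interaction attenuate
    observed correlations, these genetic targets sit above the printed
    phenotypic values (deattenuated by ≈1.3) so that line-mean
    correlations computed from the simulated trials reproduce the
    printed table.  Correlations among the morphophysiological traits
    themselves are plausible agronomic values.  The matrix is projected
    to the nearest positive-semidefinite matrix before use.
    """
    traits = list(ARCH_TRAITS)
    C = pd.DataFrame(np.eye(len(traits)), index=traits, columns=traits)

    def set_(a, b, v):
        C.loc[a, b] = v
        C.loc[b, a] = v

    set_(YIELD_MS, YIELD_PS, 0.42)
    set_(YIELD_MS, "onset_flowering", 0.65)
    set_(YIELD_PS, "onset_flowering", -0.10)
    set_(YIELD_MS, "height_flowering", 0.77)
    set_(YIELD_PS, "height_flowering", 0.29)
    set_(YIELD_MS, "seed_weight", -0.12)
    set_(YIELD_PS, "seed_weight", 0.31)
    set_(YIELD_MS, "maturity", 0.09)
    set_(YIELD_PS, "maturity", 0.13)
    set_(YIELD_MS, "height_maturity", 0.52)
    set_(YIELD_PS, "height_maturity", 0.40)
    set_(YIELD_MS, "winter_survival", 0.17)
    set_(YIELD_PS, "winter_survival", 0.35)
    set_(YIELD_MS, "ascochyta", -0.29)
    set_(YIELD_PS, "ascochyta", -0.74)
    set_("onset_flowering", "height_flowering", 0.45)
    set_("onset_flowering", "maturity", 0.30)
    set_("height_flowering", "height_maturity", 0.60)
    set_("maturity", "height_maturity", 0.20)
    set_("ascochyta", "winter_survival", -0.15)
    return C


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study; defaults are the study design."""

    n_populations: int = 6
    lines_per_population: int = 23
    parents: tuple[str, ...] = DEFAULT_PARENTS
    cross_design: tuple[tuple[str, str], ...] = DEFAULT_CROSSES
    n_chromosomes: int = 7
    n_markers: int = 1000
    map_length_cm: float = 100.0
    min_polymorphic_fraction: float = 0.8
    marker_missing_rate: float = 0.03
    genotype_missing_rate: float = 0.02
    residual_het_rate: float = 0.01
    years: tuple[str, ...] = (YEAR1, YEAR2)
    n_blocks: int = 3
    trait_targets: dict = field(default_factory=default_trait_targets)
    genetic_corr_ms_ps: float = 0.42
    # genotype x condition / year / condition x year variance relative to
    # genotypic variance; only their derived dilution ratios act on the data
    variance_ratios: dict = field(
        default_factory=lambda: {"gc_over_g": 2.0, "gy_over_g": 0.73, "gcy_over_g": 0.39}
    )
    gxy_ratio_morpho: float = 0.08
    trait_corr_matrix: pd.DataFrame = field(default_factory=default_trait_corr_matrix)
    n_qtl_per_trait: int = 40
    qtl_variance_fraction: float = 0.8
    cereal_competition_corr: float = 0.35
    block_cv: float = 5.0
    main_plot_cv: float = 6.0
    seed: int = 0

    # -- derived quantities ---------------------------------------------

    @property
    def n_lines(self) -> int:
        return self.n_populations * self.lines_per_population + len(self.parents)

    @property
    def gxy_ratio_yield(self) -> float:
        """Variance of line×year deviates relative to the year-invariant
        genetic value, for yield: (gy + gcy) / (g + gc)."""
        r = self.variance_ratios
        return (r["gy_over_g"] + r["gcy_over_g"]) / (1.0 + r["gc_over_g"])

    def validate(self) -> None:
        if self.n_markers <= 0 or len(self.parents) == 0:
            raise ConfigError("need at least one marker and one parent")
        for name in ("marker_missing_rate", "genotype_missing_rate", "residual_het_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if not -1.0 <= self.genetic_corr_ms_ps <= 1.0:
            raise ConfigError("genetic_corr_ms_ps outside [-1, 1]")
        if self.n_populations > len(self.cross_design):
            raise ConfigError("not enough crosses for the requested populations")
        for p1, p2 in self.cross_design[: self.n_populations]:
            if p1 not in self.parents or p2 not in self.parents:
                raise ConfigError(f"cross ({p1}, {p2}) references unknown parent")
        C = self.trait_corr_matrix
        if not np.allclose(C.values, C.values.T) or not np.allclose(np.diag(C.values), 1.0):
            raise ConfigError("trait_corr_matrix must be symmetric with unit diagonal")
        if self.n_populations < 1 or self.lines_per_population < 1 or self.n_blocks < 1:
            raise ConfigError("counts must be positive")

    def population_names(self) -> list[str]:
        return [
            f"{p1}x{p2}" for p1, p2 in self.cross_design[: self.n_populations]
        ]


def yield_only_config(**overrides) -> SimulationConfig:
    """A lean configuration carrying only the two pea-yield traits.

    Used for moment-recovery studies where the morphophysiological traits
    are irrelevant; defaults to the first cropping year's yield targets.
    """
    targets = {
        k: v for k, v in default_trait_targets().items() if k[0] == "pea_yield"
    }
    cfg = SimulationConfig(trait_targets=targets, **overrides)
    return cfg


def nearest_psd_correlation(C: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Project a symmetric matrix to the nearest PSD one by clipping
    eigenvalues at zero, then restore the unit diagonal."""
    w, V = np.linalg.eigh((C + C.T) / 2.0)
    w = np.clip(w, 0.0, None)
    out = (V * w) @ V.T
    d = np.sqrt(np.clip(np.diag(out), tol, None))
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return out


# -- genomes -----------------------------------------------------------------


def _marker_map(config: SimulationConfig) -> pd.DataFrame:
    per = np.full(config.n_chromosomes, config.n_markers // config.n_chromosomes)
    per[: config.n_markers % config.n_chromosomes] += 1
    chroms, pos, names = [], [], []
    for c, m in enumerate(per, start=1):
        p = np.sort(np.linspace(0.0, config.map_length_cm, int(m) + 2)[1:-1])
        chroms.extend([c] * int(m))
        pos.extend(p)
        names.extend([f"chr{c}_m{i + 1}" for i in range(int(m))])
    return pd.DataFrame({"chrom": chroms, "pos": pos}, index=pd.Index(names, name="marker"))


def simulate_founder_genomes(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> GenotypeMatrix012:
    """Fully homozygous parent genomes over biallelic loci.

    Alternate-allele carriage per parent is Bernoulli with a per-locus
    frequency drawn from U(0.2, 0.8); loci that come out monomorphic in
    the first ``min_polymorphic_fraction`` of the genome get one parent
    flipped, which bounds the polymorphic fraction from below.
    """
    config.validate()
    rng = rng or np.random.default_rng(config.seed)
    n_par, m = len(config.parents), config.n_markers
    freq = rng.uniform(0.2, 0.8, size=m)
    carry = rng.random((n_par, m)) < freq
    X = np.where(carry, 2.0, 0.0)
    n_force = int(np.ceil(config.min_polymorphic_fraction * m))
    mono = np.flatnonzero((X[:, :n_force] == X[0, :n_force]).all(axis=0))
    if mono.size:
        flip_parent = rng.integers(0, n_par, size=mono.size)
        X[flip_parent, mono] = 2.0 - X[flip_parent, mono]
    return GenotypeMatrix012(
        lines=list(config.parents),
        markers=list(_marker_map(config).index),
        values=X,
        marker_map=_marker_map(config),
    )


def simulate_ril_population(
    parents: GenotypeMatrix012,
    parent_pair: tuple[str, str],
    n_lines: int,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    line_prefix: str = "RIL",
) -> GenotypeMatrix012:
    """Homozygous RILs from a biparental cross, by selfing to fixation.

    Meiosis over the selfing generations is collapsed into the expected
    RIL recombination fraction between adjacent markers,
    ``R = 2r / (1 + 2r)`` with ``r`` from the Haldane map function on the
    adjacent map distance.  Each RIL is a homozygous mosaic of the two
    parental genomes produced by a two-state walk along each chromosome
    with switch probability R.
    """
    rng = rng or np.random.default_rng(config.seed)
    g1 = parents.values[parents.lines.index(parent_pair[0])]
    g2 = parents.values[parents.lines.index(parent_pair[1])]
    if np.any(g1 == 1) or np.any(g2 == 1):
        raise ConfigError("RIL simulation requires homozygous parents")
    mm = parents.marker_map
    out = np.empty((n_lines, parents.n_markers))
    for chrom in pd.unique(mm["chrom"]):
        idx = np.flatnonzero((mm["chrom"] == chrom).to_numpy())
        pos = mm["pos"].to_numpy()[idx]
        d_morgan = np.diff(pos) / 100.0
        r = 0.5 * (1.0 - np.exp(-2.0 * d_morgan))
        R = 2.0 * r / (1.0 + 2.0 * r)
        state = np.empty((n_lines, idx.size), dtype=bool)
        state[:, 0] = rng.random(n_lines) < 0.5
        if idx.size > 1:
            switch = rng.random((n_lines, idx.size - 1)) < R
            state[:, 1:] = state[:, [0]] ^ (np.cumsum(switch, axis=1) % 2).astype(bool)
        out[:, idx] = np.where(state, g2[idx], g1[idx])
    lines = [f"{line_prefix}_{i + 1:02d}" for i in range(n_lines)]
    return GenotypeMatrix012(
        lines=lines, markers=list(parents.markers), values=out, marker_map=mm.copy()
    )


def assemble_genotypes(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[GenotypeMatrix012, pd.DataFrame]:
    """Parents + all RIL populations; returns the matrix and a line table
    (line, population, is_parent)."""
    founders = simulate_founder_genomes(config, rng)
    blocks = [founders.values]
    lines = list(founders.lines)
    pops = [PARENT_POPULATION] * len(founders.lines)
    is_parent = [True] * len(founders.lines)
    for pop_name, pair in zip(config.population_names(), config.cross_design):
        ril = simulate_ril_population(
            founders, pair, config.lines_per_population, config, rng,
            line_prefix=pop_name,
        )
        blocks.append(ril.values)
        lines.extend(ril.lines)
        pops.extend([pop_name] * ril.n_lines)
        is_parent.extend([False] * ril.n_lines)
    gm = GenotypeMatrix012(
        lines=lines,
        markers=list(founders.markers),
        values=np.vstack(blocks),
        marker_map=founders.marker_map.copy(),
    )
    line_table = pd.DataFrame(
        {"population": pops, "is_parent": is_parent}, index=pd.Index(lines, name="line")
    )
    return gm, line_table


def apply_genotyping_noise(
    gm: GenotypeMatrix012,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> GenotypeMatrix012:
    """GBS-like degradation: missing calls per marker and per genotype,
    plus a residual rate of spurious heterozygous calls."""
    rng = rng or np.random.default_rng(config.seed)
    for name in ("marker_missing_rate", "genotype_missing_rate", "residual_het_rate"):
        v = getattr(config, name)
        if not 0.0 <= v <= 1.0:
            raise ConfigError(f"{name}={v} outside [0, 1]")
    X = gm.values.copy()
    n, m = X.shape
    miss = rng.random((n, m)) < config.marker_missing_rate
    miss |= rng.random((n, m)) < config.genotype_missing_rate
    het = (~miss) & (rng.random((n, m)) < config.residual_het_rate)
    X[het] = 1.0
    X[miss] = np.nan
    return GenotypeMatrix012(
        lines=list(gm.lines), markers=list(gm.markers), values=X,
        marker_map=gm.marker_map.copy(),
    )


# -- genetic architecture ----------------------------------------------------


@dataclass
class TrueArchitecture:
    """The simulation truth against which estimators are tested.

    ``genetic_values`` holds standardized (unit-variance, zero-mean over
    lines) year-invariant genetic values per architecture trait;
    ``marker_effects`` and ``polygenic`` reconstruct them exactly from the
    centred true genotype matrix:
    ``Z = (X - colmeans) @ marker_effects + polygenic``.
    """

    genetic_values: pd.DataFrame
    marker_effects: pd.DataFrame
    polygenic: pd.DataFrame
    genotype_col_means: pd.Series
    realized_corr: pd.DataFrame
    realized_corr_ms_ps: float
    line_table: pd.DataFrame
    trial_truth: dict = field(default_factory=dict)

    def reconstruct(self, genotypes: GenotypeMatrix012) -> pd.DataFrame:
        Xc = genotypes.values - self.genotype_col_means.to_numpy()
        return pd.DataFrame(
            Xc @ self.marker_effects.to_numpy() + self.polygenic.to_numpy(),
            index=self.genetic_values.index,
            columns=self.genetic_values.columns,
        )


def simulate_genetic_values(
    genotypes: GenotypeMatrix012,
    line_table: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> TrueArchitecture:
    """Correlated per-line genetic values with a marker-QTL backbone.

    Per trait, a QTL score (``n_qtl_per_trait`` random markers with
    normal effects, carrying ``qtl_variance_fraction`` of the variance)
    is blended with an iid polygenic deviate; the trait × line matrix is
    then whitened empirically and mixed through the Cholesky factor of
    the (nearest-PSD-projected) target correlation matrix, so the
    realized line-level correlations match the target essentially
    exactly and each trait has unit variance over lines.  The linear map
    is propagated to the marker effects, keeping genetic values exactly
    reconstructible from genotypes plus stored polygenic residuals.
    """
    rng = rng or np.random.default_rng(config.seed)
    traits = [t for t in ARCH_TRAITS]
    C_target = config.trait_corr_matrix.loc[traits, traits].to_numpy().copy()
    C_target[traits.index(YIELD_MS), traits.index(YIELD_PS)] = config.genetic_corr_ms_ps
    C_target[traits.index(YIELD_PS), traits.index(YIELD_MS)] = config.genetic_corr_ms_ps
    C_psd = nearest_psd_correlation(C_target)
    try:
        L = np.linalg.cholesky(C_psd + 1e-10 * np.eye(len(traits)))
    except np.linalg.LinAlgError as err:  # pragma: no cover - PSD by construction
        raise ConfigError(f"target correlation matrix not PSD after projection: {err}")

    X = genotypes.values
    if np.isnan(X).any():
        raise ConfigError("genetic values must be simulated on the noise-free matrix")
    n, m = X.shape
    col_means = X.mean(axis=0)
    Xc = X - col_means
    T = len(traits)

    w = config.qtl_variance_fraction if config.n_qtl_per_trait > 0 else 0.0
    Beta = np.zeros((m, T))
    if config.n_qtl_per_trait > 0:
        for t in range(T):
            qtl = rng.choice(m, size=min(config.n_qtl_per_trait, m), replace=False)
            Beta[qtl, t] = rng.standard_normal(qtl.size)
    Q = Xc @ Beta
    sd = Q.std(axis=0, ddof=1)
    Dinv = np.diag(np.where(sd > 0, 1.0 / np.where(sd > 0, sd, 1.0), 0.0))
    Qs = (Q - Q.mean(axis=0)) @ Dinv  # standardized QTL scores

    P = rng.standard_normal((n, T))
    B = np.sqrt(w) * Qs + np.sqrt(1.0 - w) * P
    Bc = B - B.mean(axis=0)
    S = Bc.T @ Bc / (n - 1)
    ew, EV = np.linalg.eigh(S)
    if np.min(ew) < 1e-12:
        raise ConfigError("degenerate base matrix; need n_lines > n_traits")
    W = EV @ np.diag(1.0 / np.sqrt(ew)) @ EV.T  # empirical whitener
    M = W @ L.T
    Z = Bc @ M

    # propagate the linear map so Z == Xc @ E + residual exactly
    E = np.sqrt(w) * (Beta @ Dinv) @ M
    resid = Z - Xc @ E

    realized = pd.DataFrame(np.corrcoef(Z.T), index=traits, columns=traits)
    return TrueArchitecture(
        genetic_values=pd.DataFrame(Z, index=genotypes.lines, columns=traits),
        marker_effects=pd.DataFrame(E, index=genotypes.markers, columns=traits),
        polygenic=pd.DataFrame(resid, index=genotypes.lines, columns=traits),
        genotype_col_means=pd.Series(col_means, index=genotypes.markers),
        realized_corr=realized,
        realized_corr_ms_ps=float(realized.loc[YIELD_MS, YIELD_PS]),
        line_table=line_table,
    )


# -- trial phenotypes --------------------------------------------------------


def _arch_trait_for(trait: str, condition: str) -> str | None:
    if trait == "pea_yield":
        return YIELD_MS if condition == MS else YIELD_PS
    if trait == "cereal_yield":
        return None  # phenomenological, derived from pea competitive value
    return trait


def simulate_trial_phenotypes(
    architecture: TrueArchitecture,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
):
    """Plot-level split-plot records for every (year, condition, block, line).

    Observed value = target mean × (1 + CVg·u + CVe·e) + block and
    main-plot (condition × block within year) effects, where ``u`` is the
    line effect for that trait, condition and year: a blend of the
    year-invariant genetic value and a line × year deviate whose relative
    variance is set by the genotype × year ratios.  For pea yield the
    line × year deviates share the MS/PS cross-condition correlation, so
    the within-year cross-condition genetic correlation equals
    ``genetic_corr_ms_ps`` exactly in expectation.  Cereal plot yield in
    MS responds negatively to the pea line's competitive (MS-yield)
    genetic value.  Winter survival and ascochyta are year-1-only traits.

    Plot values are Gaussian around the target mean; at the error levels
    of yield in mixture a small fraction of plot yields can be negative
    and is retained to keep the moment structure exact (see methods note).

    Returns the trial table (a plain DataFrame in the TrialTable layout)
    and records the per-(trait, condition, year) line effects in
    ``architecture.trial_truth``.
    """
    rng = rng or np.random.default_rng(config.seed)
    lines = list(architecture.genetic_values.index)
    n = len(lines)
    Z = architecture.genetic_values

    needed = {
        _arch_trait_for(t, c)
        for (t, c, y) in config.trait_targets
        if _arch_trait_for(t, c) is not None
    }
    missing = needed - set(Z.columns)
    if missing:
        raise ConfigError(f"architecture lacks traits: {sorted(missing)}")

    r = config.genetic_corr_ms_ps
    rho_yield = config.gxy_ratio_yield
    rho_morpho = config.gxy_ratio_morpho

    # line x year deviates
    u: dict[tuple[str, str, str], np.ndarray] = {}
    for year in config.years:
        a = rng.standard_normal(n)
        b = rng.standard_normal(n)
        w_ms = a
        w_ps = r * a + np.sqrt(max(0.0, 1.0 - r * r)) * b
        u[(YIELD_MS, MS, year)] = (Z[YIELD_MS].to_numpy() + np.sqrt(rho_yield) * w_ms) / np.sqrt(1 + rho_yield)
        u[(YIELD_PS, PS, year)] = (Z[YIELD_PS].to_numpy() + np.sqrt(rho_yield) * w_ps) / np.sqrt(1 + rho_yield)
        for trait in MORPHO_TRAITS:
            wv = rng.standard_normal(n)
            blended = (Z[trait].to_numpy() + np.sqrt(rho_morpho) * wv) / np.sqrt(1 + rho_morpho)
            for cond in (PS, MS):
                u[(trait, cond, year)] = blended
        # cereal competitive response: negative dependence on pea MS value
        beta = config.cereal_competition_corr
        noise = rng.standard_normal(n)
        u[("cereal_yield", MS, year)] = -beta * u[(YIELD_MS, MS, year)] + np.sqrt(
            max(0.0, 1.0 - beta * beta)
        ) * noise

    architecture.trial_truth = {
        "line_effects": {"|".join(k): v.copy() for k, v in u.items()},
        "lines": lines,
    }

    records = []
    trait_names = sorted({t for (t, _, _) in config.trait_targets})
    for year in config.years:
        block_eff = rng.standard_normal(config.n_blocks)
        main_plot = {
            (cond, b): rng.standard_normal()
            for cond in (MS, PS)
            for b in range(config.n_blocks)
        }
        for cond in (MS, PS):
            for b in range(config.n_blocks):
                row_vals = {}
                for trait in trait_names:
                    key = (trait, cond, year)
                    if key not in config.trait_targets:
                        row_vals[trait] = np.full(n, np.nan)
                        continue
                    tgt = config.trait_targets[key]
                    arch = _arch_trait_for(trait, cond)
                    uu = u[(arch, cond, year)] if arch is not None else u[("cereal_yield", MS, year)]
                    eps = rng.standard_normal(n)
                    v = tgt.mean * (
                        1.0
                        + tgt.cv_g / 100.0 * uu
                        + tgt.cv_e / 100.0 * eps
                        + config.block_cv / 100.0 * block_eff[b]
                        + config.main_plot_cv / 100.0 * main_plot[(cond, b)]
                    )
                    row_vals[trait] = v
                for i, line in enumerate(lines):
                    rec = {
                        "year": year,
                        "condition": cond,
                        "block": b + 1,
                        "population": architecture.line_table.loc[line, "population"],
                        "line": line,
                        "is_parent": bool(architecture.line_table.loc[line, "is_parent"]),
                    }
                    for trait in trait_names:
                        rec[trait] = row_vals[trait][i]
                    records.append(rec)
    table = pd.DataFrame.from_records(records)
    return table


# -- full scenario -----------------------------------------------------------


@dataclass
class Scenario:
    """A complete synthetic study: trial table, genotypes (true and
    noisy), architecture truth, and the configuration that produced it."""

    trial: pd.DataFrame
    genotypes: GenotypeMatrix012
    genotypes_true: GenotypeMatrix012
    architecture: TrueArchitecture
    line_table: pd.DataFrame
    config: SimulationConfig

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.trial.to_csv(out / "trial.tsv", sep="\t", index=False)
        self.genotypes.write_012(out / "genotypes.012.tsv")
        self.genotypes.write_marker_map(out / "marker_map.tsv")
        truth = {
            "genetic_values": self.architecture.genetic_values.round(10).to_dict(),
            "realized_corr_ms_ps": self.architecture.realized_corr_ms_ps,
            "seed": self.config.seed,
        }
        (out / "architecture.json").write_text(json.dumps(truth, indent=2))


def generate_scenario(config: SimulationConfig | None = None) -> Scenario:
    """One call, one fully seeded synthetic study."""
    config = config or SimulationConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    gm_true, line_table = assemble_genotypes(config, rng)
    architecture = simulate_genetic_values(gm_true, line_table, config, rng)
    trial = simulate_trial_phenotypes(architecture, config, rng)
    gm_noisy = apply_genotyping_noise(gm_true, config, rng)
    return Scenario(
        trial=trial,
        genotypes=gm_noisy,
        genotypes_true=gm_true,
        architecture=architecture,
        line_table=line_table,
        config=config,
    )
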