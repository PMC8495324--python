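"""Genotype matrices: 012/VCF I/O, marker and genotype filters, KNN imputation, kinship.

The in-memory container is :class:`GenotypeMatrix012`, a lines × markers
matrix of alternate-allele dosages (0, 1, 2, with ``NaN`` for missing
calls) plus a marker map (chromosome, position).  Filtering follows the
GBS post-calling protocol: per-marker missing rate, per-genotype missing
rate, heterozygosity ratio, and minor allele frequency, in that order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: chromosome id used for markers that could not be placed on the genome
UNPLACED_CHROM = 99


class GenotypeError(ValueError):
    """Raised for malformed genotype input or degenerate matrices."""


@dataclass
class GenotypeMatrix012:
    """Biallelic SNP dosages for a set of inbred lines.

    Parameters
    ----------
    lines:
        Line identifiers (rows).
    markers:
        Marker identifiers (columns).
    values:
        Float array of shape ``(len(lines), len(markers))`` with entries in
        ``{0, 1, 2}`` or ``NaN`` for missing calls.
    marker_map:
        DataFrame indexed like ``markers`` with columns ``chrom`` and
        ``pos``; chromosome :data:`UNPLACED_CHROM` marks unplaced markers.
    """

    lines: list[str]
    markers: list[str]
    values: np.ndarray
    marker_map: pd.DataFrame = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.lines), len(self.markers)):
            raise GenotypeError(
                f"matrix shape {self.values.shape} inconsistent with "
                f"{len(self.lines)} lines x {len(self.markers)} markers"
            )
        # raw calls are {0,1,2,NaN}; KNN-imputed entries may be fractional
        valid = np.isnan(self.values) | (
            (self.values >= 0.0) & (self.values <= 2.0)
        )
        if not valid.all():
            bad = np.unique(self.values[~valid])
            raise GenotypeError(f"dosage values outside [0, 2] or NaN: {bad}")
        if self.marker_map is None:
            self.marker_map = pd.DataFrame(
                {"chrom": UNPLACED_CHROM, "pos": np.arange(len(self.markers))},
                index=pd.Index(self.markers, name="marker"),
            )
        else:
            self.marker_map = self.marker_map.loc[self.markers]

    # -- basic summaries -------------------------------------------------

    @property
    def n_lines(self) -> int:
        return len(self.lines)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def marker_missing_rate(self) -> np.ndarray:
        return np.isnan(self.values).mean(axis=0)

    def genotype_missing_rate(self) -> np.ndarray:
        return np.isnan(self.values).mean(axis=1)

    def allele_frequency(self) -> np.ndarray:
        """Alternate-allele frequency per marker, missing calls excluded."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.values, axis=0) / 2.0

    def minor_allele_frequency(self) -> np.ndarray:
        p = self.allele_frequency()
        return np.minimum(p, 1.0 - p)

    def heterozygosity_ratio(self) -> np.ndarray:
        """Fraction of heterozygous calls among non-missing calls, per marker."""
        het = (self.values == 1).sum(axis=0)
        called = (~np.isnan(self.values)).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(called > 0, het / called, np.nan)

    def subset(self, lines=None, markers=None) -> "GenotypeMatrix012":
        line_idx = (
            np.arange(self.n_lines)
            if lines is None
            else np.array([self.lines.index(l) for l in lines])
        )
        marker_idx = (
            np.arange(self.n_markers)
            if markers is None
            else np.array([self.markers.index(m) for m in markers])
        )
        return GenotypeMatrix012(
            lines=[self.lines[i] for i in line_idx],
            markers=[self.markers[j] for j in marker_idx],
            values=self.values[np.ix_(line_idx, marker_idx)].copy(),
            marker_map=self.marker_map.iloc[marker_idx].copy(),
        )

    # -- plain-text 012 dialect ------------------------------------------

    def write_012(self, path: str | Path) -> None:
        """Tab-separated text: header of marker ids, first column line ids.

        Missing calls are written as ``NA``.
        """
        df = pd.DataFrame(self.values, index=self.lines, columns=self.markers)
        df.index.name = "line"
        out = df.where(df.isna(), df.astype("Int64").astype(str)).fillna("NA")
        out.to_csv(path, sep="\t")

    def write_marker_map(self, path: str | Path) -> None:
        self.marker_map.to_csv(path, sep="\t")

    def write_vcf(self, path: str | Path) -> None:
        """Minimal biallelic-SNP VCF 4.2 rendering of the dosage matrix."""
        mm = self.marker_map
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            for chrom in pd.unique(mm["chrom"]):
                fh.write(f"##contig=<ID={chrom}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(self.lines)
                + "\n"
            )
            gt_code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
            for j, marker in enumerate(self.markers):
                row = self.values[:, j]
                calls = "\t".join(
                    "./." if np.isnan(v) else gt_code[v] for v in row
                )
                pos = int(round(float(mm["pos"].iloc[j]))) + 1
                fh.write(
                    f"{mm['chrom'].iloc[j]}\t{pos}\t{marker}\tA\tG\t.\t.\t.\tGT\t{calls}\n"
                )


def read_genotypes(path: str | Path, format: str = "012", map_path=None) -> GenotypeMatrix012:
    """Read a genotype matrix from a 012 text table or a VCF.

    VCF records are restricted to biallelic SNPs; indels and multi-allelic
    sites are skipped (their count is recorded on the returned object as
    ``skipped_records``).  Genotypes map to the dosage of the alternate
    allele; ``./.`` becomes missing.
    """
    path = Path(path)
    if format == "012":
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
        mm = (
            pd.read_csv(map_path, sep="\t", index_col=0)
            if map_path is not None
            else None
        )
        return GenotypeMatrix012(
            lines=[str(l) for l in df.index],
            markers=[str(m) for m in df.columns],
            values=df.to_numpy(dtype=float),
            marker_map=mm,
        )
    if format == "vcf":
        return _read_vcf(path)
    raise GenotypeError(f"unknown genotype format: {format!r}")


def _read_vcf(path: Path) -> GenotypeMatrix012:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    lines = list(vcf.samples)
    markers, chroms, poss, rows = [], [], [], []
    skipped = 0
    for var in vcf:
        if not var.is_snp or len(var.ALT) != 1:
            skipped += 1
            continue
        # gt_types: 0=hom ref, 1=het, 2=unknown, 3=hom alt
        dosage = np.array(
            [
                np.nan if t == 2 else {0: 0.0, 1: 1.0, 3: 2.0}[t]
                for t in var.gt_types
            ]
        )
        markers.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}")
        chrom = var.CHROM
        chroms.append(int(chrom) if str(chrom).isdigit() else UNPLACED_CHROM)
        poss.append(var.POS - 1)
        rows.append(dosage)
    if not markers:
        raise GenotypeError(f"no biallelic SNP records in {path}")
    mm = pd.DataFrame(
        {"chrom": chroms, "pos": poss}, index=pd.Index(markers, name="marker")
    )
    gm = GenotypeMatrix012(
        lines=lines, markers=markers, values=np.column_stack(rows), marker_map=mm
    )
    gm.skipped_records = skipped
    return gm


# -- filtering ---------------------------------------------------------------


@dataclass
class FilterConfig:
    """Marker/genotype quality thresholds for a GBS-derived 012 matrix.

    Defaults are the retained configuration of the two-stage tuning:
    MAF > 5%, at most 5% missing calls per marker and 50% per genotype,
    and markers with a heterozygosity ratio above 95% discarded (spurious
    heterozygosity in inbred material indicates paralog collapse).
    """

    maf_min: float = 0.05
    max_missing_per_marker: float = 0.05
    max_missing_per_genotype: float = 0.50
    max_het_ratio: float = 0.95

    def __post_init__(self) -> None:
        for name in ("maf_min", "max_missing_per_marker", "max_missing_per_genotype", "max_het_ratio"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise GenotypeError(f"{name}={v} outside [0, 1]")


def filter_markers_and_genotypes(
    gm: GenotypeMatrix012, cfg: FilterConfig | None = None
) -> tuple[GenotypeMatrix012, dict]:
    """Apply the four quality filters in a fixed, auditable order.

    1. drop markers whose missing rate exceeds ``max_missing_per_marker``;
    2. drop genotypes (lines) whose missing rate, on the surviving
       markers, exceeds ``max_missing_per_genotype``;
    3. drop markers with heterozygosity ratio above ``max_het_ratio``;
    4. drop markers whose minor allele frequency, computed on the
       remaining data, is ``<= maf_min``.

    Returns the filtered matrix and a step-by-step report of removals.
    """
    cfg = cfg or FilterConfig()
    report: dict = {"config": cfg.__dict__.copy(), "steps": []}

    keep_m = gm.marker_missing_rate() <= cfg.max_missing_per_marker
    report["steps"].append(
        {"step": "marker_missing", "markers_removed": int((~keep_m).sum())}
    )
    gm = gm.subset(markers=[m for m, k in zip(gm.markers, keep_m) if k])

    keep_l = gm.genotype_missing_rate() <= cfg.max_missing_per_genotype
    report["steps"].append(
        {"step": "genotype_missing", "genotypes_removed": int((~keep_l).sum())}
    )
    gm = gm.subset(lines=[l for l, k in zip(gm.lines, keep_l) if k])

    keep_h = ~(gm.heterozygosity_ratio() > cfg.max_het_ratio)
    report["steps"].append(
        {"step": "heterozygosity", "markers_removed": int((~keep_h).sum())}
    )
    gm = gm.subset(markers=[m for m, k in zip(gm.markers, keep_h) if k])

    keep_f = gm.minor_allele_frequency() > cfg.maf_min
    report["steps"].append({"step": "maf", "markers_removed": int((~keep_f).sum())})
    gm = gm.subset(markers=[m for m, k in zip(gm.markers, keep_f) if k])

    if gm.n_markers == 0 or gm.n_lines == 0:
        raise GenotypeError("filtering removed every marker or every genotype")
    report["n_lines"] = gm.n_lines
    report["n_markers"] = gm.n_markers
    return gm, report


def write_filter_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2))


# -- KNN imputation ----------------------------------------------------------


def knni_impute(
    gm: GenotypeMatrix012, k: int = 5, weighted: bool = False
) -> GenotypeMatrix012:
    """k-nearest-neighbour imputation of missing dosages.

    The distance between two lines is the mean squared dosage difference
    over markers where both are called.  For each missing entry the k
    nearest lines that carry a call at that marker vote with a plain
    (default) or inverse-distance-weighted mean.  Observed entries are
    never altered.  Ties in neighbour distance are broken by line order,
    so the result is deterministic.
    """
    X = gm.values
    if np.isnan(X).all(axis=0).any():
        bad = [m for m, a in zip(gm.markers, np.isnan(X).all(axis=0)) if a]
        raise GenotypeError(f"markers with no called genotype: {bad[:5]}")
    n = gm.n_lines
    if k >= n:
        import warnings

        warnings.warn(f"k={k} >= number of lines {n}; clipping to {n - 1}")
        k = n - 1

    obs = ~np.isnan(X)
    Xz = np.where(obs, X, 0.0)
    # pairwise mean squared difference over shared markers
    shared = obs.astype(float) @ obs.astype(float).T
    sq = (Xz**2) @ obs.T.astype(float)
    cross = Xz @ Xz.T
    ssd = sq + sq.T - 2.0 * cross
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = np.where(shared > 0, ssd / shared, np.inf)
    np.fill_diagonal(dist, np.inf)

    out = X.copy()
    order = np.argsort(dist, axis=1, kind="stable")  # stable => line-order tie-break
    for i in range(n):
        miss_j = np.flatnonzero(~obs[i])
        if miss_j.size == 0:
            continue
        neighbours = order[i]
        for j in miss_j:
            donors = neighbours[obs[neighbours, j]][:k]
            if donors.size == 0:  # unreachable: all-missing markers rejected above
                continue
            if weighted:
                w = 1.0 / (dist[i, donors] + 1e-12)
                out[i, j] = float(np.average(X[donors, j], weights=w))
            else:
                out[i, j] = float(X[donors, j].mean())
    return GenotypeMatrix012(
        lines=list(gm.lines),
        markers=list(gm.markers),
        values=out,
        marker_map=gm.marker_map.copy(),
    )


# -- kinship -----------------------------------------------------------------


def kinship_astle_balding(gm: GenotypeMatrix012) -> pd.DataFrame:
    """Allele-frequency-standardised genomic relationship matrix.

    ``K = (1/m) * sum_j (x_j - 2 p_j)(x_j - 2 p_j)^T / (2 p_j (1 - p_j))``
    with ``p_j`` the sample alternate-allele frequency of marker ``j``.
    Monomorphic markers carry no information and are skipped (their count
    is attached to the result as ``K.attrs['monomorphic_skipped']``).
    Requires a complete (imputed) matrix.
    """
    X = gm.values
    if np.isnan(X).any():
        raise GenotypeError("kinship requires a complete matrix; impute first")
    p = X.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise GenotypeError("all markers monomorphic")
    Xp = X[:, poly]
    pp = p[poly]
    Z = (Xp - 2.0 * pp) / np.sqrt(2.0 * pp * (1.0 - pp))
    K = (Z @ Z.T) / poly.sum()
    K = (K + K.T) / 2.0
    out = pd.DataFrame(K, index=gm.lines, columns=gm.lines)
    out.attrs["monomorphic_skipped"] = int((~poly).sum())
    return out
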