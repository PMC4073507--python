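"""Expression-level characterization of lincRNA vs protein-coding genes.

Counts are normalized as reads per transcript divided by the per-sample total
of mapped reads (per-read fractions, typically ~1e-5, not RPKM). The module
also covers detection tallies across samples, the per-gene coefficient of
variation used as the inter-individual variability statistic, two-sample
t-test comparisons, SNP densities in regulatory windows and the mapping-table
arithmetic (percent mapped, gigabases, read-pair totals).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomicInterval

__all__ = [
    "ExpressionMatrix",
    "normalize_counts",
    "detection_summary",
    "coefficient_of_variation",
    "GroupComparison",
    "compare_groups",
    "snp_density",
    "MappingSummary",
    "mapping_summary",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples raw counts plus per-sample mapped-read totals."""

    raw_counts: pd.DataFrame  # genes x samples, non-negative integers
    mapped_totals: pd.Series  # per sample, positive

    def __post_init__(self) -> None:
        if list(self.raw_counts.columns) != list(self.mapped_totals.index):
            raise ValueError("sample ids of counts and totals disagree")
        if (self.raw_counts.to_numpy() < 0).any():
            raise ValueError("raw counts must be non-negative")
        if (self.mapped_totals.to_numpy() <= 0).any():
            raise ValueError("mapped totals must be positive")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.raw_counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.raw_counts.columns)

    @property
    def normalized(self) -> pd.DataFrame:
        """Reads per transcript divided by total mapped reads, per sample."""
        return self.raw_counts.div(self.mapped_totals, axis=1)

    def subset(self, gene_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.raw_counts.loc[list(gene_ids)], self.mapped_totals)


def normalize_counts(
    raw_counts: pd.DataFrame, mapped_totals: pd.Series
) -> ExpressionMatrix:
    """Bundle counts with totals after validating shapes and positivity."""
    totals = mapped_totals.reindex(raw_counts.columns)
    if totals.isna().any():
        raise ValueError("mapped totals missing for some samples")
    return ExpressionMatrix(raw_counts, totals)


def detection_summary(
    m: ExpressionMatrix, min_count: int = 1, few_threshold: int = 5
) -> tuple[pd.Series, dict]:
    """Per-gene number of samples with count >= ``min_count`` plus tallies of
    genes detected in all samples and in fewer than ``few_threshold`` samples."""
    detected = (m.raw_counts >= min_count).sum(axis=1)
    tallies = {
        "n_samples": m.raw_counts.shape[1],
        "detected_in_all": int((detected == m.raw_counts.shape[1]).sum()),
        f"detected_in_fewer_than_{few_threshold}": int(
            (detected < few_threshold).sum()
        ),
    }
    return detected, tallies


def coefficient_of_variation(m: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene CV (%) of normalized expression: 100 x sample SD / mean.

    Sample standard deviation uses the n-1 denominator. Genes with zero mean
    have no finite CV; they are flagged (``zero_mean``) with CV set to NaN
    rather than dropped.
    """
    norm = m.normalized
    mean = norm.mean(axis=1)
    sd = norm.std(axis=1, ddof=1)
    zero = mean == 0
    cv = pd.Series(np.nan, index=norm.index, name="cv_pct")
    cv[~zero] = 100.0 * sd[~zero] / mean[~zero]
    return pd.DataFrame({"cv_pct": cv, "zero_mean": zero})


@dataclass(frozen=True)
class GroupComparison:
    statistic: float
    p_value: float
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int

    def format_means(self, digits: int = 2) -> str:
        """Render group means the way comparisons are conventionally quoted,
        e.g. ``46.67 +/- 30.12 versus 36.58 +/- 22.69``."""
        return (
            f"{self.mean_a:.{digits}f} +/- {self.sd_a:.{digits}f} versus "
            f"{self.mean_b:.{digits}f} +/- {self.sd_b:.{digits}f}"
        )


def compare_groups(
    values_a, values_b, test: str = "student"
) -> GroupComparison:
    """Two-sided two-sample t-test (``student`` pooled or ``welch``).

    When both groups are constant and equal the statistic is 0 and p = 1 by
    convention (no evidence of a difference).
    """
    if test not in ("student", "welch"):
        raise ValueError("test must be 'student' or 'welch'")
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and a.mean() == b.mean():
        stat, p = 0.0, 1.0
    else:
        stat, p = stats.ttest_ind(a, b, equal_var=(test == "student"))
        stat, p = float(stat), float(p)
    return GroupComparison(
        statistic=stat,
        p_value=p,
        mean_a=float(a.mean()),
        sd_a=float(a.std(ddof=1)),
        n_a=int(a.size),
        mean_b=float(b.mean()),
        sd_b=float(b.std(ddof=1)),
        n_b=int(b.size),
    )


def _window_density(
    positions: np.ndarray, start: int, end: int, chrom_length: int | None
) -> float:
    lo = max(0, start)
    hi = end if chrom_length is None else min(end, chrom_length)
    if hi <= lo:
        return float("nan")
    count = int(
        np.searchsorted(positions, hi, side="left")
        - np.searchsorted(positions, lo, side="left")
    )
    return count / ((hi - lo) / 1000.0)


def snp_density(
    loci,
    snp_positions: pd.DataFrame,
    upstream_bp: int = 10_000,
    downstream_bp: int = 1_000,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """SNPs/kb in the regulatory windows flanking each locus.

    The upstream window runs ``upstream_bp`` 5' of the transcription start
    site, the downstream window ``downstream_bp`` 3' of the transcript end —
    both strand-aware (for a minus-strand locus the upstream window lies on
    the higher-coordinate side). Windows are truncated at chromosome bounds
    and densities computed over the truncated width.

    ``loci`` is an iterable of objects with ``span`` (``GenomicInterval``) and
    an id attribute (``locus_id`` or ``transcript_id``); ``snp_positions`` a
    DataFrame with columns ``chrom`` and ``pos`` (0-based).
    """
    by_chrom: dict[str, np.ndarray] = {
        chrom: np.sort(grp["pos"].to_numpy())
        for chrom, grp in snp_positions.groupby("chrom")
    }
    empty = np.empty(0, dtype=int)
    rows = []
    for locus in loci:
        span: GenomicInterval = locus.span
        lid = getattr(locus, "locus_id", None) or getattr(locus, "transcript_id")
        positions = by_chrom.get(span.chrom, empty)
        clen = chrom_lengths.get(span.chrom) if chrom_lengths else None
        if span.strand == "-":
            up = (span.end, span.end + upstream_bp)
            down = (span.start - downstream_bp, span.start)
        else:
            up = (span.start - upstream_bp, span.start)
            down = (span.end, span.end + downstream_bp)
        rows.append(
            {
                "locus_id": lid,
                "upstream_density": _window_density(positions, *up, clen),
                "downstream_density": _window_density(positions, *down, clen),
            }
        )
    return pd.DataFrame(rows).set_index("locus_id")


def _round_half_up(x: float, digits: int = 2) -> float:
    return float(Decimal(repr(x)).quantize(Decimal(f"1e-{digits}"), ROUND_HALF_UP))


@dataclass
class MappingSummary:
    """Per-sample read-mapping table plus run-level totals."""

    per_sample: pd.DataFrame
    total_pairs: int
    total_gigabases: float
    read_length_bp: int


def mapping_summary(per_sample_counts, read_length_bp: int = 100) -> MappingSummary:
    """Derive the mapping-rate arithmetic from raw per-sample read counts.

    ``per_sample_counts`` is a DataFrame (or dict-of-dicts, samples as keys)
    with ``n_reads``, ``n_mapped``, ``n_uniquely_mapped`` and optionally
    ``n_uniquely_mapped_pairs``. Read counts are single-read counts, so the
    run-wide number of read *pairs* is the total divided by two. Percentages
    are rounded half-up to 2 decimals; gigabases = reads x read length / 1e9.
    """
    df = (
        per_sample_counts.copy()
        if isinstance(per_sample_counts, pd.DataFrame)
        else pd.DataFrame.from_dict(per_sample_counts, orient="index")
    )
    required = ["n_reads", "n_mapped", "n_uniquely_mapped"]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"missing column {col!r}")
    if (df["n_reads"] <= 0).any():
        raise ValueError("n_reads must be positive for every sample")
    if (df[required] < 0).to_numpy().any():
        raise ValueError("read counts must be non-negative")
    if (df["n_uniquely_mapped"] > df["n_mapped"]).any() or (
        df["n_mapped"] > df["n_reads"]
    ).any():
        raise ValueError("need n_uniquely_mapped <= n_mapped <= n_reads")

    df["pct_mapped"] = [
        _round_half_up(100.0 * m / r) for m, r in zip(df["n_mapped"], df["n_reads"])
    ]
    df["pct_uniquely_mapped"] = [
        _round_half_up(100.0 * u / r)
        for u, r in zip(df["n_uniquely_mapped"], df["n_reads"])
    ]
    df["gigabases"] = [
        _round_half_up(r * read_length_bp / 1e9) for r in df["n_reads"]
    ]
    total_reads = int(df["n_reads"].sum())
    return MappingSummary(
        per_sample=df,
        total_pairs=total_reads // 2,
        total_gigabases=_round_half_up(total_reads * read_length_bp / 1e9),
        read_length_bp=read_length_bp,
    )
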