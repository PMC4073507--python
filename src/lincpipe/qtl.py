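"""QTL interval overlap and trait-group enrichment.

LincRNA loci are intersected with trait-labelled QTL intervals (>= 1 bp
overlap under half-open coordinates). QTLs carry one of two trait groups —
meat quality / muscle-related versus everything else — and a 1-df chi-squared
goodness-of-fit test asks whether the number of locus-QTL overlap events in
the two groups departs from expectation. Two expectation models are offered:
``span_proportional`` (events proportional to each group's summed base-pair
span; the default, since larger QTL groups intercept more of a uniformly
placed locus set) and ``count_proportional`` (proportional to the number of
QTLs per group).
"""

from __future__ import annotations

from dataclasses import dataclass

from intervaltree import IntervalTree
from scipy import stats

from .intervals import GenomicInterval, Locus

__all__ = [
    "QtlInterval",
    "EnrichmentResult",
    "overlap_qtl",
    "chi_square_enrichment",
    "assign_trait_groups",
    "DEFAULT_MEAT_MUSCLE_KEYWORDS",
]

TRAIT_GROUPS = ("meat_muscle", "other")

#: Keyword list shipped for convenience; only applied when explicitly
#: requested via :func:`assign_trait_groups`.
DEFAULT_MEAT_MUSCLE_KEYWORDS = (
    "tenderness",
    "marbling",
    "shear force",
    "meat",
    "muscle",
    "carcass",
    "beef",
    "intramuscular fat",
)


@dataclass(frozen=True)
class QtlInterval:
    """A trait-labelled genomic interval."""

    interval: GenomicInterval
    trait_name: str
    trait_group: str

    def __post_init__(self) -> None:
        if self.trait_group not in TRAIT_GROUPS:
            raise ValueError(f"trait_group must be one of {TRAIT_GROUPS}")


def assign_trait_groups(
    trait_names, keywords=DEFAULT_MEAT_MUSCLE_KEYWORDS
) -> list[str]:
    """Map trait names to groups by keyword match (case-insensitive)."""
    out = []
    for name in trait_names:
        low = name.lower()
        out.append(
            "meat_muscle" if any(k in low for k in keywords) else "other"
        )
    return out


def overlap_qtl(
    loci: list[Locus], qtls: list[QtlInterval]
) -> tuple[dict[str, list[QtlInterval]], list[int]]:
    """Intersect locus spans with QTL intervals (>= 1 bp, strand-blind).

    Returns both directions of the mapping: per-locus lists of overlapping
    QTLs, and per-QTL lincRNA-locus counts aligned with the input order.
    Overlapping or nested QTLs are counted as distinct regions.
    """
    trees: dict[str, IntervalTree] = {}
    for idx, q in enumerate(qtls):
        trees.setdefault(q.interval.chrom, IntervalTree()).addi(
            q.interval.start, q.interval.end, idx
        )
    per_locus: dict[str, list[QtlInterval]] = {}
    per_qtl = [0] * len(qtls)
    for locus in loci:
        span = locus.span
        tree = trees.get(span.chrom)
        hits = sorted(iv.data for iv in tree.overlap(span.start, span.end)) if tree else []
        per_locus[locus.locus_id] = [qtls[i] for i in hits]
        for i in hits:
            per_qtl[i] += 1
    return per_locus, per_qtl


@dataclass
class EnrichmentResult:
    observed: dict[str, int]
    expected: dict[str, float]
    statistic: float
    dof: int
    p_value: float
    expectation_model: str


def chi_square_enrichment(
    overlaps: dict[str, list[QtlInterval]],
    qtls: list[QtlInterval],
    expectation: str = "span_proportional",
) -> EnrichmentResult:
    """Chi-squared goodness-of-fit of overlap events across the two groups.

    ``overlaps`` is the per-locus mapping from :func:`overlap_qtl`; observed
    counts are locus-QTL overlap *events* per trait group. Expected counts
    distribute the total events proportionally to group span
    (``span_proportional``) or group QTL count (``count_proportional``).
    """
    if expectation not in ("span_proportional", "count_proportional"):
        raise ValueError(f"unknown expectation model {expectation!r}")
    for group in TRAIT_GROUPS:
        if not any(q.trait_group == group for q in qtls):
            raise ValueError(f"no QTL in group {group!r}")

    observed = {g: 0 for g in TRAIT_GROUPS}
    for hits in overlaps.values():
        for q in hits:
            observed[q.trait_group] += 1
    total = sum(observed.values())

    if expectation == "span_proportional":
        weight = {
            g: sum(q.interval.length for q in qtls if q.trait_group == g)
            for g in TRAIT_GROUPS
        }
    else:
        weight = {
            g: sum(1 for q in qtls if q.trait_group == g) for g in TRAIT_GROUPS
        }
    wsum = sum(weight.values())
    expected = {g: total * weight[g] / wsum for g in TRAIT_GROUPS}
    if any(e <= 0 for e in expected.values()):
        raise ValueError("zero expected count; chi-squared test invalid")

    f_obs = [observed[g] for g in TRAIT_GROUPS]
    f_exp = [expected[g] for g in TRAIT_GROUPS]
    statistic, p_value = stats.chisquare(f_obs, f_exp)
    return EnrichmentResult(
        observed=observed,
        expected=expected,
        statistic=float(statistic),
        dof=len(TRAIT_GROUPS) - 1,
        p_value=float(p_value),
        expectation_model=expectation,
    )
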