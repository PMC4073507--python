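"""Classify assembled transcripts against a reference annotation.

Implements Cuffcompare-style class codes, extraction of intergenic ("u")
lincRNA candidates via the multi-exon / >200 nt filter, and clustering of
transcripts into loci by transitive same-strand exonic overlap.

Class-code semantics (query q vs one reference transcript r, same chromosome):

``=``  identical, non-empty intron chain (both multi-exon), compatible strand
``c``  contained: every q exon inside an r exon and every q intron equal to an
       r intron (exonic sub-chain), compatible strand
``j``  shares >= 1 intron boundary (splice site) with r but is not ``=``
``e``  single-exon q overlapping an r exon and >= 10 bp of an r intron
       (possible pre-mRNA fragment), compatible strand
``o``  generic same-strand exonic overlap not qualifying as =, c, j or e
``i``  single-exon q falling entirely within an r intron, compatible strand
``x``  exonic overlap with r on the opposite strand
``s``  an intron of q overlaps an r intron on the opposite strand
``p``  no span overlap but within 2 kb of r's span, compatible strand
       (possible polymerase run-on fragment)
``u``  none of the above against any reference transcript

A query is evaluated against every reference transcript and accumulates every
code it satisfies; the primary code is chosen by the precedence
``= > c > j > e > o > i > x > s > p > u``. Queries with more than one code are
flagged multi-classified (the "." tracking category).
"""

from __future__ import annotations

from dataclasses import dataclass

from .intervals import (
    GenomicInterval,
    Locus,
    TranscriptModel,
    strands_compatible,
    strands_opposite,
)

#: Precedence order used to pick the primary class code.
CODE_PRECEDENCE = ("=", "c", "j", "e", "o", "i", "x", "s", "p", "u")

#: Maximum gap (bp) for the polymerase run-on code "p".
RUNON_WINDOW_BP = 2_000

#: Minimum intronic overlap (bp) for the pre-mRNA fragment code "e".
E_MIN_INTRON_OVERLAP_BP = 10


@dataclass
class ClassCodeResult:
    """A transcript's relationship to the reference annotation."""

    transcript_id: str
    codes: frozenset[str]
    primary_code: str
    matched_reference_id: str | None

    def __post_init__(self) -> None:
        if self.primary_code not in self.codes:
            raise ValueError("primary_code must be a member of codes")

    @property
    def multi_classified(self) -> bool:
        """True when the transcript falls into several categories ("." tracking)."""
        return len(self.codes) > 1


def _exonic_overlap(q: TranscriptModel, r: TranscriptModel) -> bool:
    return any(qe.overlaps(re) for qe in q.exons for re in r.exons)


def _codes_against(q: TranscriptModel, r: TranscriptModel) -> set[str]:
    """All class codes query q earns against a single reference transcript r."""
    if q.chrom != r.chrom:
        return set()
    codes: set[str] = set()
    same = strands_compatible(q.strand, r.strand)
    opposite = strands_opposite(q.strand, r.strand)
    exonic = _exonic_overlap(q, r)
    q_introns = q.introns
    r_introns = r.introns

    is_eq = same and len(q_introns) > 0 and q.intron_chain == r.intron_chain
    if is_eq:
        codes.add("=")

    if same and exonic:
        r_intron_set = set(r.intron_chain)
        contained = all(
            any(re.contains(qe) for re in r.exons) for qe in q.exons
        ) and all((qi.start, qi.end) in r_intron_set for qi in q_introns)
        if contained:
            codes.add("c")

    if same and q_introns and not is_eq:
        q_sites = {p for i in q_introns for p in (i.start, i.end)}
        r_sites = {p for i in r_introns for p in (i.start, i.end)}
        if q_sites & r_sites:
            codes.add("j")

    is_e = False
    if same and q.n_exons == 1 and exonic:
        qe = q.exons[0]
        if any(qe.overlap_length(ri) >= E_MIN_INTRON_OVERLAP_BP for ri in r_introns):
            is_e = True
            codes.add("e")

    if same and exonic and not (is_eq or "c" in codes or "j" in codes or is_e):
        codes.add("o")

    if same and q.n_exons == 1:
        qe = q.exons[0]
        if any(ri.contains(qe) for ri in r_introns):
            codes.add("i")

    if opposite and exonic:
        codes.add("x")

    if opposite and any(qi.overlaps(ri) for qi in q_introns for ri in r_introns):
        codes.add("s")

    if same and not q.span.overlaps(r.span):
        if q.span.gap_to(r.span) <= RUNON_WINDOW_BP:
            codes.add("p")

    return codes


def assign_class_code(
    query: TranscriptModel, reference: list[TranscriptModel] | tuple[TranscriptModel, ...]
) -> ClassCodeResult:
    """Classify one query transcript against a set of reference transcripts.

    Returns the full set of codes earned against any reference transcript,
    the precedence-selected primary code, and the reference transcript backing
    the primary code (None for "u" and "p", which carry no matched reference).
    """
    per_code_refs: dict[str, list[TranscriptModel]] = {}
    for r in reference:
        for code in _codes_against(query, r):
            per_code_refs.setdefault(code, []).append(r)

    if not per_code_refs:
        return ClassCodeResult(query.transcript_id, frozenset({"u"}), "u", None)

    codes = frozenset(per_code_refs)
    primary = next(c for c in CODE_PRECEDENCE if c in codes)
    matched: str | None = None
    if primary not in ("u", "p"):
        backing = min(
            per_code_refs[primary], key=lambda r: (r.span.start, r.transcript_id)
        )
        matched = backing.transcript_id
    return ClassCodeResult(query.transcript_id, codes, primary, matched)


def classify_transcripts(
    queries: list[TranscriptModel], reference: list[TranscriptModel]
) -> list[tuple[TranscriptModel, ClassCodeResult]]:
    """Classify every query; reference is indexed per chromosome for speed."""
    by_chrom: dict[str, list[TranscriptModel]] = {}
    for r in reference:
        by_chrom.setdefault(r.chrom, []).append(r)
    return [
        (q, assign_class_code(q, by_chrom.get(q.chrom, [])))
        for q in queries
    ]


def filter_linc_candidates(
    classified: list[tuple[TranscriptModel, ClassCodeResult]],
    min_length: int = 200,
    min_exons: int = 2,
) -> list[TranscriptModel]:
    """Keep unknown-intergenic ("u") transcripts with multiple exons and a
    spliced length strictly greater than ``min_length`` nt. Order preserved."""
    return [
        t
        for t, cc in classified
        if cc.primary_code == "u" and t.n_exons >= min_exons and t.length > min_length
    ]


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def cluster_loci(transcripts: list[TranscriptModel]) -> list[Locus]:
    """Merge transcripts sharing >= 1 bp exonic overlap (same chrom & strand)
    transitively into loci; locus ids are deterministic given sorted input.

    Uses a sweep over exons: exons falling into the same merged exon block
    connect their transcripts; a union-find closes the transitive chain for
    transcripts spanning several blocks.
    """
    uf = _UnionFind(len(transcripts))
    by_group: dict[tuple[str, str], list[tuple[GenomicInterval, int]]] = {}
    for idx, t in enumerate(transcripts):
        for ex in t.exons:
            by_group.setdefault((t.chrom, t.strand), []).append((ex, idx))

    for exons in by_group.values():
        exons.sort(key=lambda p: (p[0].start, p[0].end))
        block_end = -1
        block_rep = -1
        for ex, idx in exons:
            if ex.start < block_end:  # overlaps current block
                uf.union(block_rep, idx)
                block_end = max(block_end, ex.end)
            else:
                block_rep = idx
                block_end = ex.end

    members: dict[int, list[TranscriptModel]] = {}
    for idx, t in enumerate(transcripts):
        members.setdefault(uf.find(idx), []).append(t)

    loci = []
    for group in members.values():
        start = min(t.exons[0].start for t in group)
        end = max(t.exons[-1].end for t in group)
        span = GenomicInterval(group[0].chrom, start, end, group[0].strand)
        loci.append((span, frozenset(t.transcript_id for t in group)))
    loci.sort(key=lambda p: (p[0].chrom, p[0].start, p[0].end, p[0].strand))
    return [
        Locus(f"XLOC_{i + 1:06d}", ids, span) for i, (span, ids) in enumerate(loci)
    ]
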