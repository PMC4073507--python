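"""Class-code assignment, candidate filtering and locus clustering."""

import networkx as nx
import numpy as np
import pytest

from lincpipe.annotation import (
    CODE_PRECEDENCE,
    assign_class_code,
    cluster_loci,
    filter_linc_candidates,
)
from lincpipe.intervals import (
    StructuralValidationError,
    strands_compatible,
    strands_opposite,
)

from conftest import make_transcript, random_transcript


# ---------------------------------------------------------------------------
# Brute-force oracle: a direct, loop-based re-expression of the legend
# predicates, independent of the package implementation.
# ---------------------------------------------------------------------------

def _overlap(a, b):
    return a[0] < b[1] and b[0] < a[1]


def _oracle_codes(q, r):
    if q.chrom != r.chrom:
        return set()
    same = strands_compatible(q.strand, r.strand)
    opp = strands_opposite(q.strand, r.strand)
    q_ex = [(e.start, e.end) for e in q.exons]
    r_ex = [(e.start, e.end) for e in r.exons]
    q_in = [(i.start, i.end) for i in q.introns]
    r_in = [(i.start, i.end) for i in r.introns]
    exonic = any(_overlap(a, b) for a in q_ex for b in r_ex)
    codes = set()
    eq = same and len(q_in) > 0 and q_in == r_in
    if eq:
        codes.add("=")
    if same and exonic:
        if all(any(b[0] <= a[0] and a[1] <= b[1] for b in r_ex) for a in q_ex) and all(
            i in r_in for i in q_in
        ):
            codes.add("c")
    if same and q_in and not eq:
        q_sites = {p for i in q_in for p in i}
        r_sites = {p for i in r_in for p in i}
        if q_sites & r_sites:
            codes.add("j")
    is_e = False
    if same and len(q_ex) == 1 and exonic:
        a = q_ex[0]
        for b in r_in:
            if min(a[1], b[1]) - max(a[0], b[0]) >= 10:
                is_e = True
        if is_e:
            codes.add("e")
    if same and exonic and not (eq or "c" in codes or "j" in codes or is_e):
        codes.add("o")
    if same and len(q_ex) == 1:
        a = q_ex[0]
        if any(b[0] <= a[0] and a[1] <= b[1] for b in r_in):
            codes.add("i")
    if opp and exonic:
        codes.add("x")
    if opp and any(_overlap(a, b) for a in q_in for b in r_in):
        codes.add("s")
    if same:
        q_span = (q_ex[0][0], q_ex[-1][1])
        r_span = (r_ex[0][0], r_ex[-1][1])
        if not _overlap(q_span, r_span):
            gap = max(q_span[0], r_span[0]) - min(q_span[1], r_span[1])
            if gap <= 2000:
                codes.add("p")
    return codes


def _oracle_primary(q, reference):
    codes = set()
    for r in reference:
        codes |= _oracle_codes(q, r)
    if not codes:
        codes = {"u"}
    return next(c for c in CODE_PRECEDENCE if c in codes), frozenset(codes)


REF = make_transcript(
    "ref1", "chr1", "+", [(1000, 1200), (1500, 1700), (2000, 2200)], "gref1"
)


@pytest.mark.parametrize(
    "exons,strand,expected",
    [
        # identical intron chain, extended terminal exons -> complete match
        ([(900, 1200), (1500, 1700), (2000, 2300)], "+", "="),
        # single exon inside a reference exon -> contained
        ([(1520, 1680)], "+", "c"),
        # shares the first intron but extends into the second -> novel isoform
        ([(1000, 1200), (1500, 1750)], "+", "j"),
        # single exon across an exon/intron junction -> pre-mRNA fragment
        ([(1150, 1260)], "+", "e"),
        # multi-exon overlap, no shared boundaries -> generic overlap
        ([(700, 800), (950, 1100)], "+", "o"),
        # single exon wholly inside an intron -> intronic
        ([(1250, 1400)], "+", "i"),
        # exonic overlap on the opposite strand -> antisense
        ([(1100, 1250)], "-", "x"),
        # intron overlapping a reference intron, opposite strand, no exons hit
        ([(1210, 1260), (1430, 1480)], "-", "s"),
        # within 2 kb downstream, no overlap -> run-on fragment
        ([(2500, 2800)], "+", "p"),
        # far away -> unknown intergenic
        ([(50_000, 50_300), (51_000, 51_400)], "+", "u"),
    ],
)
def test_primary_code_examples(exons, strand, expected):
    q = make_transcript("q", "chr1", strand, exons)
    result = assign_class_code(q, [REF])
    assert result.primary_code == expected
    if expected in ("u", "p"):
        assert result.matched_reference_id is None
    else:
        assert result.matched_reference_id == "ref1"


def test_query_on_absent_chromosome_is_unknown():
    q = make_transcript("q", "chr9", "+", [(1000, 1200)])
    result = assign_class_code(q, [REF])
    assert result.primary_code == "u"
    assert result.codes == {"u"}
    assert result.matched_reference_id is None


def test_class_codes_match_bruteforce_oracle_on_random_transcripts():
    rng = np.random.default_rng(42)
    reference = [random_transcript(rng, f"r{i}") for i in range(50)]
    queries = [random_transcript(rng, f"q{i}") for i in range(200)]
    for q in queries:
        got = assign_class_code(q, reference)
        want_primary, want_codes = _oracle_primary(q, reference)
        assert got.primary_code == want_primary, q.transcript_id
        assert got.codes == want_codes, q.transcript_id


def test_classification_invariant_under_coordinate_translation():
    rng = np.random.default_rng(7)
    reference = [random_transcript(rng, f"r{i}") for i in range(20)]
    queries = [random_transcript(rng, f"q{i}") for i in range(40)]
    offset = 12_345
    for q in queries:
        a = assign_class_code(q, reference)
        b = assign_class_code(q.shifted(offset), [r.shifted(offset) for r in reference])
        assert (a.codes, a.primary_code) == (b.codes, b.primary_code)


def test_malformed_exons_rejected():
    with pytest.raises(StructuralValidationError):
        make_transcript("bad", "chr1", "+", [(100, 300), (200, 400)])


class TestFilterCandidates:
    def _classified(self, transcripts, reference=()):
        return [(t, assign_class_code(t, list(reference))) for t in transcripts]

    def test_single_exon_and_short_transcripts_excluded(self):
        long_single = make_transcript("a", "chr1", "+", [(0, 500)])
        short_multi = make_transcript("b", "chr1", "+", [(0, 70), (200, 280)])
        good = make_transcript("c", "chr1", "+", [(0, 150), (400, 500)])
        exactly_200 = make_transcript("d", "chr1", "+", [(0, 100), (300, 400)])
        out = filter_linc_candidates(
            self._classified([long_single, short_multi, good, exactly_200])
        )
        assert [t.transcript_id for t in out] == ["c"]

    def test_non_u_transcripts_excluded_and_filter_idempotent(self):
        inside = make_transcript("in", "chr1", "+", [(1000, 1210), (1500, 1700)])
        away = make_transcript("out", "chr1", "+", [(9000, 9210), (9500, 9700)])
        classified = self._classified([inside, away], [REF])
        out = filter_linc_candidates(classified)
        assert [t.transcript_id for t in out] == ["out"]
        again = filter_linc_candidates(
            [(t, assign_class_code(t, [REF])) for t in out]
        )
        assert again == out

    def test_planted_attribute_table(self, default_bundle):
        truth = default_bundle.truth
        classified = [
            (t, assign_class_code(t, default_bundle.reference))
            for t in default_bundle.queries
        ]
        out = {t.transcript_id for t in filter_linc_candidates(classified)}
        want = {
            tid for tid, ok in truth.passes_size_filter.items() if ok
        }
        assert out == want


class TestClusterLoci:
    def test_same_strand_overlap_merges(self):
        a = make_transcript("a", "chr1", "+", [(0, 100), (200, 300)])
        b = make_transcript("b", "chr1", "+", [(250, 400)])
        loci = cluster_loci([a, b])
        assert len(loci) == 1
        assert loci[0].member_transcript_ids == {"a", "b"}
        assert (loci[0].span.start, loci[0].span.end) == (0, 400)

    def test_opposite_strands_stay_separate(self):
        a = make_transcript("a", "chr1", "+", [(0, 100)])
        b = make_transcript("b", "chr1", "-", [(0, 100)])
        assert len(cluster_loci([a, b])) == 2

    def test_intron_spanning_does_not_merge(self):
        outer = make_transcript("o", "chr1", "+", [(0, 100), (900, 1000)])
        inner = make_transcript("i", "chr1", "+", [(300, 500)])
        assert len(cluster_loci([outer, inner])) == 2

    def test_partition_matches_graph_components(self):
        rng = np.random.default_rng(3)
        transcripts = [
            random_transcript(rng, f"t{i}", max_pos=20_000) for i in range(100)
        ]
        g = nx.Graph()
        g.add_nodes_from(t.transcript_id for t in transcripts)
        for i, a in enumerate(transcripts):
            for b in transcripts[i + 1 :]:
                if a.chrom == b.chrom and a.strand == b.strand and any(
                    ea.overlaps(eb) for ea in a.exons for eb in b.exons
                ):
                    g.add_edge(a.transcript_id, b.transcript_id)
        want = {frozenset(c) for c in nx.connected_components(g)}
        got = {frozenset(l.member_transcript_ids) for l in cluster_loci(transcripts)}
        assert got == want

    def test_locus_ids_deterministic_and_members_cover_input(self):
        rng = np.random.default_rng(5)
        transcripts = [
            random_transcript(rng, f"t{i}", max_pos=30_000) for i in range(80)
        ]
        loci_a = cluster_loci(transcripts)
        loci_b = cluster_loci(transcripts)
        assert [(l.locus_id, l.member_transcript_ids) for l in loci_a] == [
            (l.locus_id, l.member_transcript_ids) for l in loci_b
        ]
        covered = [t for l in loci_a for t in l.member_transcript_ids]
        assert sorted(covered) == sorted(t.transcript_id for t in transcripts)
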