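"""Synthetic data with known ground truth for every pipeline stage.

The generator emulates the full input bundle of a muscle RNA-Seq lincRNA
survey: a reference annotation plus query transcripts planted to satisfy each
class-code predicate by construction; coding vs non-coding transcript
sequences differing in ORF structure and hexamer composition (a single
``divergence`` knob interpolates from indistinguishable to well separated);
codon-constrained (synonymous-biased) vs neutral multi-species alignments;
negative-binomial count matrices over nine samples with planted perfectly
co-monotone lincRNA/coding pairs and inflated lincRNA dispersion; uniform
SNPs; and QTL intervals in two trait groups.

One seeded generator drives all sub-simulators through independent
substreams, so adding or re-running a stage never perturbs earlier outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .coding import AA_ALPHABET, CodonAlignment, MotifDb, PwmMotif, find_longest_orf
from .intervals import GenomicInterval, TranscriptModel
from .qtl import QtlInterval

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "ConfigError",
    "SyntheticBundle",
    "simulate_annotation_and_queries",
    "simulate_sequences",
    "simulate_alignments",
    "simulate_counts",
    "simulate_snps_and_qtls",
    "simulate_motifs",
    "simulate_bundle",
    "write_bundle",
]

_SENSE_CODONS = sorted(standard_dna_table.forward_table)
_STOPS = sorted(standard_dna_table.stop_codons)
_SYNONYMS = {
    c: [
        d
        for d in _SENSE_CODONS
        if d != c and standard_dna_table.forward_table[d] == standard_dna_table.forward_table[c]
    ]
    for c in _SENSE_CODONS
}
_AA_TO_CODON = {}
for _c in _SENSE_CODONS:
    _AA_TO_CODON.setdefault(standard_dna_table.forward_table[_c], _c)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

_MEAT_TRAITS = (
    "meat tenderness",
    "marbling score",
    "shear force",
    "carcass weight",
    "intramuscular fat",
)
_OTHER_TRAITS = (
    "milk yield",
    "stature",
    "somatic cell score",
    "calving ease",
    "coat colour",
)


class ConfigError(ValueError):
    """Simulation geometry or parameters are infeasible."""


def _default_class_counts() -> dict[str, int]:
    return {
        "=": 50,
        "j": 50,
        "c": 20,
        "e": 20,
        "o": 30,
        "i": 30,
        "x": 30,
        "s": 20,
        "p": 30,
        "u": 120,
    }


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study; the defaults are the study design
    (2 chromosomes x 5 Mb, 300 reference genes, 400 queries, 9 samples)."""

    seed: int
    n_chromosomes: int = 2
    chromosome_length: int = 5_000_000
    n_reference_genes: int = 300
    class_code_counts: dict[str, int] = field(default_factory=_default_class_counts)
    n_u_single_exon: int = 10  # carved out of the "u" count
    n_u_short: int = 10  # carved out of the "u" count (spliced length <= 200)
    u_coding_frac: float = 0.5

    # sequence model
    divergence: float = 0.9
    n_training_coding: int = 300
    n_training_noncoding: int = 300
    training_length_range: tuple[int, int] = (400, 2000)
    n_control_coding: int = 100
    n_control_noncoding: int = 100

    # alignments (conservation surrogate inputs)
    species: tuple[str, ...] = ("cow", "human", "mouse", "rat", "dog")
    coding_codon_sub_rate: float = 0.3
    syn_bias: float = 0.9
    noncoding_nt_sub_rate: float = 0.15

    # counts
    n_samples: int = 9
    linc_mean: float = 50.0
    linc_dispersion: float = 0.18
    coding_mean: float = 500.0
    coding_dispersion: float = 0.12
    base_depth: int = 5_000_000
    depth_jitter: float = 0.25
    n_planted_pairs: int = 5
    n_low_detection_genes: int = 15

    # SNPs and QTLs
    snp_rate_per_kb: float = 1.0
    n_qtl_meat_muscle: int = 20
    n_qtl_other: int = 20
    qtl_length_range: tuple[int, int] = (50_000, 400_000)

    # protein-domain motifs
    n_motifs: int = 3
    motif_length: int = 10
    motif_planted_frac: float = 0.3

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        for name in (
            "n_chromosomes",
            "chromosome_length",
            "n_reference_genes",
            "n_samples",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if any(v < 0 for v in self.class_code_counts.values()):
            raise ConfigError("class-code counts must be non-negative")
        for name in ("u_coding_frac", "syn_bias", "motif_planted_frac"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1]")
        if not (0.0 <= self.divergence <= 1.0):
            raise ConfigError("divergence must lie in [0, 1]")
        if self.n_u_single_exon + self.n_u_short > self.class_code_counts.get("u", 0):
            raise ConfigError("single-exon + short 'u' counts exceed the 'u' total")

    @property
    def chromosomes(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    @property
    def chromosome_lengths(self) -> dict[str, int]:
        return {c: self.chromosome_length for c in self.chromosomes}


@dataclass
class GroundTruth:
    """Book-keeping for every emitted entity (each appears exactly once)."""

    true_class: dict[str, str] = field(default_factory=dict)
    coding_label: dict[str, str] = field(default_factory=dict)
    passes_size_filter: dict[str, bool] = field(default_factory=dict)
    true_orf: dict[str, tuple[int, int]] = field(default_factory=dict)
    control_labels: dict[str, str] = field(default_factory=dict)
    gene_group: dict[str, str] = field(default_factory=dict)
    true_dispersion: dict[str, float] = field(default_factory=dict)
    planted_pairs: list[tuple[str, str]] = field(default_factory=list)
    low_detection: dict[str, int] = field(default_factory=dict)
    qtl_groups: list[str] = field(default_factory=list)
    motif_planted: dict[str, str] = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = dataclasses.asdict(self)
        payload["planted_pairs"] = [list(p) for p in self.planted_pairs]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        payload["planted_pairs"] = [tuple(p) for p in payload["planted_pairs"]]
        payload["true_orf"] = {k: tuple(v) for k, v in payload["true_orf"].items()}
        return cls(**payload)


def _stage_rng(cfg: SimulationConfig, stage: int) -> np.random.Generator:
    """Independent substream per stage, all derived from the single seed."""
    return np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(8)[stage])


def _random_seq(rng: np.random.Generator, n: int) -> str:
    if n <= 0:
        return ""
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


# ---------------------------------------------------------------------------
# Annotation + planted class codes
# ---------------------------------------------------------------------------

def _make_reference_gene(
    rng: np.random.Generator, chrom: str, start: int, idx: int
) -> TranscriptModel:
    n_exons = int(rng.integers(3, 8))
    exon_lens = rng.integers(120, 251, n_exons)
    intron_lens = rng.integers(200, 1001, n_exons - 1)
    strand = "+" if rng.random() < 0.5 else "-"
    exons = []
    pos = start
    for i in range(n_exons):
        exons.append(GenomicInterval(chrom, pos, pos + int(exon_lens[i]), strand))
        pos += int(exon_lens[i])
        if i < n_exons - 1:
            pos += int(intron_lens[i])
    return TranscriptModel(
        f"REF_T_{idx:04d}", f"REF_G_{idx:04d}", chrom, strand, exons, biotype="coding"
    )


def simulate_annotation_and_queries(
    cfg: SimulationConfig,
) -> tuple[list[TranscriptModel], list[TranscriptModel], GroundTruth]:
    """Reference transcripts plus queries constructed to satisfy each
    requested class-code predicate by construction. Deterministic per seed."""
    rng = _stage_rng(cfg, 0)
    truth = GroundTruth()

    intergap = 24_000
    margin = 15_000
    reference: list[TranscriptModel] = []
    gaps: list[tuple[str, int, int]] = []  # intergenic (chrom, start, end)
    chrom_iter = iter(cfg.chromosomes)
    chrom = next(chrom_iter)
    cursor = margin
    prev_end = 0
    for idx in range(cfg.n_reference_genes):
        gene = _make_reference_gene(rng, chrom, cursor, idx)
        while gene.span.end > cfg.chromosome_length - margin:
            nxt = next(chrom_iter, None)
            if nxt is None:
                raise ConfigError(
                    "chromosomes too short for the requested number of reference genes"
                )
            chrom, cursor, prev_end = nxt, margin, 0
            gene = _make_reference_gene(rng, chrom, cursor, idx)
        if prev_end:
            gaps.append((chrom, prev_end, gene.span.start))
        reference.append(gene)
        prev_end = gene.span.end
        cursor = gene.span.end + intergap

    gap_queue = list(gaps)

    def take_gap() -> tuple[str, int, int]:
        if not gap_queue:
            raise ConfigError("not enough intergenic space for 'u'/'p' queries")
        return gap_queue.pop(0)

    queries: list[TranscriptModel] = []
    qidx = 0

    def add_query(code: str, chrom: str, strand: str, exon_coords) -> TranscriptModel:
        nonlocal qidx
        qidx += 1
        tid, gid = f"QT_{qidx:06d}", f"QG_{qidx:06d}"
        exons = [GenomicInterval(chrom, s, e, strand) for s, e in exon_coords]
        t = TranscriptModel(tid, gid, chrom, strand, exons)
        queries.append(t)
        truth.true_class[tid] = code
        return t

    gene_cycle = 0

    def next_gene() -> TranscriptModel:
        nonlocal gene_cycle
        g = reference[gene_cycle % len(reference)]
        gene_cycle += 1
        return g

    for code, count in cfg.class_code_counts.items():
        if code in ("u", "p"):
            continue
        for _ in range(count):
            g = next_gene()
            ex = g.exons
            if code == "=":
                d1 = int(rng.integers(10, 81))
                d2 = int(rng.integers(10, 81))
                coords = [(e.start, e.end) for e in ex]
                coords[0] = (coords[0][0] - d1, coords[0][1])
                coords[-1] = (coords[-1][0], coords[-1][1] + d2)
                add_query("=", g.chrom, g.strand, coords)
            elif code == "j":
                intr = g.introns[0]
                delta = int(rng.integers(10, min(80, intr.length - 20)))
                coords = [(e.start, e.end) for e in ex]
                coords[0] = (coords[0][0], coords[0][1] + delta)
                add_query("j", g.chrom, g.strand, coords)
            elif code == "c":
                e1 = ex[1]
                add_query("c", g.chrom, g.strand, [(e1.start + 10, e1.end - 10)])
            elif code == "e":
                e1 = ex[1]
                add_query("e", g.chrom, g.strand, [(e1.end - 60, e1.end + 60)])
            elif code == "o":
                gstart = ex[0].start
                coords = [
                    (gstart - 400, gstart - 200),
                    (gstart - 100, gstart + 50),
                ]
                add_query("o", g.chrom, g.strand, coords)
            elif code == "i":
                intr = g.introns[0]
                add_query(
                    "i", g.chrom, g.strand, [(intr.start + 30, intr.start + 150)]
                )
            elif code == "x":
                e1 = ex[1]
                flipped = "-" if g.strand == "+" else "+"
                add_query("x", g.chrom, flipped, [(e1.start + 10, e1.end - 10)])
            elif code == "s":
                intr = g.introns[0]
                flipped = "-" if g.strand == "+" else "+"
                coords = [
                    (intr.start + 10, intr.start + 50),
                    (intr.end - 50, intr.end - 10),
                ]
                add_query("s", g.chrom, flipped, coords)
            else:
                raise ConfigError(f"unknown class code {code!r} in config")

    for _ in range(cfg.class_code_counts.get("p", 0)):
        chrom, gstart, gend = take_gap()
        offset = int(rng.integers(300, 1501))
        left_gene_strand = next(
            g.strand for g in reference if g.chrom == chrom and g.span.end == gstart
        )
        add_query(
            "p", chrom, left_gene_strand, [(gstart + offset, gstart + offset + 300)]
        )

    n_u = cfg.class_code_counts.get("u", 0)
    u_kinds = (
        ["single"] * cfg.n_u_single_exon
        + ["short"] * cfg.n_u_short
        + ["multi"] * (n_u - cfg.n_u_single_exon - cfg.n_u_short)
    )
    u_candidates: list[str] = []
    for kind in u_kinds:
        chrom, gstart, gend = take_gap()
        lo, hi = gstart + 2_500, gend - 2_500
        if hi - lo < 5_000:
            raise ConfigError("intergenic gap too narrow for a 'u' query")
        strand = "+" if rng.random() < 0.5 else "-"
        start = int(rng.integers(lo, hi - 4_200))
        if kind == "single":
            t = add_query("u", chrom, strand, [(start, start + int(rng.integers(400, 801)))])
            truth.passes_size_filter[t.transcript_id] = False
        elif kind == "short":
            coords = [(start, start + 60), (start + 200, start + 280)]
            t = add_query("u", chrom, strand, coords)
            truth.passes_size_filter[t.transcript_id] = False
        else:
            n_ex = int(rng.integers(2, 5))
            coords = []
            pos = start
            for i in range(n_ex):
                elen = int(rng.integers(150, 401))
                coords.append((pos, pos + elen))
                pos += elen + int(rng.integers(100, 701))
            t = add_query("u", chrom, strand, coords)
            truth.passes_size_filter[t.transcript_id] = True

        if kind == "multi":
            u_candidates.append(t.transcript_id)

    # coding/noncoding ground-truth labels for all "u" transcripts; the
    # multi-exon candidates are split per u_coding_frac exactly.
    n_coding = int(round(cfg.u_coding_frac * len(u_candidates)))
    order = rng.permutation(len(u_candidates))
    for rank, idx in enumerate(order):
        tid = u_candidates[idx]
        truth.coding_label[tid] = "coding" if rank < n_coding else "noncoding"
    for tid, code in truth.true_class.items():
        if code == "u" and tid not in truth.coding_label:
            truth.coding_label[tid] = "noncoding"

    return reference, queries, truth


# ---------------------------------------------------------------------------
# Sequences
# ---------------------------------------------------------------------------

def _codon_weights(divergence: float) -> np.ndarray:
    gc = np.array([c.count("G") + c.count("C") for c in _SENSE_CODONS], dtype=float)
    w = np.exp(1.2 * divergence * gc)
    return w / w.sum()


def _coding_seq(
    rng: np.random.Generator, length: int, divergence: float
) -> tuple[str, tuple[int, int] | None]:
    """Transcript with a planted in-frame ORF whose codon usage is biased by
    ``divergence``; at divergence 0 the generator collapses to the neutral
    (non-coding) model and plants nothing."""
    if divergence <= 0.0 or length < 30:
        return _random_seq(rng, length), None
    frac = 0.30 + 0.45 * divergence
    n_codons = max(6, int(frac * length) // 3 - 2)
    orf_len = 3 * (n_codons + 2)  # ATG + body + stop
    if orf_len > length:
        n_codons = length // 3 - 2
        orf_len = 3 * (n_codons + 2)
    weights = _codon_weights(divergence)
    body = "".join(
        _SENSE_CODONS[i] for i in rng.choice(len(_SENSE_CODONS), n_codons, p=weights)
    )
    stop = _STOPS[int(rng.integers(0, len(_STOPS)))]
    utr_total = length - orf_len
    utr5 = int(rng.integers(0, utr_total + 1)) if utr_total > 0 else 0
    seq = (
        _random_seq(rng, utr5)
        + "ATG"
        + body
        + stop
        + _random_seq(rng, utr_total - utr5)
    )
    return seq, (utr5, utr5 + orf_len)


def _noncoding_seq(rng: np.random.Generator, length: int) -> str:
    return _random_seq(rng, length)


def simulate_sequences(
    cfg: SimulationConfig,
    queries: list[TranscriptModel],
    truth: GroundTruth,
) -> tuple[dict[str, str], list[str], list[str], dict[str, str]]:
    """Sequences for every query plus training and control sets.

    Returns ``(sequences, training_coding, training_noncoding,
    control_sequences)`` and records every planted ORF in the ground truth.
    Coding transcripts carry a long in-frame GC/codon-biased ORF; non-coding
    ones are neutral. Queries outside the "u" class receive neutral sequences
    (they never reach the coding-potential cascade).
    """
    rng = _stage_rng(cfg, 1)
    sequences: dict[str, str] = {}
    for t in queries:
        label = truth.coding_label.get(t.transcript_id)
        if label == "coding":
            seq, orf = _coding_seq(rng, t.length, cfg.divergence)
            if orf is not None:
                truth.true_orf[t.transcript_id] = orf
        else:
            seq = _noncoding_seq(rng, t.length)
        sequences[t.transcript_id] = seq

    lo, hi = cfg.training_length_range
    training_coding = []
    for _ in range(cfg.n_training_coding):
        seq, _orf = _coding_seq(rng, int(rng.integers(lo, hi + 1)), cfg.divergence)
        training_coding.append(seq)
    training_noncoding = [
        _noncoding_seq(rng, int(rng.integers(lo, hi + 1)))
        for _ in range(cfg.n_training_noncoding)
    ]

    control_sequences: dict[str, str] = {}
    for i in range(cfg.n_control_coding):
        cid = f"CTRL_COD_{i:04d}"
        seq, orf = _coding_seq(rng, int(rng.integers(lo, hi + 1)), cfg.divergence)
        control_sequences[cid] = seq
        truth.control_labels[cid] = "coding"
        if orf is not None:
            truth.true_orf[cid] = orf
    for i in range(cfg.n_control_noncoding):
        cid = f"CTRL_NC_{i:04d}"
        control_sequences[cid] = _noncoding_seq(rng, int(rng.integers(lo, hi + 1)))
        truth.control_labels[cid] = "noncoding"

    return sequences, training_coding, training_noncoding, control_sequences


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

def _mutate_coding_row(
    rng: np.random.Generator, ref: str, sub_rate: float, syn_bias: float
) -> str:
    codons = [ref[i : i + 3] for i in range(0, len(ref), 3)]
    out = []
    for codon in codons:
        if len(codon) == 3 and rng.random() < sub_rate:
            if rng.random() < syn_bias:
                alts = _SYNONYMS.get(codon, [])
                if alts:
                    codon = alts[int(rng.integers(0, len(alts)))]
            else:
                while True:
                    alt = _SENSE_CODONS[int(rng.integers(0, len(_SENSE_CODONS)))]
                    if alt != codon:
                        codon = alt
                        break
        out.append(codon)
    return "".join(out)


def _mutate_neutral_row(rng: np.random.Generator, ref: str, nt_rate: float) -> str:
    arr = np.frombuffer(ref.encode(), dtype=np.uint8).copy()
    mask = rng.random(arr.size) < nt_rate
    for i in np.flatnonzero(mask):
        current = arr[i]
        choices = _BASES[_BASES != current]
        arr[i] = choices[int(rng.integers(0, len(choices)))]
    return arr.tobytes().decode()


def simulate_alignments(
    cfg: SimulationConfig,
    sequences: dict[str, str],
    labels: dict[str, str],
) -> dict[str, CodonAlignment]:
    """Gap-free multi-species alignments over each transcript's longest ORF.

    Coding transcripts are mutated with synonymous-biased codon substitutions;
    non-coding ones with uniform nucleotide substitutions. Transcripts without
    an ORF are skipped (no alignment emitted).
    """
    rng = _stage_rng(cfg, 2)
    out: dict[str, CodonAlignment] = {}
    for tid in sorted(labels):
        seq = sequences[tid]
        orf = find_longest_orf(seq)
        if not orf.found:
            continue
        rows = [seq]
        for _sp in cfg.species[1:]:
            if labels[tid] == "coding":
                core = _mutate_coding_row(
                    rng, seq[orf.start : orf.end], cfg.coding_codon_sub_rate, cfg.syn_bias
                )
                flank5 = _mutate_neutral_row(
                    rng, seq[: orf.start], cfg.noncoding_nt_sub_rate
                )
                flank3 = _mutate_neutral_row(
                    rng, seq[orf.end :], cfg.noncoding_nt_sub_rate
                )
                rows.append(flank5 + core + flank3)
            else:
                rows.append(_mutate_neutral_row(rng, seq, cfg.noncoding_nt_sub_rate))
        out[tid] = CodonAlignment(
            species=list(cfg.species), rows=rows, transcript_id=tid
        )
    return out


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------

def _nb_draws(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    mean = np.maximum(mean, 1e-8)
    if dispersion <= 1e-12:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_counts(
    cfg: SimulationConfig,
    truth: GroundTruth,
    linc_gene_ids: list[str],
    coding_gene_ids: list[str],
) -> tuple[pd.DataFrame, pd.Series]:
    """Negative-binomial counts over ``n_samples`` with per-sample depths.

    The lincRNA group receives lower means and higher dispersion than the
    coding group; ``n_planted_pairs`` lincRNA/coding pairs share a latent
    sample ordering making their profiles strictly co-monotone (Spearman rho
    of exactly 1); ``n_low_detection_genes`` lincRNAs are zeroed in most
    samples to plant a detected-in-few-samples tail.
    """
    rng = _stage_rng(cfg, 3)
    samples = [f"S{i + 1}" for i in range(cfg.n_samples)]
    depth = cfg.base_depth * rng.uniform(
        1.0 - cfg.depth_jitter, 1.0 + cfg.depth_jitter, cfg.n_samples
    )
    totals = pd.Series(depth.astype(int), index=samples, name="mapped_reads")
    rel_depth = depth / cfg.base_depth

    genes = list(linc_gene_ids) + list(coding_gene_ids)
    groups = ["linc"] * len(linc_gene_ids) + ["coding"] * len(coding_gene_ids)
    counts = np.zeros((len(genes), cfg.n_samples), dtype=int)
    for i, (gid, group) in enumerate(zip(genes, groups)):
        mean = cfg.linc_mean if group == "linc" else cfg.coding_mean
        disp = cfg.linc_dispersion if group == "linc" else cfg.coding_dispersion
        base = mean * rng.lognormal(0.0, 0.6)
        counts[i] = _nb_draws(rng, base * rel_depth, disp)
        truth.gene_group[gid] = group
        truth.true_dispersion[gid] = disp

    df = pd.DataFrame(counts, index=genes, columns=samples)

    # planted co-monotone pairs (distinct genes, kept away from the
    # low-detection set drawn below)
    # The latent mode is a geometric grid on the *normalized* scale, spaced
    # widely enough (x1.5) that integer rounding of the raw counts can never
    # reorder the normalized profile: the pair is exactly co-monotone.
    n_pairs = min(cfg.n_planted_pairs, len(linc_gene_ids), len(coding_gene_ids))
    grid = 1.5 ** np.arange(cfg.n_samples)
    grid /= np.exp(np.mean(np.log(grid)))
    for k in range(n_pairs):
        lg, cg = linc_gene_ids[k], coding_gene_ids[k]
        latent = grid[rng.permutation(cfg.n_samples)]  # per-pair sample ordering
        for gid, mean in ((lg, cfg.linc_mean), (cg, cfg.coding_mean)):
            raw = np.maximum(1, np.round(mean * latent * rel_depth)).astype(int)
            df.loc[gid] = raw
        truth.planted_pairs.append((lg, cg))

    eligible = [g for g in linc_gene_ids[n_pairs:]]
    n_low = min(cfg.n_low_detection_genes, len(eligible))
    for gid in eligible[:n_low]:
        keep = int(rng.integers(1, 5))  # detected in < 5 samples
        keep_idx = rng.choice(cfg.n_samples, keep, replace=False)
        row = df.loc[gid].to_numpy().copy()
        mask = np.ones(cfg.n_samples, dtype=bool)
        mask[keep_idx] = False
        row[mask] = 0
        row[keep_idx] = np.maximum(row[keep_idx], 1)
        df.loc[gid] = row
        truth.low_detection[gid] = keep

    return df, totals


# ---------------------------------------------------------------------------
# SNPs and QTLs
# ---------------------------------------------------------------------------

def simulate_snps_and_qtls(
    cfg: SimulationConfig, truth: GroundTruth | None = None
) -> tuple[pd.DataFrame, list[QtlInterval]]:
    """Homogeneous-Poisson SNPs along each chromosome and trait-labelled
    QTL intervals in the two trait groups (overlaps allowed; a QTL region is
    counted as distinct even when nested)."""
    rng = _stage_rng(cfg, 4)
    snp_rows = []
    for chrom in cfg.chromosomes:
        n = rng.poisson(cfg.snp_rate_per_kb * cfg.chromosome_length / 1000.0)
        positions = np.sort(rng.integers(0, cfg.chromosome_length, n))
        snp_rows.append(pd.DataFrame({"chrom": chrom, "pos": positions}))
    snps = (
        pd.concat(snp_rows, ignore_index=True)
        if snp_rows
        else pd.DataFrame(columns=["chrom", "pos"])
    )

    qtls: list[QtlInterval] = []
    lo, hi = cfg.qtl_length_range
    for group, count, traits in (
        ("meat_muscle", cfg.n_qtl_meat_muscle, _MEAT_TRAITS),
        ("other", cfg.n_qtl_other, _OTHER_TRAITS),
    ):
        for i in range(count):
            chrom = cfg.chromosomes[int(rng.integers(0, cfg.n_chromosomes))]
            length = int(rng.integers(lo, hi + 1))
            start = int(rng.integers(0, cfg.chromosome_length - length))
            qtls.append(
                QtlInterval(
                    GenomicInterval(chrom, start, start + length, "."),
                    traits[i % len(traits)],
                    group,
                )
            )
            if truth is not None:
                truth.qtl_groups.append(group)
    return snps, qtls


# ---------------------------------------------------------------------------
# Motifs
# ---------------------------------------------------------------------------

def simulate_motifs(
    cfg: SimulationConfig,
    sequences: dict[str, str],
    truth: GroundTruth,
) -> MotifDb:
    """Build a PWM motif database and plant motif instances into a fraction
    of the coding transcripts' ORFs (in-frame, stop-free encoding).

    Thresholds require near-exact consensus matches, so random peptides
    essentially never hit. Planted sequences are modified in place in
    ``sequences`` and recorded in the ground truth.
    """
    rng = _stage_rng(cfg, 5)
    motifs = []
    for m in range(cfg.n_motifs):
        consensus_idx = rng.integers(0, len(AA_ALPHABET), cfg.motif_length)
        matrix = np.full((cfg.motif_length, len(AA_ALPHABET)), -1.0)
        matrix[np.arange(cfg.motif_length), consensus_idx] = 3.0
        # score = 4 * matches - length; threshold demands >= length - 1 matches
        threshold = 4.0 * (cfg.motif_length - 1) - cfg.motif_length
        motifs.append(PwmMotif(f"MOTIF_{m + 1}", matrix, threshold))
    db = MotifDb(motifs)

    coding_ids = sorted(
        tid for tid, orf in truth.true_orf.items()
        if truth.coding_label.get(tid) == "coding" and tid in sequences
    )
    for tid in coding_ids:
        if rng.random() >= cfg.motif_planted_frac:
            continue
        motif = motifs[int(rng.integers(0, len(motifs)))]
        peptide = motif.consensus
        encoded = "".join(_AA_TO_CODON[a] for a in peptide)
        start, end = truth.true_orf[tid]
        body_codons = (end - start) // 3 - 2  # exclude ATG and stop
        if body_codons < len(peptide) + 2:
            continue
        offset = start + 3 + 3 * int(rng.integers(0, body_codons - len(peptide)))
        seq = sequences[tid]
        sequences[tid] = seq[:offset] + encoded + seq[offset + len(encoded) :]
        truth.motif_planted[tid] = motif.name
    return db


# ---------------------------------------------------------------------------
# Bundle
# ---------------------------------------------------------------------------

@dataclass
class SyntheticBundle:
    config: SimulationConfig
    reference: list[TranscriptModel]
    queries: list[TranscriptModel]
    truth: GroundTruth
    sequences: dict[str, str]
    training_coding: list[str]
    training_noncoding: list[str]
    control_sequences: dict[str, str]
    alignments: dict[str, CodonAlignment]
    control_alignments: dict[str, CodonAlignment]
    counts: pd.DataFrame
    mapped_totals: pd.Series
    snps: pd.DataFrame
    qtls: list[QtlInterval]
    motif_db: MotifDb


def simulate_bundle(cfg: SimulationConfig) -> SyntheticBundle:
    """Generate every pipeline input with consistent ground truth."""
    reference, queries, truth = simulate_annotation_and_queries(cfg)
    sequences, train_cod, train_non, controls = simulate_sequences(
        cfg, queries, truth
    )
    motif_db = simulate_motifs(cfg, sequences, truth)

    u_labels = {
        tid: truth.coding_label[tid]
        for tid, code in truth.true_class.items()
        if code == "u" and truth.passes_size_filter.get(tid, False)
    }
    alignments = simulate_alignments(cfg, sequences, u_labels)
    control_alignments = simulate_alignments(cfg, controls, truth.control_labels)

    linc_gene_ids = sorted(
        t.gene_id
        for t in queries
        if truth.true_class[t.transcript_id] == "u"
        and truth.passes_size_filter.get(t.transcript_id, False)
        and truth.coding_label[t.transcript_id] == "noncoding"
    )
    coding_gene_ids = [g.gene_id for g in reference]
    counts, totals = simulate_counts(cfg, truth, linc_gene_ids, coding_gene_ids)
    snps, qtls = simulate_snps_and_qtls(cfg, truth)
    return SyntheticBundle(
        config=cfg,
        reference=reference,
        queries=queries,
        truth=truth,
        sequences=sequences,
        training_coding=train_cod,
        training_noncoding=train_non,
        control_sequences=controls,
        alignments=alignments,
        control_alignments=control_alignments,
        counts=counts,
        mapped_totals=totals,
        snps=snps,
        qtls=qtls,
        motif_db=motif_db,
    )


def write_bundle(bundle: SyntheticBundle, outdir) -> dict[str, str]:
    """Emit the bundle in the on-disk formats the pipeline reads; returns the
    file manifest. Byte-identical for identical configs."""
    import os

    from . import io as lio

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "reference_gtf": os.path.join(outdir, "reference.gtf"),
        "query_gtf": os.path.join(outdir, "queries.gtf"),
        "sequences_fasta": os.path.join(outdir, "queries.fasta"),
        "training_coding_fasta": os.path.join(outdir, "training_coding.fasta"),
        "training_noncoding_fasta": os.path.join(outdir, "training_noncoding.fasta"),
        "controls_coding_fasta": os.path.join(outdir, "controls_coding.fasta"),
        "controls_noncoding_fasta": os.path.join(outdir, "controls_noncoding.fasta"),
        "alignments_maf": os.path.join(outdir, "alignments.maf"),
        "control_alignments_maf": os.path.join(outdir, "control_alignments.maf"),
        "counts_tsv": os.path.join(outdir, "counts.tsv"),
        "totals_tsv": os.path.join(outdir, "mapped_totals.tsv"),
        "snp_bed": os.path.join(outdir, "snps.bed"),
        "qtl_tsv": os.path.join(outdir, "qtls.tsv"),
        "motif_tsv": os.path.join(outdir, "motifs.tsv"),
        "ground_truth_json": os.path.join(outdir, "ground_truth.json"),
    }
    lio.write_gtf(bundle.reference, paths["reference_gtf"])
    lio.write_gtf(bundle.queries, paths["query_gtf"])
    lio.write_fasta(bundle.sequences, paths["sequences_fasta"])
    lio.write_fasta(
        {f"TRAIN_COD_{i:04d}": s for i, s in enumerate(bundle.training_coding)},
        paths["training_coding_fasta"],
    )
    lio.write_fasta(
        {f"TRAIN_NC_{i:04d}": s for i, s in enumerate(bundle.training_noncoding)},
        paths["training_noncoding_fasta"],
    )
    lio.write_fasta(
        {
            k: v
            for k, v in bundle.control_sequences.items()
            if bundle.truth.control_labels.get(k) == "coding"
        },
        paths["controls_coding_fasta"],
    )
    lio.write_fasta(
        {
            k: v
            for k, v in bundle.control_sequences.items()
            if bundle.truth.control_labels.get(k) == "noncoding"
        },
        paths["controls_noncoding_fasta"],
    )
    lio.write_maf(bundle.alignments, paths["alignments_maf"])
    lio.write_maf(bundle.control_alignments, paths["control_alignments_maf"])
    lio.write_counts_tsv(bundle.counts, paths["counts_tsv"])
    lio.write_totals_tsv(bundle.mapped_totals, paths["totals_tsv"])
    lio.write_snp_bed(bundle.snps, paths["snp_bed"])
    lio.write_qtl_tsv(bundle.qtls, paths["qtl_tsv"])
    bundle.motif_db.to_tsv(paths["motif_tsv"])
    bundle.truth.to_json(paths["ground_truth_json"])
    return paths
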