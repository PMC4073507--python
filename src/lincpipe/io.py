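"""Readers and writers for the standard formats the pipeline consumes.

GTF (1-based inclusive on disk, converted to the internal 0-based half-open
convention), FASTA, MAF multi-species alignments, SNP BED, QTL TSV, counts
and mapped-totals TSVs, plus the class-code tracking TSV.
"""

from __future__ import annotations

import gffutils
import pandas as pd
from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotation import ClassCodeResult
from .coding import CodonAlignment
from .intervals import GenomicInterval, TranscriptModel
from .qtl import QtlInterval

__all__ = [
    "read_gtf",
    "write_gtf",
    "read_fasta",
    "write_fasta",
    "read_maf",
    "write_maf",
    "read_snp_bed",
    "write_snp_bed",
    "read_qtl_tsv",
    "write_qtl_tsv",
    "read_counts_tsv",
    "write_counts_tsv",
    "read_totals_tsv",
    "write_totals_tsv",
    "write_class_code_tsv",
    "read_class_code_tsv",
]


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def read_gtf(path) -> list[TranscriptModel]:
    """Parse a GTF into transcript models (exon features grouped by
    ``transcript_id``; ``gene_id`` and ``transcript_id`` attributes are
    mandatory). Transcripts are returned sorted by (chrom, span start, id)."""
    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        merge_strategy="create_unique",
    )
    grouped: dict[str, dict] = {}
    for feat in db.features_of_type("exon"):
        tid = feat.attributes["transcript_id"][0]
        gid = feat.attributes["gene_id"][0]
        entry = grouped.setdefault(
            tid, {"gene_id": gid, "chrom": feat.seqid, "strand": feat.strand, "exons": []}
        )
        # GTF is 1-based inclusive; internal is 0-based half-open.
        entry["exons"].append((feat.start - 1, feat.end))
    transcripts = []
    for tid, entry in grouped.items():
        strand = entry["strand"] if entry["strand"] in ("+", "-") else "."
        exons = [
            GenomicInterval(entry["chrom"], s, e, strand)
            for s, e in sorted(entry["exons"])
        ]
        transcripts.append(
            TranscriptModel(tid, entry["gene_id"], entry["chrom"], strand, exons)
        )
    transcripts.sort(key=lambda t: (t.chrom, t.span.start, t.transcript_id))
    return transcripts


def write_gtf(transcripts: list[TranscriptModel], path, source: str = "lincpipe") -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            for ex in t.exons:
                attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
                fh.write(
                    "\t".join(
                        [
                            t.chrom,
                            source,
                            "exon",
                            str(ex.start + 1),
                            str(ex.end),
                            ".",
                            t.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# MAF (one alignment block per transcript; reference species row first)
# ---------------------------------------------------------------------------

def write_maf(alignments: dict[str, CodonAlignment], path) -> None:
    blocks = []
    for tid, aln in alignments.items():
        records = []
        for species, row in zip(aln.species, aln.rows):
            ungapped = sum(1 for c in row if c != "-")
            rec = SeqRecord(Seq(row), id=f"{species}.{tid}")
            rec.annotations.update(
                {"start": 0, "size": ungapped, "strand": 1, "srcSize": ungapped}
            )
            records.append(rec)
        blocks.append(MultipleSeqAlignment(records))
    with open(path, "w") as fh:
        AlignIO.write(blocks, fh, "maf")


def read_maf(path) -> dict[str, CodonAlignment]:
    out: dict[str, CodonAlignment] = {}
    for block in AlignIO.parse(str(path), "maf"):
        species = []
        rows = []
        tid = ""
        for rec in block:
            sp, _, rest = rec.id.partition(".")
            species.append(sp)
            tid = rest or tid
            rows.append(str(rec.seq).upper())
        out[tid] = CodonAlignment(species=species, rows=rows, transcript_id=tid)
    return out


# ---------------------------------------------------------------------------
# BED / TSV tables
# ---------------------------------------------------------------------------

def read_snp_bed(path) -> pd.DataFrame:
    """SNP positions from BED (chrom, start, end[, name]); returns a frame
    with ``chrom`` and 0-based ``pos`` columns."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.rename(columns={0: "chrom", 1: "pos", 2: "end"})
    return df[["chrom", "pos"]].astype({"pos": int})


def write_snp_bed(snps: pd.DataFrame, path) -> None:
    out = snps.copy()
    out["end"] = out["pos"] + 1
    out["name"] = [f"snp_{i}" for i in range(len(out))]
    out[["chrom", "pos", "end", "name"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_qtl_tsv(path) -> list[QtlInterval]:
    df = pd.read_csv(path, sep="\t")
    return [
        QtlInterval(
            GenomicInterval(str(r.chrom), int(r.start), int(r.end), "."),
            str(r.trait),
            str(r.group),
        )
        for r in df.itertuples()
    ]


def write_qtl_tsv(qtls: list[QtlInterval], path) -> None:
    pd.DataFrame(
        [
            {
                "chrom": q.interval.chrom,
                "start": q.interval.start,
                "end": q.interval.end,
                "trait": q.trait_name,
                "group": q.trait_group,
            }
            for q in qtls
        ]
    ).to_csv(path, sep="\t", index=False)


def read_counts_tsv(path) -> pd.DataFrame:
    """HTSeq-count-style table: gene id column followed by per-sample counts."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_totals_tsv(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0]


def write_totals_tsv(totals: pd.Series, path) -> None:
    totals.rename("mapped_reads").to_csv(path, sep="\t", index_label="sample")


def write_class_code_tsv(
    classified: list[tuple[TranscriptModel, ClassCodeResult]], path
) -> None:
    """Tracking-style TSV mirroring the class-code semantics: all codes,
    the precedence-selected primary code and the matched reference id."""
    pd.DataFrame(
        [
            {
                "transcript_id": cc.transcript_id,
                "codes": "".join(sorted(cc.codes)),
                "primary_code": cc.primary_code,
                "matched_reference_id": cc.matched_reference_id or ".",
                "multi_classified": cc.multi_classified,
            }
            for _, cc in classified
        ]
    ).to_csv(path, sep="\t", index=False)


def read_class_code_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
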