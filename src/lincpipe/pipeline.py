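"""End-to-end orchestration: classify -> filter -> coding cascade ->
expression -> co-expression -> QTL enrichment, with a reproducible report.

The report logs every stage's input/output counts in the audit style of
stepwise lincRNA pipelines (candidates -> conservation/classifier survivors
-> domain-filtered set -> loci), echoes all parameters and the seed, and is
byte-stable for identical configuration and inputs.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as lio
from .annotation import classify_transcripts, cluster_loci, filter_linc_candidates
from .coding import (
    CodonAlignment,
    MotifDb,
    calibrate_conservation_threshold,
    codon_conservation_score,
    coding_cascade,
    find_longest_orf,
    train_classifier_from_sequences,
)
from .coexpression import all_pairs_screen
from .expression import (
    coefficient_of_variation,
    compare_groups,
    detection_summary,
    normalize_counts,
    snp_density,
)
from .intervals import GenomicInterval, TranscriptModel
from .qtl import QtlInterval, chi_square_enrichment, overlap_qtl


class PipelineConfigError(ValueError):
    """A required input is missing or a parameter is out of range."""


@dataclass
class PipelineParams:
    """Stage parameters with the study defaults."""

    min_length: int = 200
    min_exons: int = 2
    folds: int = 10
    cv_scheme: str = "paper"
    n_frames: int = 3
    cutoff_criterion: str = "max_sens_plus_spec"
    conservation_mode: str = "zero"  # "zero" (score < 0 retained) | "calibrate"
    retain_noncoding_frac: float = 0.73
    alpha: float = 0.05
    cis_window_bp: int = 2_000_000
    screen_p_method: str = "asymptotic"
    detection_min_count: int = 1
    snp_upstream_bp: int = 10_000
    snp_downstream_bp: int = 1_000
    expectation_model: str = "span_proportional"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.conservation_mode not in ("zero", "calibrate", "off"):
            raise PipelineConfigError("conservation_mode must be zero|calibrate|off")
        if self.cv_scheme not in ("paper", "standard"):
            raise PipelineConfigError("cv_scheme must be paper|standard")


@dataclass
class PipelineInputs:
    """In-memory view of every file the pipeline consumes."""

    reference: list[TranscriptModel]
    queries: list[TranscriptModel]
    sequences: dict[str, str]
    training_coding: list[str]
    training_noncoding: list[str]
    counts: pd.DataFrame
    mapped_totals: pd.Series
    alignments: dict[str, CodonAlignment] | None = None
    control_alignments: dict[str, CodonAlignment] | None = None
    control_labels: dict[str, str] | None = None
    control_sequences: dict[str, str] | None = None
    snps: pd.DataFrame | None = None
    qtls: list[QtlInterval] | None = None
    motif_db: MotifDb | None = None

    @classmethod
    def from_bundle(cls, bundle) -> "PipelineInputs":
        return cls(
            reference=bundle.reference,
            queries=bundle.queries,
            sequences=bundle.sequences,
            training_coding=bundle.training_coding,
            training_noncoding=bundle.training_noncoding,
            counts=bundle.counts,
            mapped_totals=bundle.mapped_totals,
            alignments=bundle.alignments,
            control_alignments=bundle.control_alignments,
            control_labels=dict(bundle.truth.control_labels),
            control_sequences=bundle.control_sequences,
            snps=bundle.snps,
            qtls=bundle.qtls,
            motif_db=bundle.motif_db,
        )

    @classmethod
    def from_paths(cls, paths: dict[str, str]) -> "PipelineInputs":
        """Load a bundle directory manifest (keys as written by
        :func:`lincpipe.simulate.write_bundle`)."""

        def need(key):
            if key not in paths or not os.path.exists(paths[key]):
                raise PipelineConfigError(f"missing required input: {key}")
            return paths[key]

        control_sequences: dict[str, str] = {}
        control_labels: dict[str, str] = {}
        for key, label in (
            ("controls_coding_fasta", "coding"),
            ("controls_noncoding_fasta", "noncoding"),
        ):
            if key in paths and os.path.exists(paths[key]):
                seqs = lio.read_fasta(paths[key])
                control_sequences.update(seqs)
                control_labels.update({k: label for k in seqs})
        return cls(
            reference=lio.read_gtf(need("reference_gtf")),
            queries=lio.read_gtf(need("query_gtf")),
            sequences=lio.read_fasta(need("sequences_fasta")),
            training_coding=list(
                lio.read_fasta(need("training_coding_fasta")).values()
            ),
            training_noncoding=list(
                lio.read_fasta(need("training_noncoding_fasta")).values()
            ),
            counts=lio.read_counts_tsv(need("counts_tsv")),
            mapped_totals=lio.read_totals_tsv(need("totals_tsv")),
            alignments=(
                lio.read_maf(paths["alignments_maf"])
                if paths.get("alignments_maf") and os.path.exists(paths["alignments_maf"])
                else None
            ),
            control_alignments=(
                lio.read_maf(paths["control_alignments_maf"])
                if paths.get("control_alignments_maf")
                and os.path.exists(paths["control_alignments_maf"])
                else None
            ),
            control_labels=control_labels or None,
            control_sequences=control_sequences or None,
            snps=(
                lio.read_snp_bed(paths["snp_bed"])
                if paths.get("snp_bed") and os.path.exists(paths["snp_bed"])
                else None
            ),
            qtls=(
                lio.read_qtl_tsv(paths["qtl_tsv"])
                if paths.get("qtl_tsv") and os.path.exists(paths["qtl_tsv"])
                else None
            ),
            motif_db=(
                MotifDb.from_tsv(paths["motif_tsv"])
                if paths.get("motif_tsv") and os.path.exists(paths["motif_tsv"])
                else None
            ),
        )


def _conservation_scores(
    alignments: dict[str, CodonAlignment], sequences: dict[str, str], n_frames: int
) -> dict[str, float]:
    scores = {}
    for tid, aln in alignments.items():
        seq = sequences.get(tid)
        if seq is None:
            continue
        orf = find_longest_orf(seq, n_frames=n_frames)
        if orf.found:
            scores[tid] = codon_conservation_score(aln, orf)
    return scores


def run_pipeline(
    inputs: PipelineInputs,
    params: PipelineParams | None = None,
    outdir: str | None = None,
    force: bool = False,
) -> dict:
    """Execute all stages in order and return the report dictionary.

    With ``outdir`` set, per-stage tables and the report JSON are written
    there (refusing to overwrite an existing directory unless ``force``).
    """
    params = params or PipelineParams()
    report: dict = {
        "parameters": dataclasses.asdict(params),
        "seed": params.seed,
        "stages": {},
    }

    # Stage 1: classification against the reference annotation
    classified = classify_transcripts(inputs.queries, inputs.reference)
    code_counts: dict[str, int] = {}
    for _, cc in classified:
        code_counts[cc.primary_code] = code_counts.get(cc.primary_code, 0) + 1
    n_multi = sum(1 for _, cc in classified if cc.multi_classified)
    report["stages"]["classify"] = {
        "n_queries": len(inputs.queries),
        "n_reference": len(inputs.reference),
        "primary_code_counts": dict(sorted(code_counts.items())),
        "n_multi_classified": n_multi,
    }

    # Stage 2: size/exon filter on intergenic transcripts
    candidates = filter_linc_candidates(
        classified, min_length=params.min_length, min_exons=params.min_exons
    )
    candidate_loci = cluster_loci(candidates)
    report["stages"]["filter"] = {
        "n_u": code_counts.get("u", 0),
        "n_candidates": len(candidates),
        "n_candidate_loci": len(candidate_loci),
    }

    # Stage 3: coding-potential cascade
    hexamer, model = train_classifier_from_sequences(
        inputs.training_coding,
        inputs.training_noncoding,
        folds=params.folds,
        scheme=params.cv_scheme,
        seed=params.seed,
        n_frames=params.n_frames,
        cutoff_criterion=params.cutoff_criterion,
    )

    conservation_threshold: float | None
    calibration: dict | None = None
    if params.conservation_mode == "off" or inputs.alignments is None:
        conservation_threshold = None
    elif params.conservation_mode == "zero":
        conservation_threshold = 0.0
    else:
        if not (
            inputs.control_alignments
            and inputs.control_labels
            and inputs.control_sequences
        ):
            raise PipelineConfigError(
                "conservation_mode='calibrate' needs control alignments and labels"
            )
        ctrl_scores = _conservation_scores(
            inputs.control_alignments, inputs.control_sequences, params.n_frames
        )
        nc = [s for t, s in ctrl_scores.items() if inputs.control_labels.get(t) == "noncoding"]
        cod = [s for t, s in ctrl_scores.items() if inputs.control_labels.get(t) == "coding"]
        conservation_threshold, removed = calibrate_conservation_threshold(
            nc, cod, params.retain_noncoding_frac
        )
        calibration = {
            "threshold": conservation_threshold,
            "coding_removed_frac": removed,
            "n_noncoding_controls": len(nc),
            "n_coding_controls": len(cod),
        }

    cascade = coding_cascade(
        candidates,
        inputs.sequences,
        hexamer_table=hexamer,
        model=model,
        conservation_threshold=conservation_threshold,
        alignments=inputs.alignments,
        motif_db=inputs.motif_db,
        n_frames=params.n_frames,
    )
    retained = cascade.retained
    linc_loci = cluster_loci(retained)
    mean_cv_sens = float(np.mean([m[0] for m in model.cv_metrics]))
    mean_cv_spec = float(np.mean([m[1] for m in model.cv_metrics]))
    report["stages"]["coding_potential"] = {
        "classifier_cutoff": model.cutoff,
        "cv_mean_sensitivity": mean_cv_sens,
        "cv_mean_specificity": mean_cv_spec,
        "conservation_threshold": conservation_threshold,
        "conservation_calibration": calibration,
        "audit": cascade.audit,
        "n_retained_transcripts": len(retained),
        "n_retained_loci": len(linc_loci),
    }

    # Stage 4: expression characterization
    matrix = normalize_counts(inputs.counts, inputs.mapped_totals)
    detected, tallies = detection_summary(matrix, params.detection_min_count)
    cv = coefficient_of_variation(matrix)

    retained_gene_ids = sorted(
        {t.gene_id for t in retained} & set(matrix.gene_ids)
    )
    coding_gene_ids = sorted(
        {t.gene_id for t in inputs.reference} & set(matrix.gene_ids)
    )
    n_samples = matrix.raw_counts.shape[1]
    linc_all = [g for g in retained_gene_ids if detected[g] == n_samples]
    coding_all = [g for g in coding_gene_ids if detected[g] == n_samples]

    expr_section: dict = {
        "n_genes_in_matrix": len(matrix.gene_ids),
        "n_linc_genes_quantified": len(retained_gene_ids),
        "n_coding_genes_quantified": len(coding_gene_ids),
        "detection": tallies,
        "n_linc_detected_in_all": len(linc_all),
        "n_coding_detected_in_all": len(coding_all),
    }
    if len(linc_all) >= 2 and len(coding_all) >= 2:
        cv_cmp = compare_groups(
            cv.loc[linc_all, "cv_pct"].dropna(), cv.loc[coding_all, "cv_pct"].dropna()
        )
        expr_section["cv_comparison"] = {
            "linc_mean": cv_cmp.mean_a,
            "linc_sd": cv_cmp.sd_a,
            "coding_mean": cv_cmp.mean_b,
            "coding_sd": cv_cmp.sd_b,
            "statistic": cv_cmp.statistic,
            "p_value": cv_cmp.p_value,
            "formatted": cv_cmp.format_means(),
        }
        expr_cmp = compare_groups(
            matrix.normalized.loc[linc_all].mean(axis=1),
            matrix.normalized.loc[coding_all].mean(axis=1),
        )
        expr_section["expression_comparison"] = {
            "linc_mean": expr_cmp.mean_a,
            "coding_mean": expr_cmp.mean_b,
            "statistic": expr_cmp.statistic,
            "p_value": expr_cmp.p_value,
        }
    if retained and inputs.reference:
        len_cmp = compare_groups(
            [t.length for t in retained], [t.length for t in inputs.reference]
        )
        exon_cmp = compare_groups(
            [t.n_exons for t in retained], [t.n_exons for t in inputs.reference]
        )
        expr_section["transcript_length_comparison"] = {
            "linc_mean": len_cmp.mean_a,
            "coding_mean": len_cmp.mean_b,
            "p_value": len_cmp.p_value,
        }
        expr_section["exon_count_comparison"] = {
            "linc_mean": exon_cmp.mean_a,
            "coding_mean": exon_cmp.mean_b,
            "p_value": exon_cmp.p_value,
        }
    if inputs.snps is not None and linc_loci:
        linc_dens = snp_density(
            linc_loci,
            inputs.snps,
            params.snp_upstream_bp,
            params.snp_downstream_bp,
        )
        coding_dens = snp_density(
            inputs.reference,
            inputs.snps,
            params.snp_upstream_bp,
            params.snp_downstream_bp,
        )
        expr_section["snp_density"] = {
            "linc_upstream_mean": float(linc_dens["upstream_density"].mean()),
            "linc_downstream_mean": float(linc_dens["downstream_density"].mean()),
            "coding_upstream_mean": float(coding_dens["upstream_density"].mean()),
            "coding_downstream_mean": float(coding_dens["downstream_density"].mean()),
        }
    report["stages"]["expression"] = expr_section

    # Stage 5: co-expression screen (genes detected in all samples)
    gene_spans: dict[str, GenomicInterval] = {}
    for t in inputs.reference + retained:
        span = t.span
        prev = gene_spans.get(t.gene_id)
        if prev is None:
            gene_spans[t.gene_id] = span
        else:
            gene_spans[t.gene_id] = GenomicInterval(
                span.chrom,
                min(prev.start, span.start),
                max(prev.end, span.end),
                span.strand,
            )
    screen = None
    if linc_all and coding_all:
        screen = all_pairs_screen(
            matrix.normalized.loc[linc_all],
            matrix.normalized.loc[coding_all],
            loci_positions=gene_spans,
            alpha=params.alpha,
            cis_window_bp=params.cis_window_bp,
            p_method=params.screen_p_method,
        )
        report["stages"]["coexpression"] = screen.summary
    else:
        report["stages"]["coexpression"] = {"n_pairs_tested": 0, "n_significant": 0}

    # Stage 6: QTL overlap and enrichment
    if inputs.qtls:
        per_locus, per_qtl = overlap_qtl(linc_loci, inputs.qtls)
        n_overlapping_loci = sum(1 for v in per_locus.values() if v)
        qtl_section = {
            "n_loci": len(linc_loci),
            "n_qtls": len(inputs.qtls),
            "n_loci_in_qtl": n_overlapping_loci,
            "n_overlap_events": int(sum(per_qtl)),
        }
        try:
            enr = chi_square_enrichment(
                per_locus, inputs.qtls, expectation=params.expectation_model
            )
            qtl_section["enrichment"] = {
                "observed": enr.observed,
                "expected": enr.expected,
                "statistic": enr.statistic,
                "dof": enr.dof,
                "p_value": enr.p_value,
                "expectation_model": enr.expectation_model,
            }
        except ValueError as exc:
            qtl_section["enrichment_error"] = str(exc)
        report["stages"]["qtl"] = qtl_section

    if outdir is not None:
        _write_outputs(outdir, force, classified, cascade, screen, report)
    return report


def _write_outputs(outdir, force, classified, cascade, screen, report) -> None:
    if os.path.exists(outdir) and os.listdir(outdir) and not force:
        raise PipelineConfigError(
            f"output directory {outdir} is not empty; pass force=True to overwrite"
        )
    os.makedirs(outdir, exist_ok=True)
    lio.write_class_code_tsv(classified, os.path.join(outdir, "class_codes.tsv"))
    cascade.table.to_csv(
        os.path.join(outdir, "coding_potential.tsv"), sep="\t", index=False
    )
    if screen is not None:
        screen.to_frame().to_csv(
            os.path.join(outdir, "coexpression_pairs.tsv"), sep="\t", index=False
        )
    manifest = sorted(os.listdir(outdir)) + ["report.json"]
    report["output_manifest"] = manifest
    with open(os.path.join(outdir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=float)
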