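# Methods

This note documents the models, parameter choices and numerical conventions
behind `lincpipe`, and what the synthetic study does and does not establish.

## Coordinates and class codes

All coordinates are 0-based, half-open internally; GTF I/O converts to/from
the 1-based inclusive dialect. Overlap means ≥ 1 bp intersection under the
half-open convention, so touching intervals do not overlap.

Class codes are evaluated per reference transcript and accumulated; the
primary code follows the precedence `= > c > j > e > o > i > x > s > p > u`.
Conventions where the single-letter legend is underspecified:

* `=` requires a **non-empty** identical intron chain: the empty chain of a
  single-exon transcript would make any two single-exon transcripts "equal"
  regardless of position, so single-exon matches classify as `c`/`o` instead.
* `j` ("potentially novel isoform") is operationalized as sharing ≥ 1 splice
  site with a reference transcript without a full intron-chain match.
* `c` (contained) means an exonic sub-chain: every query exon inside a
  reference exon and every query intron equal to a reference intron. A
  truncated isoform whose introns all match is therefore `c`, not `j`
  (precedence resolves the tie the same way).
* `e` needs a single-exon query overlapping a reference exon and ≥ 10 bp of
  a reference intron; `i` needs the single exon entirely inside an intron.
  Both are same-strand tests; `x`/`s` require strictly opposite strands, and
  the unstranded symbol `.` acts as a same-strand wildcard but is never
  "opposite".
* `p` (run-on fragment) is same-strand, no span overlap, gap ≤ 2,000 bp.

The candidate filter keeps primary-`u` transcripts with ≥ 2 exons and spliced
length **strictly greater than** 200 nt ("larger than 200 nt" read literally).
Loci are connected components of the same-strand exonic-overlap graph; note
that a transcript nested inside another's intron forms its own locus, so
locus *spans* may nest even though exon blocks never do.

## Coding-potential cascade

The cascade intersects three independent predicates; because they are pure
per-candidate predicates, stage order never changes the retained set, only
the audit's intermediate counts.

**Conservation surrogate.** Full phylogenetic codon-model scoring is out of
scope; the stage scores codon constraint directly as
Σ_species log((syn + 1)/(nonsyn + 1)) over the candidate's longest ORF,
classifying each substituted codon with the standard genetic code (a stop↔
sense change is non-synonymous; codons with gaps or ambiguity in the
non-reference row are skipped; a gap inside the reference ORF is an error
because it breaks the anchored frame). The score is 0 for identical rows and
monotone increasing in the synonymous count. Two threshold policies are
supported: `zero` (retain score < 0, i.e. no positive evidence of coding
constraint — the default) and `calibrate` (choose the threshold as the
complementary quantile of known non-coding control scores retaining a set
fraction, default 0.73, and report the achieved coding-removal fraction).
Both policies exist because "retain negative scores" and "retain 73% of
known non-coding RNAs" describe the same contract only when the control
distributions happen to straddle zero; the package treats them as two
explicit modes rather than guessing. Candidates without an alignment or
without an ORF carry no evidence of coding constraint and pass the stage.

**Classifier.** Features are ORF length (nt), ORF coverage (fraction of the
transcript), the Fickett TESTCODE statistic (published position/composition
lookup tables; position parameter = max/(min+1) of per-frame base counts,
content parameter = base fraction, eight weighted probabilities summed), and
hexamer usage bias (mean per-hexamer log-ratio of coding vs non-coding
frequencies, pseudocount 1 per hexamer). No feature scaling is applied: the
features are already bounded or log-scaled and an unscaled logistic fit keeps
the weights interpretable. The logistic model (L2, C = 10⁴) reports
per-repetition sensitivity/specificity with **non-coding as the positive
class**. Two cross-validation schemes are provided: `paper` — the inverse
design in which each of the 10 parts is used once for *training* and the
remaining nine parts for prediction (so models are trained on 10% of the
data; this is the default and is deliberately flagged here because it is the
unusual direction) — and `standard` k-fold. The probability cutoff is chosen
on held-out scores as the candidate (midpoints of consecutive distinct
scores) maximising (sensitivity + specificity)/2, smallest candidate on
ties; a sensitivity≈specificity crossing criterion is available by flag.
Candidates with coding probability strictly below the cutoff are retained.

One methodological point discovered during development: the hexamer table
must be estimated on sequences disjoint from the classifier's training set.
Fitting both on the same sequences leaks the table's sampling noise into an
artificially separable feature — with *identical* coding and non-coding
generators the cross-validated accuracy then reads ~99% instead of 50%.
`train_classifier_from_sequences` therefore splits each training set in
half: first half for the table, second half for the classifier and its CV.

**Domain filter.** Candidates are translated in all three forward frames
(standard code, stops as `*`, trailing partial codons dropped) and scanned
against a motif database. The built-in scanner is a peptide position-weight
matrix with per-motif thresholds; an external profile-HMM mode (hmmscan via
pyhmmer) is available when explicitly configured. Any hit discards the
candidate.

## Expression, co-expression and QTL statistics

* Normalized expression is the per-read fraction count/total-mapped-reads
  (values of order 10⁻⁵), *not* RPKM — no length correction is applied.
* CV% uses the sample SD (n−1 denominator; n = 9 samples is small). Genes
  with zero mean are flagged rather than dropped.
* Group contrasts are two-sided two-sample t-tests (pooled by default,
  Welch by flag); two identical constant groups return statistic 0, p = 1 by
  convention.
* SNP windows: upstream −10 kb from the TSS, downstream +1 kb from the
  transcript 3′ end, strand-aware (the upstream window of a minus-strand
  locus lies on the higher-coordinate side), truncated at chromosome bounds
  with densities (SNPs/kb) over the truncated width. The downstream anchor is
  the annotated transcript end, since a stop-codon anchor would require a
  gene model.
* Mapping-table percentages are rounded half-up to 2 decimals; gigabases =
  reads × read length / 10⁹; read counts are single-read counts so the
  run-wide pair total is the summed count divided by two.
* Spearman's ρ uses average ranks on ties. The exact two-sided p enumerates
  all n! rank permutations (feasible for n ≤ 9; the untied null distribution
  is cached). The asymptotic p uses the t approximation with n−2 df, which
  collapses to 0 at |ρ| = 1. With nine samples the smallest exact p is
  2/9! ≈ 5.5 × 10⁻⁶ — no pair can clear a Bonferroni bound of order 10⁻⁸,
  so a study-scale screen is only decidable with the asymptotic p. The
  library default records exact p for n ≤ 9 (method tagged per pair), while
  `run_pipeline`'s screen uses the asymptotic p so that perfectly
  co-monotone pairs are reportable; this choice is deliberate and visible in
  the per-pair `p_method` field.
* Cis pairs: same chromosome, span gap (0 when overlapping) strictly below
  2 Mb. Bonferroni threshold: α / (n_linc × n_coding); FDR is deliberately
  not the default.
* QTL enrichment observes locus–QTL overlap *events* per trait group and
  tests them with a 1-df chi-squared goodness-of-fit. The default
  expectation is span-proportional (groups with more cumulative span are
  expected to intercept more uniformly-placed loci); count-proportional is
  available but confounded by QTL size. Overlapping or nested QTLs count as
  distinct regions. The shipped meat/muscle keyword list for trait grouping
  is opt-in, never applied silently.

## Synthetic study design

The generator replaces the study's raw sequencing data. One master seed
drives independent substreams per stage (annotation, sequences, alignments,
counts, SNPs/QTLs, motifs), so regenerating one stage never perturbs others
and all emitted files are byte-identical per seed.

Defaults (the study conditions): 2 chromosomes × 5 Mb; 300 reference genes
(3–7 exons of 120–250 bp, introns 200–1,000 bp, ~24 kb intergaps); 400 query
transcripts planted per class code (120 `u`, of which 10 single-exon and 10
≤ 200 nt to exercise the size filter); 9 samples; training sets of 300
coding + 300 non-coding sequences of 0.4–2 kb; 100 + 100 control sequences
for conservation calibration; 5 species per alignment.

* **Sequences.** Coding transcripts carry a planted in-frame ORF covering
  ~30–75% of the transcript with GC-biased codon usage; non-coding ones are
  iid uniform nucleotides. A single `divergence` knob (default 0.9, the
  well-separated regime) scales both the ORF fraction and the codon bias; at
  divergence 0 the two generators are *identical*, giving a chance-level
  classifier — the null behaviour the test suite checks.
* **Alignments.** Coding ORFs are mutated per codon (rate 0.3) with
  synonymous substitutions at probability 0.9; non-coding sequences per
  nucleotide (rate 0.15) uniformly. These rates put the two score
  distributions several log-units apart, which is what makes the `zero`
  threshold policy nearly lossless here.
* **Counts.** Negative-binomial with per-sample depths (5 × 10⁶ ± 25%):
  lincRNA genes mean 50, dispersion 0.18; coding genes mean 500, dispersion
  0.12 (per-gene lognormal mean scatter, σ = 0.6). Since CV² ≈ 1/μ + α,
  these give group CVs near 45% vs 35% — the inter-individual variability
  contrast the pipeline is meant to detect. Five lincRNA/coding pairs share
  a latent sample ordering with ×1.5 geometric spacing on the *normalized*
  scale, so integer rounding can never reorder them: their Spearman ρ is
  exactly 1. Fifteen lincRNA genes are zeroed in most samples to plant a
  detected-in-few-samples tail.
* **SNPs/QTLs.** Homogeneous Poisson SNPs (1/kb); 20 + 20 QTLs of
  50–400 kb in the two trait groups, overlaps allowed.
* **Motifs.** Three length-10 PWMs whose thresholds demand ≥ 9/10 consensus
  matches; consensus instances are spliced in-frame into ~30% of coding
  ORFs. Random-peptide hits are vanishingly rare, so the domain filter has
  essentially zero false-positive rate on true lincRNAs.

**What passing tests show — and don't.** The synthetic data make the class
codes, filters and statistics exactly checkable against planted truth, but
they are deliberately idealized: uniform base composition instead of real
genomic composition and repeats, gap-free alignments, no assembly noise or
fragmentary transcripts, negative-binomial counts without batch structure,
and a domain database whose motifs were planted. Perfect cascade recovery at
divergence 0.9 demonstrates correctness of the machinery, not expected
performance on real transcriptomes, where the coding/non-coding margin is
far narrower.

## Problem sizes and determinism

The default test-suite and acceptance runs use the default bundle (400
queries, 300 + 300 training sequences), 1,000-replicate null simulations for
the chi-squared calibration, 20 seeds for the cutoff- and CV-recovery
checks, and full 9! enumeration for exact p-values; the whole suite runs in
well under a minute of compute on one core. All randomness flows from
explicit seeds; the pipeline report is byte-stable given identical inputs
and configuration.

## Known limitations

* The conservation stage is a substitution-count surrogate: it ignores
  phylogeny (each species is compared to the reference independently),
  branch lengths and codon frequencies, and treats all synonymous changes as
  equal evidence.
* Exact permutation p-values are limited to n ≤ 9 profiles.
* The built-in PWM scanner is a test-friendly stand-in for profile-HMM
  search; real domain screening should configure the external HMMER mode.
* Six-frame ORF scanning reports minus-strand ORFs in reverse-complement
  coordinates; downstream conservation scoring assumes plus-strand ORFs.
* `u` classification trusts the assembled strand; unstranded (`.`) queries
  are treated as same-strand for every code that requires strand agreement.
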