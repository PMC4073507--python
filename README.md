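# lincpipe

Discovery and characterization of **long intergenic non-coding RNAs
(lincRNAs)** from assembled transcriptomes.

Surveys of mammalian muscle transcriptomes (bulk RNA-Seq, assembled into
transcript models) reveal thousands of transcripts that do not overlap any
annotated protein-coding gene. A stringent filtering pipeline is needed to
separate genuine lincRNAs from unannotated coding fragments. `lincpipe`
implements that pipeline end to end for computational biologists working
with assembled transcript models, read counts and a reference annotation:

1. **Annotation comparison** — every assembled transcript is classified
   against the reference with Cuffcompare-style class codes
   (`=`, `c`, `j`, `e`, `o`, `i`, `x`, `s`, `p`, `u`), keeping the full code
   set so multiply-classified transcripts (the "." tracking category) are
   visible. Unknown intergenic transcripts (`u`) with ≥ 2 exons and spliced
   length > 200 nt become lincRNA candidates, clustered into loci by
   same-strand exonic overlap.
2. **Coding-potential cascade** — three independent filters are intersected:
   * a *codon-conservation score*: for a multi-species alignment anchored on
     the candidate's longest ORF, each substituted codon is classified as
     synonymous or non-synonymous and every species contributes
     log((syn+1)/(nonsyn+1)); coding sequences show synonymous-biased
     (positive) scores. Candidates are retained below a threshold — either 0
     (no evidence of coding constraint) or an empirically calibrated value
     retaining a chosen fraction (default 73%) of known non-coding controls;
   * a *logistic coding classifier* over ORF length, ORF coverage, the
     Fickett TESTCODE statistic and hexamer usage bias, trained on known
     coding/non-coding sets with fold-based cross-validation (sensitivity
     = TP/(TP+FN), specificity = TN/(TN+FP), **non-coding = positive**) and
     a probability cutoff maximising sensitivity + specificity; candidates
     below the cutoff are retained;
   * a *protein-domain filter*: candidates whose three-frame translation
     hits a known protein motif (built-in PWM scanner, or HMMER profiles via
     the optional external mode) are discarded.
3. **Expression characterization** — counts are normalized as reads per
   transcript divided by the per-sample mapped-read total; detection across
   samples, per-gene coefficient of variation (CV% = 100·SD/mean) as the
   inter-individual variability statistic, Student's t contrasts between
   lincRNA and coding genes, SNP density in the −10 kb upstream / +1 kb
   downstream regulatory windows, and mapping-table arithmetic.
4. **Co-expression screen** — Spearman's rank correlation of every
   (lincRNA, coding) profile pair with Bonferroni control
   (threshold = α / n_pairs), exact permutation p-values by full enumeration
   for n ≤ 9 samples, cis annotation for same-chromosome pairs < 2 Mb apart.
5. **QTL enrichment** — overlap of lincRNA loci with trait-labelled QTL
   intervals and a 1-df chi-squared test of overlap counts between
   meat/muscle-related and other QTL groups.

A fully seeded **synthetic-data generator** emits every input (GTF, FASTA,
MAF, counts TSV, SNP BED, QTL TSV) with known ground truth, so the whole
pipeline is testable without any external download.

## Worked example

```python
from lincpipe import SimulationConfig, simulate_bundle, run_pipeline
from lincpipe.pipeline import PipelineInputs, PipelineParams

bundle = simulate_bundle(SimulationConfig(seed=1))
report = run_pipeline(PipelineInputs.from_bundle(bundle), PipelineParams(seed=1))

audit = report["stages"]["coding_potential"]["audit"]
print("candidates:", audit["n_input"])
print("after conservation filter:", audit["after_conservation"])
print("after coding classifier:", audit["after_classifier"])
print("after domain filter:", audit["after_domain"])
cv = report["stages"]["expression"]["cv_comparison"]
print("CV lincRNA vs coding:", cv["formatted"], f"(P = {cv['p_value']:.2e})")
coex = report["stages"]["coexpression"]
print("co-expression:", coex["n_significant"], "of", coex["n_pairs_tested"],
      "pairs significant")
```

prints

```
candidates: 100
after conservation filter: 50
after coding classifier: 50
after domain filter: 50
CV lincRNA vs coding: 49.91 +/- 23.43 versus 33.80 +/- 11.84 (P = 9.67e-11)
co-expression: 5 of 10500 pairs significant
```

The default bundle plants 100 multi-exon intergenic candidates, half of them
disguised coding transcripts; the cascade removes exactly those 50 and keeps
the 50 true lincRNAs. The lincRNA group's higher negative-binomial dispersion
shows up as a higher mean CV (49.91% vs 33.80%), and the five planted
co-monotone lincRNA/coding pairs are the five Bonferroni-significant pairs
(rank correlation ρ = 1).

The same run is available from the shell:

```bash
lincpipe simulate --seed 1 --outdir bundle/
lincpipe run-all --bundle bundle/ --outdir results/ --seed 1
```

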