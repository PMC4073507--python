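"""Classifier training/CV, cutoff selection, conservation surrogate,
domain filter and the assembled cascade."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize, stats

from lincpipe.coding import (
    AlignmentError,
    CodingFeatures,
    CodonAlignment,
    ConfusionCounts,
    MotifDb,
    PwmMotif,
    TrainingError,
    UndefinedRateError,
    calibrate_conservation_threshold,
    coding_cascade,
    codon_conservation_score,
    domain_filter,
    find_longest_orf,
    select_cutoff,
    sensitivity_specificity,
    train_coding_model,
    train_hexamer_table,
    translate_three_frames,
)
from lincpipe.simulate import SimulationConfig, simulate_alignments

from conftest import make_transcript


# ---------------------------------------------------------------------------
# Sensitivity / specificity (non-coding = positive)
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "tp,fp,tn,fn,sens,spec",
    [(90, 20, 80, 10, 0.90, 0.80), (0, 20, 80, 10, 0.0, 0.80), (5, 0, 5, 5, 0.5, 1.0)],
)
def test_sensitivity_specificity_examples(tp, fp, tn, fn, sens, spec):
    got = sensitivity_specificity(ConfusionCounts(TP=tp, FP=fp, TN=tn, FN=fn))
    assert got == (pytest.approx(sens), pytest.approx(spec))


@settings(derandomize=True, max_examples=200)
@given(
    tp=st.integers(0, 10_000),
    fp=st.integers(0, 10_000),
    tn=st.integers(0, 10_000),
    fn=st.integers(0, 10_000),
)
def test_sensitivity_specificity_formulas_hold(tp, fp, tn, fn):
    c = ConfusionCounts(TP=tp, FP=fp, TN=tn, FN=fn)
    if tp + fn == 0 or tn + fp == 0:
        with pytest.raises(UndefinedRateError):
            sensitivity_specificity(c)
    else:
        sens, spec = sensitivity_specificity(c)
        assert sens == tp / (tp + fn)
        assert spec == tn / (tn + fp)


# ---------------------------------------------------------------------------
# Classifier training
# ---------------------------------------------------------------------------

def _separable_features(rng, n=60):
    coding = [
        CodingFeatures(
            orf_length_nt=float(rng.integers(600, 1200)),
            orf_coverage=float(rng.uniform(0.6, 0.95)),
            fickett=float(rng.uniform(0.9, 1.2)),
            hexamer_bias=float(rng.uniform(0.2, 0.6)),
        )
        for _ in range(n)
    ]
    noncoding = [
        CodingFeatures(
            orf_length_nt=float(rng.integers(30, 150)),
            orf_coverage=float(rng.uniform(0.02, 0.2)),
            fickett=float(rng.uniform(0.5, 0.8)),
            hexamer_bias=float(rng.uniform(-0.6, -0.2)),
        )
        for _ in range(n)
    ]
    return coding, noncoding


class TestTrainCodingModel:
    def test_separable_features_give_perfect_cv(self):
        rng = np.random.default_rng(0)
        coding, noncoding = _separable_features(rng)
        for scheme in ("paper", "standard"):
            model = train_coding_model(coding, noncoding, scheme=scheme, seed=3)
            assert len(model.cv_metrics) == 10
            assert all(m == (1.0, 1.0) for m in model.cv_metrics)

    def test_same_seed_reproduces_weights_and_metrics(self):
        rng = np.random.default_rng(1)
        coding, noncoding = _separable_features(rng)
        a = train_coding_model(coding, noncoding, seed=7)
        b = train_coding_model(coding, noncoding, seed=7)
        assert np.array_equal(a.weights, b.weights)
        assert a.intercept == b.intercept
        assert a.cv_metrics == b.cv_metrics

    def test_planted_bayes_error_recovered(self):
        # one informative Normal feature with known overlap: the optimum
        # accuracy is Phi(delta/2) per class at the midpoint boundary
        delta = 2.0
        optimum = stats.norm.cdf(delta / 2)
        accs = []
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)

            def feats(mu, n):
                return [
                    CodingFeatures(
                        orf_length_nt=float(rng.normal(mu, 1.0)),
                        orf_coverage=0.5,
                        fickett=0.7,
                        hexamer_bias=0.0,
                    )
                    for _ in range(n)
                ]

            model = train_coding_model(
                feats(delta, 400), feats(0.0, 400), scheme="standard", seed=seed
            )
            acc = float(np.mean([(s + p) / 2 for s, p in model.cv_metrics]))
            accs.append(acc)
        assert abs(np.mean(accs) - optimum) < 0.03

    def test_single_class_input_rejected(self):
        rng = np.random.default_rng(2)
        coding, _ = _separable_features(rng, n=5)
        with pytest.raises(TrainingError):
            train_coding_model(coding, [], seed=0)

    def test_monotone_in_hexamer_bias(self):
        rng = np.random.default_rng(3)
        coding, noncoding = _separable_features(rng)
        model = train_coding_model(coding, noncoding, seed=0)
        lo = CodingFeatures(300.0, 0.4, 0.8, -0.5)
        hi = CodingFeatures(300.0, 0.4, 0.8, 0.5)
        p_lo, p_hi = model.predict_proba([lo, hi])
        assert p_hi > p_lo


class TestSelectCutoff:
    def test_separated_scores_choose_gap_midpoint(self):
        sel = select_cutoff([0.1, 0.2, 0.3], [0.7, 0.8, 0.9])
        assert sel.cutoff == pytest.approx(0.5)
        assert sel.sensitivity == 1.0 and sel.specificity == 1.0

    def test_swapping_lists_inverts_labels_at_same_boundary(self):
        nc = [0.1, 0.25, 0.4]
        cod = [0.6, 0.75, 0.9]
        a = select_cutoff(nc, cod, criterion="sens_spec_crossing")
        b = select_cutoff(cod, nc, criterion="sens_spec_crossing")
        assert a.cutoff == pytest.approx(b.cutoff)
        assert (a.sensitivity, a.specificity) == (1.0, 1.0)
        assert (b.sensitivity, b.specificity) == (0.0, 0.0)

    def test_recovers_analytic_beta_optimum(self):
        # Beta(2,5) vs Beta(5,2) cross exactly at 0.5 (symmetric densities),
        # where sensitivity + specificity is maximised.
        cutoffs = []
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            nc = rng.beta(2, 5, 1000)
            cod = rng.beta(5, 2, 1000)
            cutoffs.append(select_cutoff(nc, cod).cutoff)
        assert abs(float(np.mean(cutoffs)) - 0.5) < 0.05


# ---------------------------------------------------------------------------
# Conservation surrogate
# ---------------------------------------------------------------------------

def _aln(ref, others):
    return CodonAlignment(
        species=[f"sp{i}" for i in range(len(others) + 1)], rows=[ref, *others]
    )


class TestConservationScore:
    def test_identical_rows_score_zero(self):
        seq = "ATGAAACCCGGGTAA"
        orf = find_longest_orf(seq)
        assert codon_conservation_score(_aln(seq, [seq, seq]), orf) == 0.0

    def test_hand_built_balanced_substitutions(self):
        # one synonymous (AAA->AAG, both Lys) and one non-synonymous
        # (CCC->ACC, Pro->Thr): log(2/2) = 0
        ref = "ATGAAACCCTAA"
        other = "ATGAAGACCTAA"
        orf = find_longest_orf(ref)
        assert codon_conservation_score(_aln(ref, [other]), orf) == pytest.approx(0.0)

    def test_synonymous_only_substitution_scores_positive(self):
        ref = "ATGAAACCCTAA"
        other = "ATGAAGCCGTAA"  # two synonymous changes
        orf = find_longest_orf(ref)
        assert codon_conservation_score(_aln(ref, [other]), orf) == pytest.approx(
            math.log(3)
        )

    def test_frame_breaking_gap_rejected(self):
        ref = "ATGAA-ACCCTAA"
        other = "ATGAAAACCCTAA"
        orf = find_longest_orf(ref.replace("-", ""))
        with pytest.raises(AlignmentError):
            codon_conservation_score(_aln(ref, [other]), orf)

    def test_score_monotone_in_synonymous_count(self):
        ref = "ATG" + "AAA" * 6 + "TAA"
        orf = find_longest_orf(ref)
        scores = []
        for k in range(4):
            other = "ATG" + "AAG" * k + "AAA" * (6 - k) + "TAA"
            scores.append(codon_conservation_score(_aln(ref, [other]), orf))
        assert scores == sorted(scores) and scores[0] == 0.0

    def test_regimes_separate_under_generator(self, default_bundle):
        """Synonymous-biased vs neutral alignments separate with AUC >= 0.9."""
        truth = default_bundle.truth
        scores, labels = [], []
        for tid, aln in default_bundle.alignments.items():
            seq = default_bundle.sequences[tid]
            orf = find_longest_orf(seq)
            scores.append(codon_conservation_score(aln, orf))
            labels.append(truth.coding_label[tid] == "coding")
        scores = np.array(scores)
        labels = np.array(labels)
        pos = scores[labels]
        neg = scores[~labels]
        auc = float(np.mean(pos[:, None] > neg[None, :]))
        assert auc >= 0.9
        # coding-like constraint yields positive scores; neutral mostly negative
        assert np.median(pos) > 0 > np.median(neg)


class TestCalibrateThreshold:
    def test_retain_all_puts_threshold_above_max(self):
        nc = [-3.0, -1.0, 0.5]
        thr, removed = calibrate_conservation_threshold(nc, [5.0, 6.0], 1.0)
        assert thr > 0.5
        assert removed == 1.0

    def test_disjoint_sets_remove_all_coding(self):
        thr, removed = calibrate_conservation_threshold(
            [-5.0, -4.0, -3.0], [2.0, 3.0], 0.73
        )
        assert removed == 1.0

    def test_matches_quantile_oracle_on_normal_scores(self):
        rng = np.random.default_rng(9)
        nc = rng.normal(-2.0, 1.0, 5000)
        cod = rng.normal(3.0, 1.0, 5000)
        thr, _ = calibrate_conservation_threshold(nc, cod, 0.73)
        # independent quantile computation on the noncoding sample
        want = float(np.quantile(nc, 0.73))
        assert abs(thr - want) < 0.05
        assert np.mean(nc < thr) >= 0.73

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            calibrate_conservation_threshold([0.0], [1.0], 1.5)


# ---------------------------------------------------------------------------
# Domain filter
# ---------------------------------------------------------------------------

def _motif(name="M1", consensus="WYKRHDEQNC", match=3.0, miss=-1.0):
    alpha = "ACDEFGHIKLMNPQRSTVWY"
    matrix = np.full((len(consensus), 20), miss)
    for i, aa in enumerate(consensus):
        matrix[i, alpha.index(aa)] = match
    threshold = 4.0 * (len(consensus) - 1) - len(consensus)
    return PwmMotif(name, matrix, threshold)


class TestDomainFilter:
    def test_planted_consensus_is_hit(self):
        m = _motif()
        db = MotifDb([m])
        hit, hits = domain_filter(["AAAA" + m.consensus + "AAAA"], db)
        assert hit and hits[0].motif == "M1"

    def test_empty_db_never_hits(self):
        assert domain_filter(["WYKRHDEQNC"], MotifDb([])) == (False, [])

    def test_random_peptides_rarely_hit(self):
        rng = np.random.default_rng(13)
        db = MotifDb([_motif()])
        alpha = "ACDEFGHIKLMNPQRSTVWY"
        hits = 0
        for _ in range(1000):
            pep = "".join(alpha[i] for i in rng.integers(0, 20, 80))
            hits += domain_filter([pep], db)[0]
        assert hits <= 10  # false in >= 99% of trials


# ---------------------------------------------------------------------------
# Cascade
# ---------------------------------------------------------------------------

class TestCascade:
    def test_all_stages_disabled_is_identity(self):
        t = make_transcript("t1", "chr1", "+", [(0, 30)])
        res = coding_cascade([t], {"t1": "ATGAAACCCGGGTTTCCCAAATTTGGGTAA"})
        assert res.retained == [t]
        assert res.audit["n_retained"] == 1

    def test_single_candidate_failing_only_domain_stage(self):
        m = _motif()
        # encode the motif consensus into codons for frame 0
        codon_of = {
            "W": "TGG", "Y": "TAT", "K": "AAA", "R": "CGT", "H": "CAT",
            "D": "GAT", "E": "GAA", "Q": "CAA", "N": "AAT", "C": "TGT",
        }
        seq = "ATG" + "".join(codon_of[a] for a in m.consensus) + "TAA"
        t = make_transcript("t1", "chr1", "+", [(0, len(seq))])
        res = coding_cascade([t], {"t1": seq}, motif_db=MotifDb([m]))
        assert res.retained == []
        assert res.audit["stage_pass_counts"]["domain"] == 0
        assert res.audit["after_domain"] == 0

    def test_generator_truth_recovered_and_audit_monotone(self, default_bundle):
        """On well-separated synthetic candidates the cascade retains exactly
        the non-coding set; audit counts shrink monotonically."""
        from lincpipe.annotation import classify_transcripts, filter_linc_candidates
        from lincpipe.coding import train_classifier_from_sequences

        b = default_bundle
        classified = classify_transcripts(b.queries, b.reference)
        candidates = filter_linc_candidates(classified)
        hexamer, model = train_classifier_from_sequences(
            b.training_coding, b.training_noncoding, seed=1
        )
        res = coding_cascade(
            candidates,
            b.sequences,
            hexamer_table=hexamer,
            model=model,
            conservation_threshold=0.0,
            alignments=b.alignments,
            motif_db=b.motif_db,
        )
        audit = res.audit
        assert (
            audit["n_input"]
            >= audit["after_conservation"]
            >= audit["after_classifier"]
            >= audit["after_domain"]
            == audit["n_retained"]
        )
        truth_noncoding = {
            t.transcript_id
            for t in candidates
            if b.truth.coding_label[t.transcript_id] == "noncoding"
        }
        retained = {t.transcript_id for t in res.retained}
        tp = len(retained & truth_noncoding)
        sens = tp / len(truth_noncoding)
        spec = (len(candidates) - len(truth_noncoding) - len(retained - truth_noncoding)) / (
            len(candidates) - len(truth_noncoding)
        )
        assert sens >= 0.95 and spec >= 0.95
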