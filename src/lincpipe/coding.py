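"""Coding-potential filter cascade for lincRNA candidates.

Three independent evidence streams are intersected:

1. a codon-conservation score computed from multi-species alignments — a
   synonymous/non-synonymous substitution log-ratio surrogate for full
   phylogenetic codon-model scoring, calibrated empirically on control sets;
2. a logistic classifier over ORF length, ORF coverage, Fickett TESTCODE
   score and hexamer usage bias, with cross-validated accuracy and a cutoff
   chosen to maximise sensitivity and specificity (non-coding sequences are
   the positive class throughout);
3. a protein-domain filter on the three-frame in-silico translations, using
   either a built-in position-weight-matrix scanner or an external HMMER
   profile database.

Transcripts surviving all enabled stages are retained as putative lincRNAs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq
from sklearn.linear_model import LogisticRegression

from ._fickett import fickett_score
from .intervals import TranscriptModel

__all__ = [
    "OrfResult",
    "find_longest_orf",
    "fickett_score",
    "HexamerTable",
    "train_hexamer_table",
    "CodingFeatures",
    "compute_features",
    "ConfusionCounts",
    "sensitivity_specificity",
    "UndefinedRateError",
    "CodingModel",
    "TrainingError",
    "train_coding_model",
    "train_classifier_from_sequences",
    "CutoffSelection",
    "select_cutoff",
    "CodonAlignment",
    "AlignmentError",
    "codon_conservation_score",
    "calibrate_conservation_threshold",
    "translate_three_frames",
    "PwmMotif",
    "MotifDb",
    "HmmerMotifDb",
    "DomainHit",
    "domain_filter",
    "CascadeResult",
    "coding_cascade",
]

_VALID_BASES = frozenset("ACGTN")
_STOP_CODONS = frozenset(standard_dna_table.stop_codons)
_FORWARD_TABLE = dict(standard_dna_table.forward_table)

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


class UndefinedRateError(ValueError):
    """A sensitivity or specificity denominator is zero."""


class TrainingError(ValueError):
    """Classifier training received degenerate input."""


class AlignmentError(ValueError):
    """A codon alignment is inconsistent with the anchored reading frame."""


def _validate_sequence(sequence: str) -> str:
    seq = sequence.upper()
    bad = set(seq) - _VALID_BASES
    if bad:
        raise ValueError(f"invalid nucleotide characters: {sorted(bad)}")
    return seq


def _codon_aa(codon: str) -> str:
    if codon in _STOP_CODONS:
        return "*"
    return _FORWARD_TABLE.get(codon, "X")


# ---------------------------------------------------------------------------
# ORF finding
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OrfResult:
    """A complete ATG-to-stop open reading frame within a transcript.

    ``start``/``end`` are 0-based half-open offsets in the scanned sequence
    (for minus-strand hits of a 6-frame scan, offsets are within the
    reverse-complemented sequence). The stop codon is included in the span.
    """

    start: int
    end: int
    frame: int
    length_nt: int
    found: bool
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.found:
            if self.end - self.start != self.length_nt:
                raise ValueError("ORF length inconsistent with coordinates")
            if self.length_nt % 3 != 0:
                raise ValueError("ORF length must be a multiple of 3")


_NO_ORF = OrfResult(0, 0, 0, 0, False)


def _scan_frames(seq: str) -> OrfResult | None:
    """Longest complete ORF over frames 0/1/2 of one strand; None if absent."""
    best: tuple[int, int, int] | None = None  # (-length, start, frame)
    best_coords = None
    for frame in range(3):
        orf_start = -1
        for pos in range(frame, len(seq) - 2, 3):
            codon = seq[pos : pos + 3]
            if orf_start < 0 and codon == "ATG":
                orf_start = pos
            elif orf_start >= 0 and codon in _STOP_CODONS:
                end = pos + 3
                key = (-(end - orf_start), orf_start, frame)
                if best is None or key < best:
                    best = key
                    best_coords = (orf_start, end, frame)
                orf_start = -1
    if best_coords is None:
        return None
    start, end, frame = best_coords
    return OrfResult(start, end, frame, end - start, True)


def find_longest_orf(sequence: str, n_frames: int = 3) -> OrfResult:
    """Longest complete ATG-to-stop ORF over 3 (forward) or 6 frames.

    Ties are broken by smaller start offset, then smaller frame; with 6
    frames the forward strand wins ties against the reverse strand.
    """
    if n_frames not in (3, 6):
        raise ValueError("n_frames must be 3 or 6")
    seq = _validate_sequence(sequence)
    if len(seq) < 3:
        raise ValueError("sequence shorter than one codon")
    fwd = _scan_frames(seq)
    if n_frames == 3:
        return fwd if fwd is not None else _NO_ORF
    rev = _scan_frames(str(Seq(seq).reverse_complement()))
    if rev is not None:
        rev = OrfResult(rev.start, rev.end, rev.frame, rev.length_nt, True, "-")
    if fwd is None:
        return rev if rev is not None else _NO_ORF
    if rev is None or rev.length_nt <= fwd.length_nt:
        return fwd
    return rev


# ---------------------------------------------------------------------------
# Hexamer usage bias
# ---------------------------------------------------------------------------

_BASE_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i
    _BASE_CODE[_b + 32] = _i  # lowercase


def _hexamer_indices(sequence: str) -> np.ndarray:
    """Indices (0..4095) of all overlapping hexamers; windows with non-ACGT
    characters are dropped."""
    arr = _BASE_CODE[np.frombuffer(sequence.encode(), dtype=np.uint8)]
    n = arr.size - 5
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    idx = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for k in range(6):
        window = arr[k : k + n]
        idx = idx * 4 + np.where(window < 0, 0, window)
        valid &= window >= 0
    return idx[valid]


@dataclass
class HexamerTable:
    """Per-hexamer log-ratio of coding vs non-coding usage frequencies."""

    log_ratio: np.ndarray  # shape (4096,)

    def __post_init__(self) -> None:
        if self.log_ratio.shape != (4096,):
            raise ValueError("hexamer table must have 4096 entries")
        if not np.all(np.isfinite(self.log_ratio)):
            raise ValueError("hexamer table entries must be finite")

    def bias(self, sequence: str) -> float:
        """Mean per-hexamer log-ratio over the sequence; 0.0 if no usable
        hexamer (sequence shorter than 6 nt)."""
        idx = _hexamer_indices(sequence)
        if idx.size == 0:
            return 0.0
        return float(self.log_ratio[idx].mean())


def _hexamer_freq(seqs: list[str], pseudocount: float) -> np.ndarray:
    counts = np.zeros(4096, dtype=np.float64)
    for s in seqs:
        idx = _hexamer_indices(s)
        if idx.size:
            counts += np.bincount(idx, minlength=4096)
    counts += pseudocount
    return counts / counts.sum()


def train_hexamer_table(
    coding_seqs: list[str], noncoding_seqs: list[str], pseudocount: float = 1.0
) -> HexamerTable:
    """Estimate the 4^6 hexamer log-ratio table from two training sets.

    Each hexamer receives ``log(f_coding / f_noncoding)`` where frequencies
    are pseudocount-smoothed (``pseudocount`` added per hexamer count).
    """
    if not coding_seqs or not noncoding_seqs:
        raise ValueError("both training sets must be non-empty")
    f_cod = _hexamer_freq(coding_seqs, pseudocount)
    f_non = _hexamer_freq(noncoding_seqs, pseudocount)
    return HexamerTable(np.log(f_cod / f_non))


# ---------------------------------------------------------------------------
# Feature vector and classifier
# ---------------------------------------------------------------------------

FEATURE_NAMES = ("orf_length_nt", "orf_coverage", "fickett", "hexamer_bias")


@dataclass(frozen=True)
class CodingFeatures:
    """The four-dimensional coding-potential feature vector."""

    orf_length_nt: float
    orf_coverage: float
    fickett: float
    hexamer_bias: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.orf_coverage <= 1.0):
            raise ValueError("orf_coverage must lie in [0, 1]")
        for name in FEATURE_NAMES:
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"feature {name} is not finite")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES], dtype=float)


def compute_features(
    sequence: str, hexamer_table: HexamerTable, n_frames: int = 3
) -> CodingFeatures:
    """ORF length/coverage, Fickett score and hexamer bias of one sequence."""
    seq = _validate_sequence(sequence)
    orf = find_longest_orf(seq, n_frames=n_frames)
    return CodingFeatures(
        orf_length_nt=float(orf.length_nt),
        orf_coverage=orf.length_nt / len(seq),
        fickett=fickett_score(seq),
        hexamer_bias=hexamer_table.bias(seq),
    )


def _features_matrix(features: list[CodingFeatures]) -> np.ndarray:
    return np.array([f.as_array() for f in features], dtype=float)


@dataclass(frozen=True)
class ConfusionCounts:
    """Confusion-matrix counts with *non-coding sequences as positives*:
    TP = non-coding predicted non-coding, FP = coding predicted non-coding,
    TN = coding predicted coding, FN = non-coding predicted coding."""

    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")


def sensitivity_specificity(c: ConfusionCounts) -> tuple[float, float]:
    """Sensitivity = TP/(TP+FN), Specificity = TN/(TN+FP)."""
    if c.TP + c.FN == 0 or c.TN + c.FP == 0:
        raise UndefinedRateError("zero denominator in sensitivity/specificity")
    return c.TP / (c.TP + c.FN), c.TN / (c.TN + c.FP)


@dataclass
class CodingModel:
    """Trained logistic classifier over :class:`CodingFeatures`.

    ``predict_proba`` returns the probability that a sequence is *coding*;
    candidates with probability strictly below ``cutoff`` are treated as
    non-coding.
    """

    weights: np.ndarray  # one per feature
    intercept: float
    cutoff: float
    cv_metrics: list[tuple[float, float]]
    training_seed: int

    def __post_init__(self) -> None:
        if not (0.0 < self.cutoff < 1.0):
            raise ValueError("cutoff must lie strictly inside (0, 1)")
        if self.weights.shape != (len(FEATURE_NAMES),):
            raise ValueError("one weight per feature expected")

    def predict_proba(self, features: list[CodingFeatures] | np.ndarray) -> np.ndarray:
        X = features if isinstance(features, np.ndarray) else _features_matrix(features)
        z = X @ self.weights + self.intercept
        return 1.0 / (1.0 + np.exp(-z))


def _confusion_from_scores(
    proba: np.ndarray, is_coding: np.ndarray, cutoff: float
) -> ConfusionCounts:
    pred_noncoding = proba < cutoff
    return ConfusionCounts(
        TP=int(np.sum(~is_coding & pred_noncoding)),
        FP=int(np.sum(is_coding & pred_noncoding)),
        TN=int(np.sum(is_coding & ~pred_noncoding)),
        FN=int(np.sum(~is_coding & ~pred_noncoding)),
    )


def _fit_logistic(X: np.ndarray, y: np.ndarray) -> LogisticRegression:
    clf = LogisticRegression(C=1e4, solver="lbfgs", max_iter=5000)
    clf.fit(X, y)
    return clf


def train_coding_model(
    coding_features: list[CodingFeatures],
    noncoding_features: list[CodingFeatures],
    folds: int = 10,
    scheme: str = "paper",
    seed: int = 0,
) -> CodingModel:
    """Train the logistic coding-potential classifier with fold-based CV.

    ``scheme="paper"`` follows the inverse cross-validation design: the data
    are split into ``folds`` parts, the model is trained on *one* part and
    evaluated on the remaining parts, repeated once per part (each sample is
    used once for training). ``scheme="standard"`` is conventional k-fold
    (train on k-1 parts, test on the held-out part). ``cv_metrics`` holds one
    (sensitivity, specificity) pair per repetition, computed at probability
    0.5 with non-coding as the positive class.

    The returned model is refit on all data; deterministic given ``seed``.
    """
    if scheme not in ("paper", "standard"):
        raise ValueError("scheme must be 'paper' or 'standard'")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if not coding_features or not noncoding_features:
        raise TrainingError("both feature sets must be non-empty")

    X = np.vstack(
        [_features_matrix(coding_features), _features_matrix(noncoding_features)]
    )
    y = np.concatenate(
        [np.ones(len(coding_features), bool), np.zeros(len(noncoding_features), bool)]
    )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(y))
    parts = np.array_split(order, folds)

    cv_metrics: list[tuple[float, float]] = []
    for i, part in enumerate(parts):
        if scheme == "paper":
            train_idx = part
            test_idx = np.concatenate([p for j, p in enumerate(parts) if j != i])
        else:
            train_idx = np.concatenate([p for j, p in enumerate(parts) if j != i])
            test_idx = part
        if len(np.unique(y[train_idx])) < 2:
            raise TrainingError(
                f"fold {i} training part contains a single class; "
                "provide more data or fewer folds"
            )
        clf = _fit_logistic(X[train_idx], y[train_idx])
        proba = clf.predict_proba(X[test_idx])[:, 1]
        cv_metrics.append(
            sensitivity_specificity(
                _confusion_from_scores(proba, y[test_idx], 0.5)
            )
        )

    final = _fit_logistic(X, y)
    return CodingModel(
        weights=final.coef_[0].copy(),
        intercept=float(final.intercept_[0]),
        cutoff=0.5,
        cv_metrics=cv_metrics,
        training_seed=seed,
    )


def train_classifier_from_sequences(
    coding_seqs: list[str],
    noncoding_seqs: list[str],
    folds: int = 10,
    scheme: str = "paper",
    seed: int = 0,
    n_frames: int = 3,
    cutoff_criterion: str = "max_sens_plus_spec",
) -> tuple["HexamerTable", "CodingModel"]:
    """Train the full classifier (hexamer table + logistic model + cutoff)
    from two sequence sets.

    The hexamer table is estimated on the first half of each set and the
    classifier is trained and cross-validated on the second half only:
    fitting both on the same sequences would leak sampling noise from the
    table into an artificially separable feature (visible as above-chance
    accuracy even when the two generators are identical).
    """
    if len(coding_seqs) < 2 or len(noncoding_seqs) < 2:
        raise TrainingError("need at least two sequences per class")
    c_split = len(coding_seqs) // 2
    n_split = len(noncoding_seqs) // 2
    table = train_hexamer_table(coding_seqs[:c_split], noncoding_seqs[:n_split])
    feats_cod = [
        compute_features(s, table, n_frames) for s in coding_seqs[c_split:]
    ]
    feats_non = [
        compute_features(s, table, n_frames) for s in noncoding_seqs[n_split:]
    ]
    model = train_coding_model(
        feats_cod, feats_non, folds=folds, scheme=scheme, seed=seed
    )
    sel = select_cutoff(
        model.predict_proba(feats_non),
        model.predict_proba(feats_cod),
        criterion=cutoff_criterion,
    )
    model.cutoff = sel.cutoff
    return table, model


@dataclass(frozen=True)
class CutoffSelection:
    cutoff: float
    sensitivity: float
    specificity: float


def select_cutoff(
    scores_noncoding: np.ndarray | list[float],
    scores_coding: np.ndarray | list[float],
    criterion: str = "max_sens_plus_spec",
) -> CutoffSelection:
    """Choose the coding-probability cutoff from two held-out score sets.

    Candidates are the midpoints between consecutive distinct observed scores.
    ``max_sens_plus_spec`` maximises (sensitivity + specificity)/2 (smallest
    qualifying cutoff on ties); ``sens_spec_crossing`` picks the candidate
    where sensitivity and specificity are closest. Non-coding sequences are
    called non-coding when their score falls strictly below the cutoff.
    """
    if criterion not in ("max_sens_plus_spec", "sens_spec_crossing"):
        raise ValueError(f"unknown criterion {criterion!r}")
    nc = np.asarray(scores_noncoding, dtype=float)
    cod = np.asarray(scores_coding, dtype=float)
    if nc.size == 0 or cod.size == 0:
        raise ValueError("both score lists must be non-empty")
    pooled = np.unique(np.concatenate([nc, cod]))
    if pooled.size == 1:
        candidates = np.array([pooled[0]])
    else:
        candidates = (pooled[:-1] + pooled[1:]) / 2.0

    sens = np.array([(nc < t).mean() for t in candidates])
    spec = np.array([(cod >= t).mean() for t in candidates])
    if criterion == "max_sens_plus_spec":
        objective = (sens + spec) / 2.0
        best = int(np.argmax(objective))  # argmax takes the first (smallest) tie
    else:
        objective = -np.abs(sens - spec)
        best = int(np.argmax(objective))
    return CutoffSelection(float(candidates[best]), float(sens[best]), float(spec[best]))


# ---------------------------------------------------------------------------
# Codon-conservation surrogate
# ---------------------------------------------------------------------------

@dataclass
class CodonAlignment:
    """A gapless-frame multi-species alignment anchored on the reference row.

    ``rows[0]`` is the reference species and corresponds (ungapped) to the
    transcript segment the ORF coordinates refer to.
    """

    species: list[str]
    rows: list[str]
    transcript_id: str = ""

    def __post_init__(self) -> None:
        if len(self.species) != len(self.rows) or not self.rows:
            raise ValueError("one row per species required")
        if len({len(r) for r in self.rows}) != 1:
            raise ValueError("alignment rows must have equal length")

    @property
    def reference_ungapped_length(self) -> int:
        return sum(1 for c in self.rows[0] if c != "-")


def codon_conservation_score(aln: CodonAlignment, orf: OrfResult) -> float:
    """Synonymous/non-synonymous substitution log-ratio over the ORF.

    For every non-reference species, each substituted codon (relative to the
    reference row, standard genetic code) is classified as synonymous or
    non-synonymous; the species contributes ``log((syn + 1)/(nonsyn + 1))``
    and contributions are summed. Positive scores indicate coding-like
    (synonymous-biased) constraint. Codons with gaps or ambiguity in the
    non-reference row are skipped; a gap inside the reference ORF breaks the
    anchored frame and raises :class:`AlignmentError`.
    """
    if not orf.found:
        raise ValueError("conservation score requires a found ORF")
    ref = aln.rows[0].upper()
    cols = [i for i, ch in enumerate(ref) if ch != "-"]
    if len(cols) < orf.end:
        raise AlignmentError("reference row does not cover the ORF")
    orf_cols = cols[orf.start : orf.end]
    if orf_cols[-1] - orf_cols[0] + 1 != len(orf_cols):
        raise AlignmentError("frame-breaking gap inside the reference ORF")

    score = 0.0
    for row in aln.rows[1:]:
        row = row.upper()
        syn = nonsyn = 0
        for k in range(0, len(orf_cols), 3):
            c3 = orf_cols[k : k + 3]
            ref_codon = "".join(ref[c] for c in c3)
            other_codon = "".join(row[c] for c in c3)
            if "-" in other_codon or any(b not in "ACGT" for b in other_codon):
                continue
            if other_codon == ref_codon:
                continue
            if _codon_aa(other_codon) == _codon_aa(ref_codon):
                syn += 1
            else:
                nonsyn += 1
        score += math.log((syn + 1) / (nonsyn + 1))
    return score


def calibrate_conservation_threshold(
    scores_known_noncoding: np.ndarray | list[float],
    scores_coding_controls: np.ndarray | list[float],
    retain_noncoding_frac: float = 0.73,
) -> tuple[float, float]:
    """Empirically place the conservation threshold from two control sets.

    Transcripts are retained as non-coding when ``score < threshold``
    (coding-like constraint yields high scores). The threshold is the
    smallest candidate boundary that keeps at least ``retain_noncoding_frac``
    of the known non-coding scores on the retained side — i.e. the
    complementary quantile of the non-coding score distribution — which
    maximises the fraction of coding controls removed. Returns
    ``(threshold, coding_removed_frac)``.
    """
    if not (0.0 < retain_noncoding_frac <= 1.0):
        raise ValueError("retain_noncoding_frac must lie in (0, 1]")
    nc = np.sort(np.asarray(scores_known_noncoding, dtype=float))
    cod = np.asarray(scores_coding_controls, dtype=float)
    if nc.size == 0 or cod.size == 0:
        raise ValueError("both score lists must be non-empty")
    k = math.ceil(retain_noncoding_frac * nc.size)

    distinct = np.unique(nc)
    candidates = list((distinct[:-1] + distinct[1:]) / 2.0)
    candidates.append(distinct[-1] + max(1e-9, 1e-9 * abs(distinct[-1])))
    threshold = candidates[-1]
    for t in candidates:
        if np.sum(nc < t) >= k:
            threshold = t
            break
    return float(threshold), float(np.mean(cod >= threshold))


# ---------------------------------------------------------------------------
# Three-frame translation and protein-domain filter
# ---------------------------------------------------------------------------

def translate_three_frames(sequence: str) -> tuple[str, str, str]:
    """Standard-code translation in frames 0/1/2; stops rendered as ``*``,
    trailing partial codons dropped, ambiguous codons as ``X``."""
    seq = _validate_sequence(sequence)
    if len(seq) < 3:
        raise ValueError("sequence shorter than one codon")
    out = []
    for frame in range(3):
        sub = seq[frame:]
        sub = sub[: 3 * (len(sub) // 3)]
        out.append(str(Seq(sub).translate()) if sub else "")
    return tuple(out)  # type: ignore[return-value]


@dataclass(frozen=True)
class DomainHit:
    motif: str
    frame: int
    position: int
    score: float


@dataclass
class PwmMotif:
    """A peptide position-weight-matrix with a per-motif score threshold."""

    name: str
    matrix: np.ndarray  # (length, 20) scores over AA_ALPHABET
    threshold: float
    unknown_score: float = -4.0

    def __post_init__(self) -> None:
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(AA_ALPHABET):
            raise ValueError("matrix must be (length, 20) over the AA alphabet")

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(AA_ALPHABET[j] for j in self.matrix.argmax(axis=1))

    def best_window(self, peptide: str) -> tuple[int, float] | None:
        """(offset, score) of the best-scoring window, or None if too short."""
        L = self.length
        if len(peptide) < L:
            return None
        aa_index = {a: j for j, a in enumerate(AA_ALPHABET)}
        best: tuple[int, float] | None = None
        for off in range(len(peptide) - L + 1):
            s = 0.0
            for k in range(L):
                j = aa_index.get(peptide[off + k])
                s += self.matrix[k, j] if j is not None else self.unknown_score
            if best is None or s > best[1]:
                best = (off, s)
        return best


class MotifDb:
    """Built-in PWM motif database (the test-friendly scanner mode)."""

    def __init__(self, motifs: list[PwmMotif]):
        self.motifs = list(motifs)

    def __len__(self) -> int:
        return len(self.motifs)

    def scan(self, peptides: list[str]) -> list[DomainHit]:
        hits = []
        for frame, pep in enumerate(peptides):
            for motif in self.motifs:
                bw = motif.best_window(pep)
                if bw is not None and bw[1] >= motif.threshold:
                    hits.append(DomainHit(motif.name, frame, bw[0], bw[1]))
        return hits

    def to_tsv(self, path) -> None:
        rows = []
        for m in self.motifs:
            for pos in range(m.length):
                rows.append(
                    [m.name, m.threshold, pos, *m.matrix[pos].tolist()]
                )
        df = pd.DataFrame(rows, columns=["motif", "threshold", "pos", *AA_ALPHABET])
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "MotifDb":
        try:
            df = pd.read_csv(path, sep="\t")
        except OSError as exc:  # pragma: no cover - filesystem dependent
            raise IOError(f"unreadable motif database {path}: {exc}") from exc
        motifs = []
        for name, grp in df.groupby("motif", sort=False):
            grp = grp.sort_values("pos")
            matrix = grp[list(AA_ALPHABET)].to_numpy(dtype=float)
            motifs.append(PwmMotif(str(name), matrix, float(grp["threshold"].iloc[0])))
        return cls(motifs)


class HmmerMotifDb:
    """External scanner mode: profile HMMs searched with the hmmscan
    algorithm (via pyhmmer). Only invoked when explicitly configured."""

    def __init__(self, hmm_path, e_value: float = 1e-5):
        self.hmm_path = str(hmm_path)
        self.e_value = e_value

    def scan(self, peptides: list[str]) -> list[DomainHit]:
        try:
            import pyhmmer
        except ImportError as exc:  # pragma: no cover
            raise IOError("pyhmmer is required for HMMER profile scanning") from exc
        alphabet = pyhmmer.easel.Alphabet.amino()
        seqs = [
            pyhmmer.easel.TextSequence(
                name=str(i).encode(), sequence=pep.replace("*", "X")
            ).digitize(alphabet)
            for i, pep in enumerate(peptides)
        ]
        with pyhmmer.plan7.HMMFile(self.hmm_path) as hmm_file:
            hmms = list(hmm_file)
        hits = []
        for top in pyhmmer.hmmscan(seqs, hmms):
            frame = int(top.query.name.decode())
            for hit in top:
                if hit.evalue <= self.e_value:
                    hits.append(DomainHit(hit.name.decode(), frame, 0, hit.score))
        return hits


def domain_filter(peptides: list[str], motif_db) -> tuple[bool, list[DomainHit]]:
    """True iff any frame's peptide hits a motif at or above its threshold."""
    hits = motif_db.scan(peptides)
    return bool(hits), hits


# ---------------------------------------------------------------------------
# Cascade
# ---------------------------------------------------------------------------

@dataclass
class CascadeResult:
    retained: list[TranscriptModel]
    audit: dict
    table: pd.DataFrame


def coding_cascade(
    candidates: list[TranscriptModel],
    sequences: dict[str, str],
    hexamer_table: HexamerTable | None = None,
    model: CodingModel | None = None,
    conservation_threshold: float | None = None,
    alignments: dict[str, CodonAlignment] | None = None,
    motif_db=None,
    n_frames: int = 3,
) -> CascadeResult:
    """Run the three-stage filter and intersect the survivors.

    A candidate is retained when it passes every *enabled* stage:
    conservation score strictly below the threshold (candidates without an
    alignment or without an ORF carry no coding evidence and pass), coding
    probability strictly below the model cutoff, and no known protein motif
    in any of the three frame translations. Any stage is disabled by leaving
    its inputs ``None``. The audit records the candidate count after each
    stage applied in sequence, plus standalone per-stage pass counts.
    """
    if model is not None and hexamer_table is None:
        raise ValueError("classifier stage requires a hexamer table")
    cons_enabled = conservation_threshold is not None and alignments is not None
    clf_enabled = model is not None
    dom_enabled = motif_db is not None

    records = []
    for t in candidates:
        seq = sequences[t.transcript_id]
        orf = find_longest_orf(seq, n_frames=n_frames)

        cons_score = np.nan
        cons_pass = True
        if cons_enabled:
            aln = alignments.get(t.transcript_id)
            if aln is not None and orf.found:
                cons_score = codon_conservation_score(aln, orf)
                cons_pass = cons_score < conservation_threshold

        proba = np.nan
        clf_pass = True
        if clf_enabled:
            feats = CodingFeatures(
                orf_length_nt=float(orf.length_nt),
                orf_coverage=orf.length_nt / len(seq),
                fickett=fickett_score(seq),
                hexamer_bias=hexamer_table.bias(seq),
            )
            proba = float(model.predict_proba([feats])[0])
            clf_pass = proba < model.cutoff

        has_motif = False
        if dom_enabled:
            has_motif, _ = domain_filter(list(translate_three_frames(seq)), motif_db)

        records.append(
            {
                "transcript_id": t.transcript_id,
                "orf_length_nt": orf.length_nt,
                "conservation_score": cons_score,
                "coding_probability": proba,
                "has_known_motif": has_motif,
                "pass_conservation": cons_pass,
                "pass_classifier": clf_pass,
                "pass_domain": not has_motif,
                "retained": cons_pass and clf_pass and not has_motif,
            }
        )

    table = pd.DataFrame(
        records,
        columns=[
            "transcript_id",
            "orf_length_nt",
            "conservation_score",
            "coding_probability",
            "has_known_motif",
            "pass_conservation",
            "pass_classifier",
            "pass_domain",
            "retained",
        ],
    )
    retained_ids = (
        set(table.loc[table["retained"], "transcript_id"]) if len(table) else set()
    )
    retained = [t for t in candidates if t.transcript_id in retained_ids]

    n = len(candidates)
    if n:
        after_cons = int((table["pass_conservation"]).sum())
        after_clf = int((table["pass_conservation"] & table["pass_classifier"]).sum())
        after_dom = int(table["retained"].sum())
        stage_pass = {
            "conservation": int(table["pass_conservation"].sum()),
            "classifier": int(table["pass_classifier"].sum()),
            "domain": int(table["pass_domain"].sum()),
        }
    else:
        after_cons = after_clf = after_dom = 0
        stage_pass = {"conservation": 0, "classifier": 0, "domain": 0}
    audit = {
        "n_input": n,
        "stages_enabled": {
            "conservation": cons_enabled,
            "classifier": clf_enabled,
            "domain": dom_enabled,
        },
        "after_conservation": after_cons,
        "after_classifier": after_clf,
        "after_domain": after_dom,
        "stage_pass_counts": stage_pass,
        "n_retained": len(retained),
    }
    return CascadeResult(retained=retained, audit=audit, table=table)
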