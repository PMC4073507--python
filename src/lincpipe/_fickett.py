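"""Fickett TESTCODE lookup tables.

The statistic combines, for each base, a *position* parameter (asymmetry of
the base's usage across the three codon positions, max count / (min count + 1))
and a *content* parameter (overall fraction of the base). Each parameter is
converted to a probability-of-coding through the published lookup tables and
weighted by the base-specific discriminative weight; the score is the sum of
the eight weighted probabilities.
"""

from __future__ import annotations

# Thresholds scanned top-down; the first threshold <= parameter selects the row.
POSITION_PARAMETER = (1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 0.0)
CONTENT_PARAMETER = (0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.19, 0.17, 0.0)

POSITION_PROBABILITY = {
    "A": (0.94, 0.68, 0.84, 0.93, 0.58, 0.68, 0.45, 0.34, 0.20, 0.22),
    "C": (0.80, 0.70, 0.70, 0.81, 0.66, 0.48, 0.51, 0.33, 0.30, 0.23),
    "G": (0.90, 0.88, 0.74, 0.64, 0.53, 0.48, 0.27, 0.16, 0.08, 0.08),
    "T": (0.97, 0.97, 0.91, 0.68, 0.69, 0.44, 0.54, 0.20, 0.09, 0.09),
}

CONTENT_PROBABILITY = {
    "A": (0.28, 0.49, 0.44, 0.55, 0.62, 0.49, 0.67, 0.65, 0.81, 0.21),
    "C": (0.82, 0.64, 0.51, 0.64, 0.59, 0.59, 0.43, 0.44, 0.39, 0.31),
    "G": (0.40, 0.54, 0.47, 0.64, 0.64, 0.73, 0.41, 0.41, 0.33, 0.29),
    "T": (0.28, 0.24, 0.39, 0.40, 0.55, 0.75, 0.56, 0.69, 0.51, 0.58),
}

POSITION_WEIGHT = {"A": 0.26, "C": 0.18, "G": 0.31, "T": 0.33}
CONTENT_WEIGHT = {"A": 0.11, "C": 0.12, "G": 0.15, "T": 0.14}


def _lookup(value: float, thresholds: tuple[float, ...], probs: tuple[float, ...]) -> float:
    for thr, p in zip(thresholds, probs):
        if value >= thr:
            return p
    return probs[-1]


def fickett_score(sequence: str) -> float:
    """Fickett TESTCODE score of a nucleotide sequence (case-insensitive).

    Bases other than A/C/G/T (e.g. N) are ignored in the counts. Raises
    ValueError for sequences shorter than 6 nt.
    """
    seq = sequence.upper()
    if len(seq) < 6:
        raise ValueError("fickett_score needs a sequence of length >= 6")

    phase_counts = {b: [0, 0, 0] for b in "ACGT"}
    total = {b: 0 for b in "ACGT"}
    for i, base in enumerate(seq):
        if base in phase_counts:
            phase_counts[base][i % 3] += 1
            total[base] += 1
    n_counted = sum(total.values())
    if n_counted == 0:
        raise ValueError("sequence contains no A/C/G/T bases")

    score = 0.0
    for base in "ACGT":
        counts = phase_counts[base]
        position_param = max(counts) / (min(counts) + 1)
        content_param = total[base] / n_counted
        score += POSITION_WEIGHT[base] * _lookup(
            position_param, POSITION_PARAMETER, POSITION_PROBABILITY[base]
        )
        score += CONTENT_WEIGHT[base] * _lookup(
            content_param, CONTENT_PARAMETER, CONTENT_PROBABILITY[base]
        )
    return score
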