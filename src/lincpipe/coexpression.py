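"""All-pairs lincRNA / protein-coding co-expression screen.

Spearman's rank correlation is computed for every (lincRNA, coding) pair of
expression profiles; significance is controlled family-wise by Bonferroni
(alpha divided by the number of pairs). With the study design of nine
samples the exact permutation p-value is available by full enumeration of
9! = 362,880 rank permutations — note that its smallest attainable two-sided
value, 2/9!, can never beat a Bonferroni bound of order 1e-8, so exact-p
screens of that size report no significant pair; only the asymptotic
t-approximation (which collapses to 0 at |rho| = 1) can. Each pair records
which method produced its p-value.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomicInterval

__all__ = [
    "CorrelationPair",
    "spearman_pair",
    "bonferroni_threshold",
    "all_pairs_screen",
    "ScreenResult",
]

EXACT_MAX_N = 9  #: exact enumeration is n! permutations; capped at 9


@dataclass(frozen=True)
class CorrelationPair:
    linc_id: str
    coding_id: str
    rho: float | None  # None when a profile is constant (undefined)
    p_value: float | None
    p_method: str  # "exact" | "asymptotic" | "undefined"
    genomic_distance_bp: int | None  # None across chromosomes
    is_cis: bool
    passes_bonferroni: bool


@lru_cache(maxsize=4)
def _permutation_matrix(n: int) -> np.ndarray:
    return np.array(list(itertools.permutations(range(n))), dtype=np.int8)


@lru_cache(maxsize=4)
def _untied_null_abs_rho(n: int) -> np.ndarray:
    """Sorted |rho| over all n! permutations of untied ranks vs untied ranks."""
    perms = _permutation_matrix(n).astype(np.float64)
    ranks = np.arange(n, dtype=np.float64)
    rho = _pearson_rows(perms, ranks)
    return np.sort(np.abs(rho))


def _pearson_rows(rows: np.ndarray, y: np.ndarray) -> np.ndarray:
    rc = rows - rows.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    denom = np.sqrt((rc**2).sum(axis=1) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        return (rc @ yc) / denom


def _exact_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p by full enumeration of n! permutations."""
    n = rx.size
    if n > EXACT_MAX_N:
        raise ValueError(f"exact permutation p limited to n <= {EXACT_MAX_N}")
    tol = 1e-12
    untied = not (_has_ties(rx) or _has_ties(ry))
    if untied:
        null_abs = _untied_null_abs_rho(n)
        count = null_abs.size - np.searchsorted(null_abs, abs(rho_obs) - tol, "left")
        return count / null_abs.size
    perms = _permutation_matrix(n)
    rho = _pearson_rows(rx[perms].astype(np.float64), ry.astype(np.float64))
    return float(np.mean(np.abs(rho) >= abs(rho_obs) - tol))


def _has_ties(ranks: np.ndarray) -> bool:
    return np.unique(ranks).size < ranks.size


def _asymptotic_p(rho: float, n: int) -> float:
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    return 2.0 * float(stats.t.sf(abs(t), df=n - 2))


def spearman_pair(
    x, y, p_method: str | None = None
) -> tuple[float | None, float | None, str]:
    """Spearman rho (average ranks on ties) and a two-sided p-value.

    ``p_method`` is ``"exact"`` (full permutation enumeration, n <= 9),
    ``"asymptotic"`` (t approximation), or None for the default: exact when
    n <= 9, asymptotic above. A constant profile has undefined rank
    correlation; (None, None, "undefined") is returned rather than NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("profiles must share a length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None, None, "undefined"
    if p_method is None:
        p_method = "exact" if x.size <= EXACT_MAX_N else "asymptotic"
    if p_method not in ("exact", "asymptotic"):
        raise ValueError(f"unknown p_method {p_method!r}")

    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(_pearson_rows(rx[None, :], ry)[0])
    if p_method == "exact":
        p = _exact_p(rx, ry, rho)
    else:
        p = _asymptotic_p(rho, x.size)
    return rho, p, p_method


def bonferroni_threshold(n_linc: int, n_coding: int, alpha: float = 0.05) -> float:
    """Per-test threshold alpha / (n_linc x n_coding)."""
    if n_linc < 1 or n_coding < 1:
        raise ValueError("need at least one gene per group")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    return alpha / (n_linc * n_coding)


def _span_distance(a: GenomicInterval, b: GenomicInterval) -> int | None:
    """Gap between spans (0 if overlapping); None across chromosomes."""
    if a.chrom != b.chrom:
        return None
    return a.gap_to(b)


@dataclass
class ScreenResult:
    pairs: list[CorrelationPair]
    summary: dict

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "linc_id": p.linc_id,
                    "coding_id": p.coding_id,
                    "rho": p.rho,
                    "p_value": p.p_value,
                    "p_method": p.p_method,
                    "distance_bp": p.genomic_distance_bp,
                    "is_cis": p.is_cis,
                    "significant": p.passes_bonferroni,
                }
                for p in self.pairs
            ]
        )


def all_pairs_screen(
    linc_matrix: pd.DataFrame,
    coding_matrix: pd.DataFrame,
    loci_positions: dict[str, GenomicInterval] | None = None,
    alpha: float = 0.05,
    cis_window_bp: int = 2_000_000,
    p_method: str | None = None,
    correction: str = "bonferroni",
) -> ScreenResult:
    """Test every (lincRNA, coding) profile pair and flag significant ones.

    Both matrices are genes x samples with identical sample ordering.
    Significance under ``correction="bonferroni"`` means p below
    ``alpha / n_pairs``; ``correction="none"`` reproduces the uncorrected
    screen (raw p < alpha). A pair is *cis* when both genes sit on the same
    chromosome with a span gap strictly below ``cis_window_bp``;
    anti-correlated pairs are significant pairs with rho < 0.
    """
    if list(linc_matrix.columns) != list(coding_matrix.columns):
        raise ValueError("sample ordering of the two matrices must agree")
    if correction not in ("bonferroni", "none"):
        raise ValueError(f"unknown correction {correction!r}")
    n_samples = linc_matrix.shape[1]
    n_pairs = linc_matrix.shape[0] * coding_matrix.shape[0]
    if n_pairs == 0:
        return ScreenResult(
            [],
            {
                "n_pairs_tested": 0,
                "n_significant": 0,
                "n_cis_significant": 0,
                "n_anti_correlated": 0,
                "per_test_threshold": None,
            },
        )
    threshold = (
        bonferroni_threshold(linc_matrix.shape[0], coding_matrix.shape[0], alpha)
        if correction == "bonferroni"
        else alpha
    )

    pairs: list[CorrelationPair] = []
    linc_values = linc_matrix.to_numpy(dtype=float)
    coding_values = coding_matrix.to_numpy(dtype=float)
    for i, linc_id in enumerate(linc_matrix.index):
        for j, coding_id in enumerate(coding_matrix.index):
            rho, p, method = spearman_pair(
                linc_values[i], coding_values[j], p_method=p_method
            )
            distance = None
            is_cis = False
            if loci_positions is not None:
                pa = loci_positions.get(str(linc_id))
                pb = loci_positions.get(str(coding_id))
                if pa is not None and pb is not None:
                    distance = _span_distance(pa, pb)
                    is_cis = distance is not None and distance < cis_window_bp
            significant = p is not None and p < threshold
            pairs.append(
                CorrelationPair(
                    linc_id=str(linc_id),
                    coding_id=str(coding_id),
                    rho=rho,
                    p_value=p,
                    p_method=method,
                    genomic_distance_bp=distance,
                    is_cis=is_cis,
                    passes_bonferroni=significant,
                )
            )

    significant_pairs = [p for p in pairs if p.passes_bonferroni]
    summary = {
        "n_pairs_tested": len(pairs),
        "n_samples": n_samples,
        "n_significant": len(significant_pairs),
        "n_cis_significant": sum(1 for p in significant_pairs if p.is_cis),
        "n_anti_correlated": sum(
            1 for p in significant_pairs if p.rho is not None and p.rho < 0
        ),
        "per_test_threshold": threshold,
        "correction": correction,
    }
    return ScreenResult(pairs, summary)
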