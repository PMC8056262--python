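"""Repertoire diversity statistics and the paired small-sample test.

The clonality index of a sample with N unique clonotypes at frequencies
P_i is

    H      = -sum_i P_i log2 P_i        (Shannon entropy, bits)
    H_max  = log2 N
    H_norm = H / H_max
    clonality = 1 - H_norm

ranging from 0 (maximal diversity) to 1 (a completely oligoclonal sample);
normalising by H_max makes the index comparable across sequencing depths.

Paired brain/blood comparisons use the Wilcoxon signed-rank test with an
exact null distribution for small samples (n <= 25), obtained by dynamic
programming over the W+ distribution — identical to enumerating all 2^n
sign assignments. Larger samples fall back to the normal approximation
with tie-corrected variance and continuity correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .repertoire_io import ClonotypeTable, DegenerateInputError

EXACT_ENUMERATION_CUTOFF = 25


@dataclass(frozen=True)
class ClonalityResult:
    H: float
    H_max: float
    H_norm: float
    clonality: float
    n_unique: int


@dataclass(frozen=True)
class PairedTestResult:
    statistic: float  # min(W+, W-)
    n_effective: int  # pairs remaining after dropping zero differences
    p_two_sided: float
    method: str  # "exact" or "normal_approx"


def shannon_entropy(frequencies: Sequence[float], tol: float = 1e-6) -> float:
    """Shannon entropy in bits of a frequency vector summing to 1.

    Zero frequencies contribute nothing (0·log 0 := 0); negative entries or
    a sum outside ``1 ± tol`` raise a domain error.
    """
    p = np.asarray(frequencies, dtype=float)
    if p.size == 0:
        raise ValueError("empty frequency vector")
    if (p < 0).any():
        raise ValueError("frequencies must be non-negative")
    total = p.sum()
    if abs(total - 1.0) > tol:
        raise ValueError(f"frequencies sum to {total}, outside 1 ± {tol}")
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def clonality_index(table: ClonotypeTable) -> ClonalityResult:
    """Clonality index 1 - H/log2(N) of one clonotype table.

    A single-clonotype sample has H_max = 0 and an undefined ratio; its
    clonality is defined as 1 (the oligoclonal endpoint).
    """
    n = table.n_unique
    if n == 0:
        raise DegenerateInputError("cannot compute clonality of an empty table")
    h = shannon_entropy(table.frequencies)
    if n == 1:
        return ClonalityResult(H=0.0, H_max=0.0, H_norm=0.0, clonality=1.0, n_unique=1)
    h_max = float(np.log2(n))
    h_norm = h / h_max
    return ClonalityResult(H=h, H_max=h_max, H_norm=h_norm, clonality=1.0 - h_norm, n_unique=n)


def _signed_ranks(differences: np.ndarray) -> np.ndarray:
    """Average ranks of |differences| (ties share their mean rank)."""
    return stats.rankdata(np.abs(differences), method="average")


def _exact_two_sided_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p for the signed-rank W+ over all 2^n sign vectors.

    Ranks may be half-integers under ties, so everything is doubled to
    integers; the distribution of W+ is built by convolution, one pair at
    a time (equivalent to full enumeration).
    """
    ranks2 = np.rint(2 * ranks).astype(np.int64)
    total2 = int(ranks2.sum())
    counts = np.zeros(total2 + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total2 + 1 - r]
        counts = counts + shifted
    n_outcomes = 2.0 ** len(ranks)
    w2 = int(round(2 * w_plus))
    lower = counts[: min(w2, total2 - w2) + 1].sum()
    upper = counts[max(w2, total2 - w2):].sum()
    return min(1.0, (lower + upper) / n_outcomes)


def paired_signed_rank(
    values_a: Sequence[float], values_b: Sequence[float]
) -> PairedTestResult:
    """Two-sided Wilcoxon signed-rank test on paired observations.

    Zero differences are dropped; the statistic is min(W+, W-). The exact
    null is used for n_effective <= 25, the tie-corrected normal
    approximation with continuity correction above that.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("values_a and values_b must be 1-d and of equal length")
    d = a - b
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise DegenerateInputError("all paired differences are zero; test undefined")
    ranks = _signed_ranks(d)
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    statistic = min(w_plus, w_minus)
    if n <= EXACT_ENUMERATION_CUTOFF:
        p = _exact_two_sided_p(ranks, w_plus)
        method = "exact"
    else:
        mean = n * (n + 1) / 4.0
        # tie correction over groups of equal |d|
        _, tie_counts = np.unique(np.abs(d), return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - ((tie_counts**3 - tie_counts).sum()) / 48.0
        z = (statistic - mean + 0.5) / np.sqrt(var)
        p = min(1.0, 2.0 * stats.norm.cdf(z))
        method = "normal_approx"
    return PairedTestResult(
        statistic=statistic, n_effective=n, p_two_sided=float(p), method=method
    )
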