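"""Significance machinery: permutation tests of AuROC and Wilcoxon tests.

The permutation test asks whether a classifier's AuROC on a test set beats
chance: the class labels are permuted ``n_perm`` times, the AuROC recomputed
under each permutation, and the p-value taken as ``(1 + #{null >= observed})
/ (1 + n_perm)`` (add-one rule, so p is never zero and never below
``1/(n_perm+1)``).  Labels are permuted within one test set (in the
evaluation protocol: within one held-out patient).

The Wilcoxon signed-rank test compares paired per-patient performances of two
models.  Zero differences are dropped; for up to 25 informative pairs the
two-sided p-value is exact (computed by enumerating the sign-flip null over
the — possibly tied — ranks via dynamic programming); above that, a normal
approximation with tie-corrected variance and continuity correction is used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    n: int  # permutations drawn, or informative pairs
    method: str
    seed: int | None = None


def _auroc_from_ranks(pos_mask: np.ndarray, ranks: np.ndarray) -> np.ndarray:
    """Mann-Whitney AuROC (ties counted 1/2) from average ranks.

    ``pos_mask`` may be a matrix of label permutations (one per row).
    """
    pos_mask = np.atleast_2d(pos_mask)
    n1 = pos_mask[0].sum()
    n0 = pos_mask.shape[1] - n1
    r1 = pos_mask @ ranks
    return (r1 - n1 * (n1 + 1) / 2.0) / (n1 * n0)


def permutation_test_auroc(scores, labels, n_perm: int = 999,
                           seed: int | None = 0) -> TestResult:
    """One-sided permutation test of AuROC > chance."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    pos = labels == np.max(labels)
    if pos.all() or not pos.any():
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)
    observed = float(_auroc_from_ranks(pos, ranks)[0])
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(pos, (n_perm, 1)), axis=1)
    null = _auroc_from_ranks(perms, ranks)
    p = (1.0 + np.sum(null >= observed - 1e-12)) / (1.0 + n_perm)
    return TestResult(observed, float(p), n_perm, "permutation", seed)


def _exact_signflip_p(ranks2: np.ndarray, w2: int) -> float:
    """Two-sided exact p for scaled (x2, integer) signed ranks.

    Enumerates the 2^n equiprobable sign assignments with a subset-sum DP
    over the doubled ranks; the null distribution of W+ is symmetric about
    total/2, so the two-sided p is twice the smaller tail.
    """
    total = int(ranks2.sum())
    dp = np.zeros(total + 1)
    dp[0] = 1.0
    for s in ranks2:
        s = int(s)
        dp[s:] = dp[s:] + dp[:-s] if s > 0 else dp[s:] * 2
    dp /= dp.sum()
    lo = min(w2, total - w2)
    p = 2.0 * dp[: lo + 1].sum()
    return float(min(p, 1.0))


def wilcoxon_signed_rank(paired_a, paired_b) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired samples."""
    a = np.asarray(paired_a, dtype=np.float64)
    b = np.asarray(paired_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if len(a) < 5:
        raise ValueError("need at least 5 pairs")
    d = a - b
    d = d[d != 0.0]
    n = len(d)
    if n == 0:
        return TestResult(0.0, 1.0, 0, "exact")
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= 25:
        ranks2 = np.round(2.0 * ranks).astype(int)
        w2 = int(round(2.0 * w_plus))
        return TestResult(w_plus, _exact_signflip_p(ranks2, w2), n, "exact")
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, counts = np.unique(ranks, return_counts=True)
    var -= np.sum(counts**3 - counts) / 48.0
    z = (abs(w_plus - mu) - 0.5) / np.sqrt(var)
    return TestResult(w_plus, float(min(1.0, 2.0 * norm.sf(z))), n, "normal")
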