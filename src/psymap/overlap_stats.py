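"""Gene-set overlap testing against a background universe.

The question is always the same: given a query set of n genes and a
reference set of K genes drawn from a background of N genes, is an overlap
of k genes larger than chance? Under the null the overlap is
hypergeometric, and the one-tailed Fisher exact test on the 2x2 table is
exactly the hypergeometric upper tail P(X >= k). Multiple references are
adjusted with Benjamini-Hochberg.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .gene_sets import GeneSet, intersect

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class OverlapResult:
    k: int           # overlap count
    n: int           # query size (within background)
    K: int           # reference size (within background)
    N: int           # background size
    expected: float  # n*K/N genes expected by chance
    odds_ratio: float
    p: float         # upper-tail probability P(X >= k)

    def to_dict(self) -> dict:
        return asdict(self)


def _validate_counts(k: int, n: int, K: int, N: int) -> None:
    if min(k, n, K, N) < 0:
        raise ValueError("counts must be non-negative")
    if k > min(n, K):
        raise ValueError(f"overlap k={k} exceeds min(n={n}, K={K})")
    if N < n + K - k:
        raise ValueError(f"background N={N} smaller than union n+K-k={n + K - k}")
    if n > N or K > N:
        raise ValueError("set sizes cannot exceed background size")


def hypergeom_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    Equivalent to a one-tailed (greater) Fisher exact test on the 2x2
    overlap table. k = 0 covers the whole support, so p = 1.
    """
    _validate_counts(k, n, K, N)
    # sf(k-1) = P(X >= k); scipy evaluates the tail in log space internally
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def _odds_ratio(k: int, n: int, K: int, N: int) -> float:
    num_den = (n - k) * (K - k)
    numerator = k * (N - n - K + k)
    if num_den == 0:
        return float("inf") if numerator > 0 else float("nan")
    return numerator / num_den


def fisher_overlap(query: GeneSet, reference: GeneSet,
                   background: GeneSet) -> OverlapResult:
    """One-tailed overlap test of two gene sets on a common background.

    Genes of either set absent from the background are dropped (with a
    log message) before counting — mirroring analyses where both sets are
    pre-filtered to the genes the expression atlas actually quantifies.
    """
    if len(background) == 0:
        raise ValueError("background gene set is empty")
    q = intersect(query, background, name=query.name)
    r = intersect(reference, background, name=reference.name)
    dropped = (len(query) - len(q)) + (len(reference) - len(r))
    if dropped:
        log.warning("fisher_overlap: dropped %d genes absent from background", dropped)
    k = len(intersect(q, r))
    n, K, N = len(q), len(r), len(background)
    return OverlapResult(
        k=k, n=n, K=K, N=N,
        expected=n * K / N,
        odds_ratio=_odds_ratio(k, n, K, N),
        p=hypergeom_upper_tail(k, n, K, N),
    )


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
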