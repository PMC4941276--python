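"""Directional overlap of differential probe sets between two cohorts.

Given differential-methylation tables for two cohorts labelled with the same
thresholds, the overlap of each direction pair (A-hyper×B-hyper,
A-hyper×B-hypo, A-hypo×B-hyper, A-hypo×B-hypo) is scored with an upper-tail
hypergeometric test. The universe is the set of probes tested in both
cohorts (probes "with available data" in each), not the whole array, and no
multiple-testing correction is applied across the four cells.

The tail probability is computed in log space (gammaln + logsumexp), which
stays accurate for the extreme tails that concordant cohorts produce
(p ≈ 1e-200 and below).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from sklearn.base import BaseEstimator

__all__ = [
    "DirectionalOverlapResult",
    "DirectionalOverlap",
    "hypergeom_upper",
    "hypergeom_logsf",
    "directional_overlap",
]


@dataclass(frozen=True)
class DirectionalOverlapResult:
    direction_a: str
    direction_b: str
    n_universe: int
    n_a: int
    n_b: int
    k: int
    proportion: float  # k / n_a
    p_hyper: float  # P(X >= k), X ~ Hypergeom(N, K=n_b, n=n_a)


def _log_hyper_pmf(k: np.ndarray, N: int, K: int, n: int) -> np.ndarray:
    """log P(X = k) for X ~ Hypergeometric(N, K, n) via log binomials."""

    def logC(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    return logC(K, k) + logC(N - K, n - k) - logC(N, n)


def hypergeom_logsf(k: int, K: int, n: int, N: int) -> float:
    """log P(X >= k) for X ~ Hypergeometric(N, K, n), exact in log space."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"require 0 <= K,n <= N, got K={K}, n={n}, N={N}")
    if k > min(K, n):
        raise ValueError(f"k ({k}) exceeds min(K, n) = {min(K, n)}")
    lo = max(k, 0, n - (N - K))
    hi = min(K, n)
    if lo > hi:
        return float("-inf")
    support = np.arange(lo, hi + 1)
    return float(logsumexp(_log_hyper_pmf(support, N, K, n)))


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric p-value P(X >= k).

    X counts the overlap between a size-n draw and a size-K subset of a
    size-N universe. P(X >= 0) = 1 by construction.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"require 0 <= K,n <= N, got K={K}, n={n}, N={N}")
    if k > min(K, n):
        raise ValueError(f"k ({k}) exceeds min(K, n) = {min(K, n)}")
    if k <= max(0, n - (N - K)):
        return 1.0
    return float(np.exp(min(0.0, hypergeom_logsf(k, K, n, N))))


_DIRECTIONS = ("hyper", "hypo")


def directional_overlap(
    diff_a: pd.DataFrame, diff_b: pd.DataFrame
) -> list[DirectionalOverlapResult]:
    """Four directional overlap tests between two labelled cohort tables.

    Each table needs columns probe_id and label (from the differential caller,
    with identical thresholds). The universe is the intersection of probes
    present in both tables; set sizes and overlaps are counted inside it.
    """
    for name, t in (("A", diff_a), ("B", diff_b)):
        missing = {"probe_id", "label"} - set(t.columns)
        if missing:
            raise ValueError(f"cohort {name} table missing columns {sorted(missing)}")
    a = diff_a.set_index("probe_id")["label"]
    b = diff_b.set_index("probe_id")["label"]
    universe = a.index.intersection(b.index)
    n_universe = len(universe)
    if n_universe == 0:
        raise ValueError("empty universe: the cohorts share no probes")
    a = a.loc[universe]
    b = b.loc[universe]
    results = []
    for da in _DIRECTIONS:
        set_a = set(universe[a == da])
        for db in _DIRECTIONS:
            set_b = set(universe[b == db])
            k = len(set_a & set_b)
            n_a, n_b = len(set_a), len(set_b)
            p = hypergeom_upper(k, n_b, n_a, n_universe) if n_a and n_b else 1.0
            results.append(
                DirectionalOverlapResult(
                    direction_a=da,
                    direction_b=db,
                    n_universe=n_universe,
                    n_a=n_a,
                    n_b=n_b,
                    k=k,
                    proportion=(k / n_a) if n_a else 0.0,
                    p_hyper=p,
                )
            )
    return results


class DirectionalOverlap(BaseEstimator):
    """Estimator wrapper: ``fit(diff_a, diff_b)`` leaves the 4-cell table in ``results_``."""

    def fit(self, diff_a: pd.DataFrame, diff_b: pd.DataFrame):
        cells = directional_overlap(diff_a, diff_b)
        self.results_ = pd.DataFrame([c.__dict__ for c in cells])
        return self
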