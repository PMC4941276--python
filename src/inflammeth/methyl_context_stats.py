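"""Methylation-context statistics around the core pipeline.

Covers: coverage-filtered RRBS methylation partitioned by binding-peak
overlap with two-sample Kolmogorov-Smirnov testing (methylation vs
looping-factor occupancy); methylation-sensitive high-resolution melting
(MS-HRM) categorical analysis with Fisher's exact test and bin-midpoint
mapping; Spearman methylation–expression correlation; Mann-Whitney U group
comparison; and the join of enhancer-linked genes onto expression
fold-change tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genomic_core import FeatureSet, GenomePosition

__all__ = [
    "CpGMethRecord",
    "KSResult",
    "HRM_BINS",
    "ContingencyTable2x2",
    "filter_coverage",
    "partition_by_peaks",
    "ks_two_sample",
    "fisher_exact_2x2",
    "hrm_midpoint",
    "spearman_corr",
    "mann_whitney",
    "target_expression_summary",
    "read_rrbs",
]

#: Exact Mann-Whitney enumeration is used when n*m is at most this.
MANN_WHITNEY_EXACT_MAX = 400


@dataclass(frozen=True)
class CpGMethRecord:
    """One RRBS CpG: position, read coverage, methylated fraction (beta)."""

    position: GenomePosition
    coverage: int
    beta: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.beta <= 1.0):
            raise ValueError(f"beta must be in [0,1], got {self.beta}")
        if self.coverage < 0:
            raise ValueError("coverage must be >= 0")


@dataclass(frozen=True)
class KSResult:
    D: float
    p: float


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]; rows are groups, columns outcomes."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("table total must be > 0")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


#: MS-HRM percent-methylation bins and their midpoints (mean of bin edges).
HRM_BINS: dict[str, tuple[float, float]] = {
    "0-5": (0.0, 5.0),
    "6-10": (6.0, 10.0),
    "11-25": (11.0, 25.0),
    "26-50": (26.0, 50.0),
}


def hrm_midpoint(category: str) -> float:
    """Midpoint (arithmetic mean of bin edges) of an MS-HRM category, in percent."""
    try:
        lo, hi = HRM_BINS[category]
    except KeyError:
        raise ValueError(f"unknown MS-HRM category {category!r}; valid: {list(HRM_BINS)}") from None
    return (lo + hi) / 2.0


def filter_coverage(records: Iterable[CpGMethRecord], min_cov: int = 5) -> list[CpGMethRecord]:
    """Records with coverage >= min_cov ("at least 5X"), order preserved."""
    return [r for r in records if r.coverage >= min_cov]


def partition_by_peaks(
    records: Iterable[CpGMethRecord], peaks: FeatureSet
) -> tuple[np.ndarray, np.ndarray]:
    """Split betas into (inside peaks, outside peaks): a disjoint, exhaustive partition."""
    betas_in, betas_out = [], []
    for r in records:
        (betas_in if peaks.overlaps(r.position) else betas_out).append(r.beta)
    return np.asarray(betas_in, dtype=float), np.asarray(betas_out, dtype=float)


def ks_two_sample(a, b) -> KSResult:
    """Two-sided two-sample Kolmogorov-Smirnov test with asymptotic p-value."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(a, b, alternative="two-sided", method="asymp")
    return KSResult(D=float(res.statistic), p=float(res.pvalue))


def fisher_exact_2x2(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p: sum of conditional table probabilities <= observed."""
    return float(stats.fisher_exact(table.as_array(), alternative="two-sided")[1])


def spearman_corr(x, y) -> float | None:
    """Spearman rank correlation (mid-ranks for ties); None for constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("vectors must share length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        return None
    return float(stats.spearmanr(x, y).statistic)


def mann_whitney(a, b) -> tuple[float, float]:
    """Mann-Whitney U (for sample a) with two-sided p.

    Exact enumeration when n·m <= 400 and no cross-group ties; otherwise
    tie-corrected normal approximation with continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    use_exact = a.size * b.size <= MANN_WHITNEY_EXACT_MAX and not np.isin(a, b).any()
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact" if use_exact else "asymptotic")
    return float(res.statistic), float(res.pvalue)


def target_expression_summary(
    links: pd.DataFrame,
    expr: pd.DataFrame,
    p_adj_max: float = 0.05,
) -> pd.DataFrame:
    """Join enhancer-linked genes onto per-gene expression statistics.

    links: table with a gene_id column (one row per link). expr: columns
    gene_id, fold_change, p_adj. Genes absent from expr are kept and flagged
    (in_expr=False) rather than dropped. direction: 'down' when
    fold_change < 1 and p_adj < p_adj_max, 'up' when fold_change > 1 and
    p_adj < p_adj_max, else 'ns'.
    """
    genes = (
        links["gene_id"].dropna().drop_duplicates().sort_values().reset_index(drop=True)
    )
    expr_idx = expr.set_index("gene_id")
    rows = []
    for g in genes:
        if g in expr_idx.index:
            fc = float(expr_idx.loc[g, "fold_change"])
            p = float(expr_idx.loc[g, "p_adj"])
            if p < p_adj_max:
                direction = "down" if fc < 1 else ("up" if fc > 1 else "ns")
            else:
                direction = "ns"
            rows.append({"gene_id": g, "fold_change": fc, "p_adj": p, "direction": direction, "in_expr": True})
        else:
            rows.append({"gene_id": g, "fold_change": np.nan, "p_adj": np.nan, "direction": "missing", "in_expr": False})
    return pd.DataFrame(rows, columns=["gene_id", "fold_change", "p_adj", "direction", "in_expr"])


def read_rrbs(path: str | Path) -> list[CpGMethRecord]:
    """Read RRBS records from TSV: chrom, pos, coverage, beta."""
    table = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        CpGMethRecord(GenomePosition(str(c), int(p)), int(cov), float(b))
        for c, p, cov, b in zip(table["chrom"], table["pos"], table["coverage"], table["beta"])
    ]


def write_rrbs(records: Sequence[CpGMethRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "chrom": [r.position.chrom for r in records],
            "pos": [r.position.pos for r in records],
            "coverage": [r.coverage for r in records],
            "beta": [r.beta for r in records],
        }
    ).to_csv(path, sep="\t", index=False)
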