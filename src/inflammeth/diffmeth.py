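"""Per-probe differential methylation between case and control groups.

The effect size is the beta-value difference Δβ = mean(case) − mean(control);
significance is a two-sided Welch t-test per probe (a Wilcoxon rank-sum
variant is selectable), corrected across all tested probes by
Benjamini–Hochberg. A probe is called hypermethylated when q < 0.05 and
Δβ > 0.15, hypomethylated when q < 0.05 and Δβ < −0.15 (strict inequalities);
otherwise it is unchanged.

The primary surface is the :class:`DifferentialMethylation` estimator
(scikit-learn conventions: ``fit(X, y)``, fitted attributes with a trailing
underscore); the module-level functions are thin wrappers kept for scripting.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

__all__ = [
    "Thresholds",
    "DifferentialMethylation",
    "delta_beta",
    "test_probe",
    "adjust_fdr",
    "classify_probes",
    "magnitude_summary",
    "read_beta_matrix",
]

CASE, CONTROL = "case", "control"


@dataclass(frozen=True)
class Thresholds:
    """Significance cut-offs for calling a probe differential.

    q_max: maximum FDR-adjusted p-value (default 0.05).
    delta_min: minimum |Δβ| (default 0.15). Both strict.
    """

    q_max: float = 0.05
    delta_min: float = 0.15

    def __post_init__(self) -> None:
        if not (0 < self.q_max < 1):
            raise ValueError(f"q_max must be in (0,1), got {self.q_max}")
        if not (0 < self.delta_min < 1):
            raise ValueError(f"delta_min must be in (0,1), got {self.delta_min}")


def _clean(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    v = v[~np.isnan(v)]
    if v.size and (v.min() < 0 or v.max() > 1):
        raise ValueError("beta values must lie in [0, 1]")
    return v


def delta_beta(case_betas, control_betas) -> float:
    """Mean beta difference, case minus control; missing values dropped per group."""
    case = _clean(case_betas)
    control = _clean(control_betas)
    if case.size == 0 or control.size == 0:
        raise ValueError("empty group after missing-value removal")
    return float(case.mean() - control.mean())


def test_probe(case_betas, control_betas, test: str = "welch") -> tuple[float, float]:
    """Two-sided per-probe test; returns (statistic, p).

    Degenerate zero-variance inputs follow fixed conventions: both groups
    constant and equal -> p = 1; constant and different -> p = 0.
    """
    case = _clean(case_betas)
    control = _clean(control_betas)
    if case.size < 2 or control.size < 2:
        raise ValueError("need >= 2 observations per group")
    if np.ptp(case) == 0 and np.ptp(control) == 0:
        equal = case[0] == control[0]
        return (0.0, 1.0) if equal else (np.inf * np.sign(case[0] - control[0]), 0.0)
    if test == "welch":
        stat, p = stats.ttest_ind(case, control, equal_var=False)
    elif test == "wilcoxon":
        stat, p = stats.ranksums(case, control)
    else:
        raise ValueError(f"unknown test {test!r}; use 'welch' or 'wilcoxon'")
    return float(stat), float(p)


def adjust_fdr(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values (order-preserving)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_probes(records: pd.DataFrame, thresholds: Thresholds = Thresholds()) -> pd.DataFrame:
    """Label each probe hyper / hypo / unchanged from its q and delta_beta.

    hyper: q < q_max and Δβ > delta_min; hypo: q < q_max and Δβ < −delta_min;
    strict inequalities on both sides.
    """
    out = records.copy()
    q = out["q"].to_numpy(dtype=float)
    d = out["delta_beta"].to_numpy(dtype=float)
    label = np.full(len(out), "unchanged", dtype=object)
    label[(q < thresholds.q_max) & (d > thresholds.delta_min)] = "hyper"
    label[(q < thresholds.q_max) & (d < -thresholds.delta_min)] = "hypo"
    out["label"] = label
    return out


def magnitude_summary(deltas_cohort_a, deltas_cohort_b) -> pd.DataFrame:
    """Five-number summaries of |effect| distributions for two cohorts.

    Used to compare the magnitude of differential methylation on a shared
    probe subset (e.g. inflamed-vs-healthy against tumor-vs-normal).
    """
    rows = {}
    for name, v in (("A", deltas_cohort_a), ("B", deltas_cohort_b)):
        v = np.asarray(v, dtype=float)
        if v.size == 0:
            raise ValueError(f"cohort {name}: empty vector")
        q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])
        rows[name] = {
            "min": float(v.min()),
            "q1": float(q1),
            "median": float(med),
            "q3": float(q3),
            "max": float(v.max()),
            "n": int(v.size),
        }
    return pd.DataFrame(rows).T


class DifferentialMethylation(BaseEstimator):
    """Per-probe case/control differential methylation caller.

    Parameters
    ----------
    test : {'welch', 'wilcoxon'}
        Per-probe two-sided test on beta values.
    q_max, delta_min : float
        Calling thresholds (FDR q and |Δβ|), both strict.
    min_group_size : int
        Probes with fewer observed values in either group are excluded
        from testing (reported with NaN statistics, label 'unchanged').

    Attributes
    ----------
    results_ : pd.DataFrame
        Columns probe_id, delta_beta, p, q, label.
    counts_ : dict
        {'hyper': int, 'hypo': int, 'unchanged': int}.
    """

    def __init__(
        self,
        test: str = "welch",
        q_max: float = 0.05,
        delta_min: float = 0.15,
        min_group_size: int = 2,
    ):
        self.test = test
        self.q_max = q_max
        self.delta_min = delta_min
        self.min_group_size = min_group_size

    def fit(self, X: pd.DataFrame, y: Sequence[str]):
        """Fit on a probes × samples beta matrix.

        X: DataFrame indexed by probe_id, one column per sample, betas in
        [0,1] (NaN = missing). y: per-sample group labels, 'case'/'control',
        aligned with X's columns.
        """
        thresholds = Thresholds(self.q_max, self.delta_min)
        y = np.asarray(y, dtype=object)
        if len(y) != X.shape[1]:
            raise ValueError("y must have one label per sample column")
        bad = set(y) - {CASE, CONTROL}
        if bad:
            raise ValueError(f"labels must be 'case'/'control', got extras {sorted(bad)}")
        case_m = X.loc[:, y == CASE].to_numpy(dtype=float)
        ctrl_m = X.loc[:, y == CONTROL].to_numpy(dtype=float)
        if case_m.shape[1] < self.min_group_size or ctrl_m.shape[1] < self.min_group_size:
            raise ValueError("need >= min_group_size samples per group")
        for m in (case_m, ctrl_m):
            vals = m[~np.isnan(m)]
            if vals.size and (vals.min() < 0 or vals.max() > 1):
                raise ValueError("beta values must lie in [0, 1]")

        n_case = np.sum(~np.isnan(case_m), axis=1)
        n_ctrl = np.sum(~np.isnan(ctrl_m), axis=1)
        testable = (n_case >= self.min_group_size) & (n_ctrl >= self.min_group_size)

        delta = np.full(X.shape[0], np.nan)
        delta[testable] = np.nanmean(case_m[testable], axis=1) - np.nanmean(ctrl_m[testable], axis=1)

        p = np.full(X.shape[0], np.nan)
        if self.test == "welch":
            with np.errstate(invalid="ignore", divide="ignore"):
                res = stats.ttest_ind(
                    case_m[testable], ctrl_m[testable], axis=1, equal_var=False, nan_policy="omit"
                )
            pt = np.asarray(res.pvalue, dtype=float)
            # zero-variance conventions: equal constants -> 1, separated -> 0
            degen = np.isnan(pt)
            if degen.any():
                dsub = np.where(degen)[0]
                pt[dsub] = np.where(np.abs(delta[testable][dsub]) > 0, 0.0, 1.0)
            p[testable] = pt
        elif self.test == "wilcoxon":
            idx = np.where(testable)[0]
            for i in idx:
                p[i] = test_probe(case_m[i], ctrl_m[i], test="wilcoxon")[1]
        else:
            raise ValueError(f"unknown test {self.test!r}")

        q = np.full(X.shape[0], np.nan)
        q[testable] = adjust_fdr(p[testable])

        results = pd.DataFrame(
            {"probe_id": X.index.astype(str), "delta_beta": delta, "p": p, "q": q}
        )
        results.loc[~testable, ["delta_beta", "p", "q"]] = np.nan
        results = classify_probes(
            results.fillna({"q": 1.0, "delta_beta": 0.0}), thresholds
        ).assign(delta_beta=delta, p=p, q=q)
        self.results_ = results.reset_index(drop=True)
        self.counts_ = self.results_["label"].value_counts().reindex(
            ["hyper", "hypo", "unchanged"], fill_value=0
        ).to_dict()
        self.n_tested_ = int(testable.sum())
        return self

    def probe_sets(self) -> dict[str, list[str]]:
        """Hyper / hypo probe-id sets from the fitted results."""
        r = self.results_
        return {
            "hyper": r.loc[r["label"] == "hyper", "probe_id"].tolist(),
            "hypo": r.loc[r["label"] == "hypo", "probe_id"].tolist(),
        }

    def volcano_data(self) -> pd.DataFrame:
        """Δβ and −log10 q per probe, for volcano plots."""
        r = self.results_
        with np.errstate(divide="ignore"):
            neg_log_q = -np.log10(r["q"].to_numpy(dtype=float))
        return pd.DataFrame(
            {"probe_id": r["probe_id"], "delta_beta": r["delta_beta"], "neg_log10_q": neg_log_q}
        )


def read_beta_matrix(
    betas_path: str | Path, samples_path: str | Path
) -> tuple[pd.DataFrame, np.ndarray]:
    """Load a beta TSV (rows probes, columns samples) plus a sample sheet.

    The sample sheet has columns sample_id, group; returns (X, y) aligned for
    :meth:`DifferentialMethylation.fit`.
    """
    X = pd.read_csv(betas_path, sep="\t", index_col=0)
    sheet = pd.read_csv(samples_path, sep="\t", dtype=str)
    groups = sheet.set_index("sample_id")["group"]
    missing = [s for s in X.columns if s not in groups.index]
    if missing:
        raise ValueError(f"samples missing from sample sheet, e.g. {missing[:3]}")
    y = groups.loc[X.columns].to_numpy()
    return X, y
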