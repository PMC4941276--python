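"""Permutation enrichment of probe sets at genomic feature sets.

For a differential probe set of size k, the null is built by repeatedly
drawing k distinct probes uniformly without replacement from the full array
manifest and counting how many fall inside the feature set. Enrichment is
summarized by a Z-score against the permutation null and an add-one
empirical p-value (never exactly 0):

    z     = (observed − mean(null)) / sd(null)
    p_emp = (1 + #{null >= observed}) / (n_perm + 1)     (enrichment)
            (1 + #{null <= observed}) / (n_perm + 1)     (depletion)
            min(1, 2·min(the two one-sided p's)) for two_sided

The background is the whole manifest (plain array permutation); replicates
are independent and each feature set gets its own RNG stream (seed + index)
so multi-feature reports are reproducible regardless of evaluation order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .genomic_core import FeatureSet, ProbeManifest

__all__ = [
    "PermutationConfig",
    "EnrichmentResult",
    "PermutationEnrichment",
    "observed_overlap",
    "permutation_null",
    "enrichment_z",
    "enrich_report",
]

#: Empirical-p threshold below which a direction (enriched/depleted) is called.
SIGNIFICANCE_ALPHA = 0.05


@dataclass(frozen=True)
class PermutationConfig:
    n_perm: int = 1000
    seed: int = 0
    alternative: str = "enrichment"  # enrichment | depletion | two_sided

    def __post_init__(self) -> None:
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        if self.alternative not in ("enrichment", "depletion", "two_sided"):
            raise ValueError(f"unknown alternative {self.alternative!r}")


@dataclass(frozen=True)
class EnrichmentResult:
    feature_name: str
    observed: int
    null_mean: float
    null_sd: float
    z: float
    p_emp: float
    direction: str  # enriched | depleted | none
    degenerate_null: bool = False


def _overlap_mask(manifest: ProbeManifest, features: FeatureSet) -> np.ndarray:
    """Boolean per-manifest-probe overlap vector, in manifest row order."""
    chroms = manifest.table["chrom"].to_numpy()
    poss = manifest.table["pos"].to_numpy()
    return np.fromiter(
        (features.overlaps((c, int(p))) for c, p in zip(chroms, poss)),
        dtype=bool,
        count=len(manifest),
    )


def observed_overlap(
    probes: Sequence[str], manifest: ProbeManifest, features: FeatureSet
) -> int:
    """Number of probes whose CpG position falls inside >= 1 feature interval."""
    sub = manifest.positions(list(probes))  # raises on unknown ids
    return int(
        sum(features.overlaps((c, int(p))) for c, p in zip(sub["chrom"], sub["pos"]))
    )


def permutation_null(
    k: int,
    manifest: ProbeManifest,
    features: FeatureSet,
    config: PermutationConfig,
    _mask: np.ndarray | None = None,
) -> np.ndarray:
    """n_perm overlap counts of random k-probe draws from the full manifest."""
    n = len(manifest)
    if k > n:
        raise ValueError(f"k ({k}) exceeds manifest size ({n})")
    mask = _overlap_mask(manifest, features) if _mask is None else _mask
    rng = np.random.default_rng(config.seed)
    if k == 0:
        return np.zeros(config.n_perm, dtype=np.int64)
    # Gumbel-top-k style draw: argpartition of uniform keys picks k distinct
    # probes uniformly without replacement, vectorized across replicates.
    keys = rng.random((config.n_perm, n))
    picked = np.argpartition(keys, k - 1, axis=1)[:, :k]
    return mask[picked].sum(axis=1).astype(np.int64)


def enrichment_z(
    observed: int,
    null_counts: np.ndarray,
    feature_name: str = "",
    alternative: str = "enrichment",
    alpha: float = SIGNIFICANCE_ALPHA,
) -> EnrichmentResult:
    """Z-score and add-one empirical p of an observed count against its null."""
    null_counts = np.asarray(null_counts)
    n_perm = null_counts.size
    if n_perm < 100:
        raise ValueError("need >= 100 null replicates")
    mean = float(null_counts.mean())
    sd = float(null_counts.std(ddof=1))
    p_ge = (1 + int(np.sum(null_counts >= observed))) / (n_perm + 1)
    p_le = (1 + int(np.sum(null_counts <= observed))) / (n_perm + 1)
    if alternative == "enrichment":
        p_emp = p_ge
    elif alternative == "depletion":
        p_emp = p_le
    elif alternative == "two_sided":
        p_emp = min(1.0, 2.0 * min(p_ge, p_le))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    if sd == 0.0:
        return EnrichmentResult(
            feature_name, int(observed), mean, 0.0, float("nan"), p_emp, "none", True
        )
    z = (observed - mean) / sd
    direction = "none"
    if p_emp < alpha and z > 0:
        direction = "enriched"
    elif p_emp < alpha and z < 0:
        direction = "depleted"
    return EnrichmentResult(feature_name, int(observed), mean, sd, float(z), p_emp, direction)


class PermutationEnrichment(BaseEstimator):
    """Enrichment/depletion of probe sets at feature sets vs array permutation.

    Parameters follow :class:`PermutationConfig`; ``fit`` takes the probe sets
    and feature sets and leaves a tidy results table in ``results_``.
    """

    def __init__(self, n_perm: int = 1000, seed: int = 0, alternative: str = "two_sided"):
        self.n_perm = n_perm
        self.seed = seed
        self.alternative = alternative

    def fit(
        self,
        probe_sets: Mapping[str, Sequence[str]],
        manifest: ProbeManifest,
        feature_sets: Sequence[FeatureSet],
    ):
        rows = []
        for f_idx, features in enumerate(feature_sets):
            # one RNG stream per feature set: reproducible under reordering
            cfg = PermutationConfig(self.n_perm, self.seed + f_idx, self.alternative)
            mask = _overlap_mask(manifest, features)
            for set_name, probes in probe_sets.items():
                probes = list(probes)
                obs = observed_overlap(probes, manifest, features)
                null = permutation_null(len(probes), manifest, features, cfg, _mask=mask)
                res = enrichment_z(obs, null, features.name, self.alternative)
                rows.append(
                    {
                        "probe_set": set_name,
                        "feature": features.name,
                        "set_size": len(probes),
                        "observed": res.observed,
                        "null_mean": res.null_mean,
                        "null_sd": res.null_sd,
                        "z": res.z,
                        "p_emp": res.p_emp,
                        "direction": res.direction,
                    }
                )
        self.results_ = pd.DataFrame(rows)
        return self


def enrich_report(
    probe_sets: Mapping[str, Sequence[str]],
    feature_sets: Sequence[FeatureSet],
    manifest: ProbeManifest,
    config: PermutationConfig = PermutationConfig(),
) -> pd.DataFrame:
    """One EnrichmentResult row per (probe set × feature set); deterministic by seed."""
    est = PermutationEnrichment(config.n_perm, config.seed, config.alternative)
    return est.fit(probe_sets, manifest, feature_sets).results_
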