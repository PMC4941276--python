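"""Putative-enhancer calling and enhancer→target-gene linking.

Putative enhancers are DNase I hypersensitive sites (DHS) with zero
base-pair overlap with the promoter mark H3K4me3. An enhancer that contains
at least one hypermethylated CpG is a "hypermethylated enhancer". Targets
are found by correlating the enhancer's DHS signal with every other DHS
within ±500 kb across a panel of cell lines; pairs with r² ≥ 0.7 are kept,
and a target DHS is assigned to a gene when its midpoint lies within
±2.5 kb of that gene's TSS (nearest TSS wins; ties broken by gene_id).

Distances are midpoint-to-midpoint. Correlation uses raw signal by default;
``log1p=True`` applies log(1+x) first, useful for heavy-tailed signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .genomic_core import FeatureSet, GeneModel, Interval, ProbeManifest

__all__ = [
    "LinkConfig",
    "EnhancerLink",
    "SignalMatrix",
    "EnhancerLinker",
    "call_putative_enhancers",
    "hypermethylated_enhancers",
    "pearson_r",
    "link_enhancer_targets",
    "read_signal_matrix",
    "write_links",
]


@dataclass(frozen=True)
class LinkConfig:
    """Linking parameters: ±window around the enhancer, r² floor, promoter half-width."""

    window: int = 500_000
    r2_min: float = 0.7
    promoter_halfwidth: int = 2_500
    log1p: bool = False

    def __post_init__(self) -> None:
        if self.window <= 0 or self.r2_min <= 0 or self.promoter_halfwidth <= 0:
            raise ValueError("window, r2_min and promoter_halfwidth must be positive")


@dataclass(frozen=True)
class EnhancerLink:
    enhancer: Interval
    target_dhs: Interval
    r: float
    r2: float
    distance: float  # bp between midpoints
    gene_id: str | None


class SignalMatrix:
    """DHS signal intensities: one row per site interval, one column per cell line."""

    def __init__(self, sites: Sequence[Interval | tuple], cell_lines: Sequence[str], values):
        self.sites = [Interval(*s).validate() for s in sites]
        self.cell_lines = list(cell_lines)
        self.values = np.asarray(values, dtype=float)
        if self.values.shape != (len(self.sites), len(self.cell_lines)):
            raise ValueError("values shape must be (n_sites, n_cell_lines)")
        if np.any(self.values < 0):
            raise ValueError("signal intensities must be non-negative")

    @property
    def n_cell_lines(self) -> int:
        return len(self.cell_lines)

    def __len__(self) -> int:
        return len(self.sites)


def call_putative_enhancers(dhs: FeatureSet, h3k4me3: FeatureSet) -> FeatureSet:
    """DHS intervals with zero bp overlap with any H3K4me3 interval."""
    kept = [iv for iv in dhs.intervals if not h3k4me3.overlaps_interval(iv)]
    return FeatureSet("putative_enhancers", kept)


def hypermethylated_enhancers(
    enhancers: FeatureSet, hyper_probes: Sequence[str], manifest: ProbeManifest
) -> FeatureSet:
    """Enhancers containing >= 1 hypermethylated probe position (each kept once)."""
    sub = manifest.positions(list(hyper_probes))
    probe_pts = FeatureSet(
        "hyper_probes",
        [(c, int(p), int(p) + 1) for c, p in zip(sub["chrom"], sub["pos"])],
    )
    kept = [iv for iv in enhancers.intervals if probe_pts.overlaps_interval(iv)]
    return FeatureSet("hypermethylated_enhancers", kept)


def pearson_r(x, y) -> float | None:
    """Pearson product-moment correlation; None when either vector is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("vectors must share length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        return None
    return float(np.corrcoef(x, y)[0, 1])


def _match_anchor_site(anchor: Interval, signal: SignalMatrix) -> int:
    """Index of the signal-matrix site overlapping the anchor (greatest bp overlap)."""
    best, best_ov = None, 0
    for i, s in enumerate(signal.sites):
        if s.chrom != anchor.chrom:
            continue
        ov = min(s.end, anchor.end) - max(s.start, anchor.start)
        if ov > 0 and ov > best_ov:
            best, best_ov = i, ov
    if best is None:
        raise ValueError(f"anchor {anchor} matches no site in the signal matrix")
    return best


def _assign_gene(
    midpoint: float, chrom: str, genes: Sequence[GeneModel], halfwidth: int
) -> str | None:
    """Nearest gene whose TSS lies within ±halfwidth of the midpoint; ties by gene_id."""
    best: tuple[float, str] | None = None
    for g in genes:
        if g.chrom != chrom:
            continue
        d = abs(midpoint - g.tss)
        if d <= halfwidth and (best is None or (d, g.gene_id) < best):
            best = (d, g.gene_id)
    return None if best is None else best[1]


def link_enhancer_targets(
    anchor: Interval,
    signal: SignalMatrix,
    genes: Sequence[GeneModel],
    config: LinkConfig = LinkConfig(),
) -> list[EnhancerLink]:
    """Correlation-supported links from one enhancer to surrounding DHS.

    Candidates are same-chromosome sites with midpoint within ±window of the
    anchor midpoint (the anchor itself excluded). Links with r² >= r2_min are
    emitted, sorted by descending r²; each gets a gene when its midpoint is
    within ±promoter_halfwidth of a TSS.
    """
    anchor = Interval(*anchor).validate()
    a_idx = _match_anchor_site(anchor, signal)
    values = np.log1p(signal.values) if config.log1p else signal.values
    a_sig = values[a_idx]
    a_mid = signal.sites[a_idx].midpoint
    links: list[EnhancerLink] = []
    for i, site in enumerate(signal.sites):
        if i == a_idx or site.chrom != anchor.chrom:
            continue
        dist = abs(site.midpoint - a_mid)
        if dist > config.window:
            continue
        r = pearson_r(a_sig, values[i])
        if r is None:
            continue  # constant signal: correlation undefined, pair excluded
        r2 = r * r
        if r2 < config.r2_min:
            continue
        gene = _assign_gene(site.midpoint, site.chrom, genes, config.promoter_halfwidth)
        links.append(EnhancerLink(anchor, site, r, r2, dist, gene))
    links.sort(key=lambda l: (-l.r2, l.target_dhs.start))
    return links


class EnhancerLinker(BaseEstimator):
    """Enhancer→DHS→gene linker over a set of anchor enhancers.

    ``fit`` computes links for every anchor and stores a tidy table in
    ``links_`` (one row per emitted link).
    """

    def __init__(
        self,
        window: int = 500_000,
        r2_min: float = 0.7,
        promoter_halfwidth: int = 2_500,
        log1p: bool = False,
    ):
        self.window = window
        self.r2_min = r2_min
        self.promoter_halfwidth = promoter_halfwidth
        self.log1p = log1p

    def fit(
        self,
        anchors: FeatureSet | Sequence[Interval],
        signal: SignalMatrix,
        genes: Sequence[GeneModel] = (),
    ):
        config = LinkConfig(self.window, self.r2_min, self.promoter_halfwidth, self.log1p)
        anchor_list = anchors.intervals if isinstance(anchors, FeatureSet) else list(anchors)
        rows = []
        for anchor in anchor_list:
            for link in link_enhancer_targets(Interval(*anchor), signal, genes, config):
                rows.append(
                    {
                        "enh_chrom": link.enhancer.chrom,
                        "enh_start": link.enhancer.start,
                        "enh_end": link.enhancer.end,
                        "dhs_chrom": link.target_dhs.chrom,
                        "dhs_start": link.target_dhs.start,
                        "dhs_end": link.target_dhs.end,
                        "r": link.r,
                        "r2": link.r2,
                        "distance": link.distance,
                        "gene_id": link.gene_id,
                    }
                )
        self.links_ = pd.DataFrame(
            rows,
            columns=[
                "enh_chrom", "enh_start", "enh_end",
                "dhs_chrom", "dhs_start", "dhs_end",
                "r", "r2", "distance", "gene_id",
            ],
        )
        self.target_genes_ = sorted(self.links_["gene_id"].dropna().unique().tolist())
        return self


def read_signal_matrix(path: str | Path) -> SignalMatrix:
    """Read a signal TSV: columns chrom, start, end, then one column per cell line."""
    table = pd.read_csv(path, sep="\t")
    sites = [
        Interval(str(c), int(s), int(e))
        for c, s, e in zip(table["chrom"], table["start"], table["end"])
    ]
    cell_lines = [c for c in table.columns if c not in ("chrom", "start", "end")]
    return SignalMatrix(sites, cell_lines, table[cell_lines].to_numpy(dtype=float))


def write_signal_matrix(signal: SignalMatrix, path: str | Path) -> None:
    coords = pd.DataFrame(
        {
            "chrom": [s.chrom for s in signal.sites],
            "start": [s.start for s in signal.sites],
            "end": [s.end for s in signal.sites],
        }
    )
    sig = pd.DataFrame(signal.values, columns=signal.cell_lines)
    pd.concat([coords, sig], axis=1).to_csv(path, sep="\t", index=False)


def write_links(links: pd.DataFrame, path: str | Path) -> None:
    links.to_csv(path, sep="\t", index=False)
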