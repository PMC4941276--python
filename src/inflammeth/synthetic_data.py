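"""Synthetic inputs with planted ground truth for every pipeline stage.

The generator emulates the statistical structure of the study design it is
modelled on: a 450K-style beta-value matrix for inflamed (n=19) vs healthy
(n=23) tissue with Beta-distributed noise and planted group effects; peak
sets with planted over-representation among the hyper probes; DHS signal
across ~100 cell lines with planted enhancer-promoter pairs sharing latent
activity (true r ≈ 0.9); and RRBS-style CpG records whose methylation is
suppressed inside binding peaks (mutual exclusivity).

Planted hypermethylated probes draw their baseline from the low-methylation
mode and hypomethylated probes from the high mode: regulatory elements that
gain methylation in disease start out unmethylated in healthy tissue, and
this also keeps the planted effect size honest (little clipping at the
[0,1] boundary). Everything is deterministic given ``SyntheticConfig.seed``;
each generator consumes an independent, named RNG stream derived from it.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .enhancer_link import SignalMatrix, write_signal_matrix
from .genomic_core import (
    FeatureSet,
    GeneModel,
    GenomePosition,
    Interval,
    ProbeManifest,
    write_feature_bed,
    write_gene_models,
    write_manifest,
)
from .methyl_context_stats import CpGMethRecord, write_rrbs

__all__ = [
    "SyntheticConfig",
    "TruthSet",
    "SyntheticBundle",
    "gen_manifest",
    "select_planted_probes",
    "gen_beta_matrix",
    "gen_feature_sets",
    "gen_dhs_signal",
    "gen_binding_peaks",
    "gen_rrbs",
    "gen_expression",
    "generate_bundle",
    "write_bundle",
]

# stream tags keep the per-generator RNGs independent under one seed
_STREAMS = {
    "manifest": 1, "plant": 2, "betas": 3, "features": 4,
    "signal": 5, "rrbs": 6, "expression": 7,
}


def _rng(config: "SyntheticConfig", stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((config.seed, _STREAMS[stream])))


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design parameters of the synthetic cohort.

    Sample sizes default to the emulated cohort (19 inflamed vs 23 healthy);
    planted effect |Δβ| = 0.25 with Beta noise of concentration 50 (per-value
    sd ≈ 0.06-0.07); one enriched feature set covering planted hyper probes
    at base_rate × enrichment_fold; 50 planted enhancer-promoter pairs with
    true signal correlation ≈ link_true_r across 100 cell lines plus 500
    independent decoy DHS; RRBS with full methylation/occupancy exclusivity.
    """

    seed: int = 0
    # array / methylation
    n_probes: int = 10_000
    genome_length: int = 10_000_000
    n_case: int = 19
    n_control: int = 23
    frac_hyper: float = 0.05
    frac_hypo: float = 0.05
    effect_delta: float = 0.25
    beta_concentration: float = 50.0
    # annotation scaffold
    n_cgis: int = 200
    cgi_length: int = 1_000
    n_genes: int = 100
    gene_length: int = 20_000
    # feature sets
    feature_base_rate: float = 0.10
    enrichment_fold: float = 5.0
    n_enriched_features: int = 1
    n_null_features: int = 1
    feature_halfwidth: int = 100
    # enhancer linking
    n_cell_lines: int = 100
    n_planted_links: int = 50
    n_decoy_dhs: int = 500
    link_true_r: float = 0.9
    link_window: int = 500_000
    # RRBS
    n_rrbs: int = 12_000
    n_binding_peaks: int = 500
    binding_peak_length: int = 400
    frac_in_peaks: float = 0.5
    exclusivity_strength: float = 1.0
    frac_low_coverage: float = 0.2
    # expression
    down_fold_change: float = 0.5

    def __post_init__(self) -> None:
        for name in ("frac_hyper", "frac_hypo", "feature_base_rate", "frac_in_peaks",
                     "frac_low_coverage"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if not (0.0 < self.effect_delta < 1.0):
            raise ValueError("effect_delta must be in (0,1)")
        if not (0.0 <= self.exclusivity_strength <= 1.0):
            raise ValueError("exclusivity_strength must be in [0,1]")
        for name in ("n_probes", "genome_length", "n_case", "n_control", "n_cell_lines"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_probes > self.genome_length:
            raise ValueError("n_probes exceeds genome_length")
        if self.feature_base_rate * self.enrichment_fold > 1.0:
            raise ValueError("feature_base_rate * enrichment_fold exceeds 1")


@dataclass
class TruthSet:
    """Planted ground truth, used for recovery testing of every stage."""

    planted_hyper_probe_ids: list[str] = field(default_factory=list)
    planted_hypo_probe_ids: list[str] = field(default_factory=list)
    planted_enriched_feature_names: list[str] = field(default_factory=list)
    planted_links: list[dict] = field(default_factory=list)
    planted_downregulated_genes: list[str] = field(default_factory=list)

    def validate(self) -> "TruthSet":
        if set(self.planted_hyper_probe_ids) & set(self.planted_hypo_probe_ids):
            raise ValueError("hyper and hypo planted sets must be disjoint")
        return self

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthSet":
        with open(path) as fh:
            return cls(**json.load(fh)).validate()


CHROM_ARRAY = "chrS"  # synthetic array chromosome
CHROM_LINK = "chrL"  # enhancer-linking chromosome
CHROM_RRBS = "chrR"  # RRBS chromosome


def gen_manifest(
    config: SyntheticConfig,
) -> tuple[ProbeManifest, FeatureSet, list[GeneModel]]:
    """Probe manifest plus CGI set and gene models on one synthetic chromosome.

    CGIs are seeded so that island, shore, shelf and open-sea probes all
    exist; genes are long enough that promoter, exon, intron and intergenic
    probes all exist. Raises if any context class comes out empty.
    """
    rng = _rng(config, "manifest")
    positions = np.sort(rng.choice(config.genome_length, size=config.n_probes, replace=False))
    probe_ids = [f"cg{i:06d}" for i in range(config.n_probes)]
    manifest = ProbeManifest(
        pd.DataFrame({"probe_id": probe_ids, "chrom": CHROM_ARRAY, "pos": positions})
    )

    # CGI placement: a third of the islands sit directly on a probe, a third
    # 1 kb to its right (shore band), a third 3 kb (shelf band); this pins
    # every class without relying on chance at small n.
    half = config.cgi_length // 2
    anchor_probes = rng.choice(config.n_probes, size=min(config.n_cgis, config.n_probes), replace=False)
    cgi_intervals = []
    for j, pi in enumerate(anchor_probes):
        p = int(positions[pi])
        offset = (-half, 1_000, 3_000)[j % 3]
        start = max(0, p + offset)
        end = min(config.genome_length, start + config.cgi_length)
        if start < end:
            cgi_intervals.append((CHROM_ARRAY, start, end))
    cgis = FeatureSet("cgi", cgi_intervals)

    genes = []
    gene_starts = rng.choice(
        max(1, config.genome_length - config.gene_length), size=config.n_genes, replace=False
    )
    L = config.gene_length
    for gi, s in enumerate(np.sort(gene_starts)):
        s = int(s)
        strand = "+" if gi % 2 == 0 else "-"
        exons = [(s, s + L // 10), (s + L // 2, s + L // 2 + L // 10), (s + L - L // 10, s + L)]
        tss = s if strand == "+" else s + L - 1
        genes.append(GeneModel(f"gene{gi:04d}", CHROM_ARRAY, strand, tss, exons))

    table = manifest.annotate(cgis, genes)
    for col, classes in (("cgi_context", 4), ("gene_context", 4)):
        if table[col].nunique() < classes:
            raise ValueError(
                f"synthetic layout left a {col} class empty; increase n_probes/n_cgis/n_genes"
            )
    return manifest, cgis, genes


def select_planted_probes(manifest: ProbeManifest, config: SyntheticConfig) -> TruthSet:
    """Choose disjoint hyper/hypo probe sets uniformly from the manifest."""
    rng = _rng(config, "plant")
    n_hyper = int(round(config.frac_hyper * len(manifest)))
    n_hypo = int(round(config.frac_hypo * len(manifest)))
    picked = rng.choice(len(manifest), size=n_hyper + n_hypo, replace=False)
    ids = manifest.probe_ids.to_numpy()
    return TruthSet(
        planted_hyper_probe_ids=sorted(ids[picked[:n_hyper]].tolist()),
        planted_hypo_probe_ids=sorted(ids[picked[n_hyper:]].tolist()),
    ).validate()


# Beta mixture for per-probe baseline means: most CpGs are either lowly or
# highly methylated (bimodal), as on real arrays.
_LOW_MODE = (2.0, 10.0)
_HIGH_MODE = (10.0, 2.0)
_MEAN_CLIP = (0.02, 0.98)  # keeps Beta shape parameters strictly positive


def gen_beta_matrix(
    manifest: ProbeManifest, truth: TruthSet, config: SyntheticConfig
) -> tuple[pd.DataFrame, np.ndarray, int]:
    """Probes × samples beta matrix with planted group effects.

    Returns (X, y, n_clipped): X indexed by probe_id with randomized sample
    column order, y the aligned case/control labels, n_clipped the number of
    planted probes whose shifted mean hit the [0,1] clip.
    """
    rng = _rng(config, "betas")
    n = len(manifest)
    ids = manifest.probe_ids.to_numpy()
    hyper = np.isin(ids, truth.planted_hyper_probe_ids)
    hypo = np.isin(ids, truth.planted_hypo_probe_ids)

    low = rng.beta(*_LOW_MODE, size=n)
    high = rng.beta(*_HIGH_MODE, size=n)
    pick_high = rng.random(n) < 0.5
    baseline = np.where(pick_high, high, low)
    baseline[hyper] = low[hyper]  # hyper probes start unmethylated
    baseline[hypo] = high[hypo]  # hypo probes start methylated

    control_mean = np.clip(baseline, *_MEAN_CLIP)
    shifted = baseline + config.effect_delta * (hyper.astype(float) - hypo.astype(float))
    case_mean = np.clip(shifted, *_MEAN_CLIP)
    n_clipped = int(np.sum((hyper | hypo) & ((shifted < _MEAN_CLIP[0]) | (shifted > _MEAN_CLIP[1]))))

    c = config.beta_concentration
    n_case, n_ctrl = config.n_case, config.n_control
    case_vals = rng.beta(case_mean[:, None] * c, (1 - case_mean[:, None]) * c, size=(n, n_case))
    ctrl_vals = rng.beta(control_mean[:, None] * c, (1 - control_mean[:, None]) * c, size=(n, n_ctrl))

    sample_ids = [f"case{i:03d}" for i in range(n_case)] + [f"ctrl{i:03d}" for i in range(n_ctrl)]
    labels = np.array(["case"] * n_case + ["control"] * n_ctrl, dtype=object)
    values = np.hstack([case_vals, ctrl_vals])
    order = rng.permutation(n_case + n_ctrl)
    X = pd.DataFrame(values[:, order], index=pd.Index(ids, name="probe_id"),
                     columns=np.array(sample_ids)[order])
    return X, labels[order], n_clipped


def gen_feature_sets(
    manifest: ProbeManifest, truth: TruthSet, config: SyntheticConfig
) -> list[FeatureSet]:
    """Feature sets with (enriched) and without (null) planted over-representation.

    An enriched set covers background probes at ``feature_base_rate`` but
    planted-hyper probes at rate × enrichment_fold; null sets cover every
    probe at the base rate. Within a set, probe-centred intervals are merged,
    so each set is non-overlapping. Enriched set names are recorded in the
    truth set.
    """
    rng = _rng(config, "features")
    ids = manifest.probe_ids.to_numpy()
    positions = manifest.table["pos"].to_numpy()
    hyper = np.isin(ids, truth.planted_hyper_probe_ids)
    hw = config.feature_halfwidth
    out = []

    order = np.argsort(positions)
    sorted_pos = positions[order]

    def build(name: str, cover_prob: np.ndarray) -> FeatureSet:
        covered = rng.random(len(ids)) < cover_prob
        cov_sorted = covered[order]
        merged: list[tuple[int, int]] = []
        for j in np.where(cov_sorted)[0]:
            p = int(sorted_pos[j])
            # clip at the neighbouring probes so the interval covers only the
            # selected probe; per-probe coverage then matches cover_prob exactly
            left = int(sorted_pos[j - 1]) + 1 if j > 0 else 0
            right = int(sorted_pos[j + 1]) if j + 1 < len(sorted_pos) else config.genome_length
            s = max(0, p - hw, left)
            e = min(p + hw + 1, right)
            if merged and s < merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        return FeatureSet(name, [(CHROM_ARRAY, s, e) for s, e in merged])

    base = config.feature_base_rate
    for i in range(config.n_enriched_features):
        prob = np.where(hyper, base * config.enrichment_fold, base)
        name = f"enriched_{i}"
        out.append(build(name, prob))
        if name not in truth.planted_enriched_feature_names:
            truth.planted_enriched_feature_names.append(name)
    for i in range(config.n_null_features):
        out.append(build(f"null_{i}", np.full(len(ids), base)))
    return out


def gen_dhs_signal(
    truth: TruthSet, config: SyntheticConfig
) -> tuple[SignalMatrix, list[GeneModel], FeatureSet]:
    """Cross-cell-line DHS signal with planted enhancer-promoter pairs.

    Each planted pair shares a Gamma-distributed latent activity per cell
    line plus independent noise calibrated so the true Pearson correlation is
    ``link_true_r``; decoy DHS have fully independent signal. Anchors are
    spaced so their ±window neighbourhoods do not overlap; each target DHS
    sits under the TSS of its target gene. Returns (signal, target gene
    models, anchor FeatureSet) and records links and down-regulated genes in
    the truth set.
    """
    rng = _rng(config, "signal")
    n_links = config.n_planted_links
    n_cells = config.n_cell_lines
    spacing = 2 * config.link_window + 200_000
    site_len = 200

    # noise variance that yields the requested true correlation for the
    # shared-latent model: r = var(L) / (var(L) + var(eps))
    lat_shape, lat_scale = 4.0, 1.0
    lat_var = lat_shape * lat_scale**2
    noise_var = lat_var * (1.0 - config.link_true_r) / config.link_true_r
    noise_shape = 4.0  # Gamma(shape, scale): var = shape * scale^2
    noise_scale = float(np.sqrt(noise_var / noise_shape))

    sites: list[Interval] = []
    values: list[np.ndarray] = []
    genes: list[GeneModel] = []
    anchors: list[Interval] = []

    def noise() -> np.ndarray:
        return rng.gamma(noise_shape, noise_scale, size=n_cells)

    decoys_per_anchor = int(np.ceil(config.n_decoy_dhs / max(1, n_links)))
    n_decoys_left = config.n_decoy_dhs
    for i in range(n_links):
        center = config.link_window + i * spacing
        anchor = Interval(CHROM_LINK, center, center + site_len)
        latent = rng.gamma(lat_shape, lat_scale, size=n_cells)
        sites.append(anchor)
        values.append(latent + noise())
        anchors.append(anchor)

        offset = int(rng.integers(50_000, config.link_window - 50_000)) * int(rng.choice([-1, 1]))
        t_start = center + offset
        target = Interval(CHROM_LINK, t_start, t_start + site_len)
        sites.append(target)
        values.append(latent + noise())
        gene_id = f"tgt{i:04d}"
        tss = int(target.midpoint)
        genes.append(GeneModel(gene_id, CHROM_LINK, "+", tss, [(tss, tss + 5_000)]))
        truth.planted_links.append(
            {
                "enhancer": [anchor.chrom, anchor.start, anchor.end],
                "target_dhs": [target.chrom, target.start, target.end],
                "gene_id": gene_id,
            }
        )
        if gene_id not in truth.planted_downregulated_genes:
            truth.planted_downregulated_genes.append(gene_id)

        for _ in range(min(decoys_per_anchor, n_decoys_left)):
            d_off = int(rng.integers(10_000, config.link_window - 10_000)) * int(rng.choice([-1, 1]))
            d_start = center + d_off
            sites.append(Interval(CHROM_LINK, d_start, d_start + site_len))
            values.append(rng.gamma(lat_shape, lat_scale, size=n_cells) + noise())
            n_decoys_left -= 1

    cell_lines = [f"cell{j:03d}" for j in range(n_cells)]
    signal = SignalMatrix(sites, cell_lines, np.vstack(values))
    return signal, genes, FeatureSet("planted_enhancers", anchors)


def gen_binding_peaks(config: SyntheticConfig) -> FeatureSet:
    """Non-overlapping looping-factor binding peaks on the RRBS chromosome."""
    rng = _rng(config, "rrbs")
    pitch = config.genome_length // max(1, config.n_binding_peaks)
    if pitch <= config.binding_peak_length:
        raise ValueError("binding peaks would overlap; reduce n_binding_peaks")
    starts = np.arange(config.n_binding_peaks) * pitch + rng.integers(
        0, pitch - config.binding_peak_length, size=config.n_binding_peaks
    )
    return FeatureSet(
        "binding_peaks",
        [(CHROM_RRBS, int(s), int(s) + config.binding_peak_length) for s in starts],
    )


# RRBS beta mixture components: fully-unmethylated-like and fully-methylated-like
_RRBS_LOW = (1.5, 15.0)
_RRBS_HIGH = (15.0, 1.5)


def gen_rrbs(peaks: FeatureSet, config: SyntheticConfig) -> list[CpGMethRecord]:
    """RRBS-style CpG records with methylation suppressed inside peaks.

    At exclusivity_strength s, an in-peak CpG draws its beta from the
    low-methylation component with probability 0.5 + s/2 (s=0: same bimodal
    mixture as outside; s=1: always low). Coverage includes values < 5 at the
    configured fraction so the coverage filter is exercised.
    """
    rng = _rng(config, "rrbs")
    rng = np.random.default_rng(rng.integers(0, 2**31))  # decouple from peak placement
    n = config.n_rrbs
    peak_ivs = peaks.intervals
    records = []
    in_peak = rng.random(n) < config.frac_in_peaks
    s = config.exclusivity_strength
    low_prob = np.where(in_peak, 0.5 + s / 2.0, 0.5)
    use_low = rng.random(n) < low_prob
    betas = np.where(use_low, rng.beta(*_RRBS_LOW, size=n), rng.beta(*_RRBS_HIGH, size=n))
    low_cov = rng.random(n) < config.frac_low_coverage
    coverage = np.where(low_cov, rng.integers(1, 5, size=n), 5 + rng.poisson(10.0, size=n))
    for i in range(n):
        if in_peak[i] and peak_ivs:
            iv = peak_ivs[int(rng.integers(0, len(peak_ivs)))]
            pos = int(rng.integers(iv.start, iv.end))
        else:
            pos = int(rng.integers(0, config.genome_length))
            while peaks.overlaps((CHROM_RRBS, pos)):
                pos = int(rng.integers(0, config.genome_length))
        records.append(
            CpGMethRecord(GenomePosition(CHROM_RRBS, pos), int(coverage[i]), float(betas[i]))
        )
    return records


def gen_expression(
    truth: TruthSet, config: SyntheticConfig, genes: Sequence[GeneModel]
) -> pd.DataFrame:
    """Per-gene fold change and adjusted p; planted genes are down-regulated.

    Planted down-regulated genes get fold change around ``down_fold_change``
    with small adjusted p; all other genes sit near fold change 1 with
    uniform p (so ~5% are nominally significant by design).
    """
    rng = _rng(config, "expression")
    planted = set(truth.planted_downregulated_genes)
    rows = []
    for g in genes:
        if g.gene_id in planted:
            fc = float(np.exp(rng.normal(np.log(config.down_fold_change), 0.15)))
            p = float(rng.uniform(1e-6, 0.04))
        else:
            fc = float(np.exp(rng.normal(0.0, 0.05)))
            p = float(rng.uniform(0.0, 1.0))
        rows.append({"gene_id": g.gene_id, "fold_change": fc, "p_adj": p})
    return pd.DataFrame(rows)


@dataclass
class SyntheticBundle:
    """Everything one pipeline run consumes, plus the planted truth."""

    config: SyntheticConfig
    manifest: ProbeManifest
    cgis: FeatureSet
    genes: list[GeneModel]
    betas: pd.DataFrame
    groups: np.ndarray
    n_clipped: int
    feature_sets: list[FeatureSet]
    signal: SignalMatrix
    target_genes: list[GeneModel]
    anchors: FeatureSet
    binding_peaks: FeatureSet
    rrbs: list[CpGMethRecord]
    expression: pd.DataFrame
    truth: TruthSet


def generate_bundle(config: SyntheticConfig = SyntheticConfig()) -> SyntheticBundle:
    """Generate all inputs deterministically from one config."""
    manifest, cgis, genes = gen_manifest(config)
    truth = select_planted_probes(manifest, config)
    betas, groups, n_clipped = gen_beta_matrix(manifest, truth, config)
    feature_sets = gen_feature_sets(manifest, truth, config)
    signal, target_genes, anchors = gen_dhs_signal(truth, config)
    peaks = gen_binding_peaks(config)
    rrbs = gen_rrbs(peaks, config)
    expression = gen_expression(truth, config, list(genes) + list(target_genes))
    return SyntheticBundle(
        config=config,
        manifest=manifest,
        cgis=cgis,
        genes=genes,
        betas=betas,
        groups=groups,
        n_clipped=n_clipped,
        feature_sets=feature_sets,
        signal=signal,
        target_genes=target_genes,
        anchors=anchors,
        binding_peaks=peaks,
        rrbs=rrbs,
        expression=expression,
        truth=truth.validate(),
    )


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> dict[str, str]:
    """Emit the bundle as plain-text files; returns {artifact: path}."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "features").mkdir(exist_ok=True)
    paths: dict[str, str] = {}

    write_manifest(bundle.manifest, outdir / "manifest.tsv")
    bundle.betas.to_csv(outdir / "betas.tsv", sep="\t")
    pd.DataFrame({"sample_id": bundle.betas.columns, "group": bundle.groups}).to_csv(
        outdir / "samples.tsv", sep="\t", index=False
    )
    write_feature_bed(bundle.cgis, outdir / "cgi.bed")
    write_gene_models(list(bundle.genes) + list(bundle.target_genes), outdir / "genes.tsv")
    for fs in bundle.feature_sets:
        write_feature_bed(fs, outdir / "features" / f"{fs.name}.bed")
        paths[f"features/{fs.name}"] = str(outdir / "features" / f"{fs.name}.bed")
    write_signal_matrix(bundle.signal, outdir / "dhs_signal.tsv")
    write_feature_bed(bundle.anchors, outdir / "anchors.bed")
    write_feature_bed(bundle.binding_peaks, outdir / "binding_peaks.bed")
    write_rrbs(bundle.rrbs, outdir / "rrbs.tsv")
    bundle.expression.to_csv(outdir / "expression.tsv", sep="\t", index=False)
    bundle.truth.to_json(outdir / "truth.json")

    for name in ("manifest.tsv", "betas.tsv", "samples.tsv", "cgi.bed", "genes.tsv",
                 "dhs_signal.tsv", "anchors.bed", "binding_peaks.bed", "rrbs.tsv",
                 "expression.tsv", "truth.json"):
        paths[name] = str(outdir / name)
    return paths
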