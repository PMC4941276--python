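"""Generator calibration, determinism and planted-truth round-trips."""

import filecmp

import numpy as np
import pandas as pd
import pytest

from inflammeth.genomic_core import annotate_cgi_context, annotate_gene_context
from inflammeth.methyl_context_stats import filter_coverage, ks_two_sample, partition_by_peaks
from inflammeth.perm_enrich import _overlap_mask
from inflammeth.synthetic_data import (
    SyntheticConfig,
    TruthSet,
    gen_beta_matrix,
    gen_binding_peaks,
    gen_manifest,
    gen_rrbs,
    generate_bundle,
    select_planted_probes,
    write_bundle,
)


class TestManifest:
    def test_deterministic_given_seed(self):
        cfg = SyntheticConfig(seed=4, n_probes=2_000, n_cgis=60, n_genes=40)
        m1, c1, g1 = gen_manifest(cfg)
        m2, c2, g2 = gen_manifest(cfg)
        pd.testing.assert_frame_equal(m1.table, m2.table)
        assert c1.intervals == c2.intervals
        assert [g.gene_id for g in g1] == [g.gene_id for g in g2]

    def test_all_context_classes_present(self, bundle):
        table = bundle.manifest.table
        assert set(table["cgi_context"]) == {"island", "shore", "shelf", "open_sea"}
        assert set(table["gene_context"]) == {"promoter", "exon", "intron", "intergenic"}

    def test_contexts_match_independent_reannotation(self, bundle):
        """Emitted annotations equal a fresh per-probe recomputation."""
        sub = bundle.manifest.table.sample(n=200, random_state=0)
        for _, row in sub.iterrows():
            pos = (row["chrom"], int(row["pos"]))
            assert annotate_cgi_context(pos, bundle.cgis).value == row["cgi_context"]
            assert annotate_gene_context(pos, bundle.genes).value == row["gene_context"]

    def test_too_many_probes_errors(self):
        with pytest.raises(ValueError):
            SyntheticConfig(n_probes=100, genome_length=50)


class TestBetaMatrix:
    def test_values_in_unit_interval(self, bundle):
        v = bundle.betas.to_numpy()
        assert v.min() >= 0.0 and v.max() <= 1.0

    def test_planted_delta_calibration(self):
        """Empirical mean Δβ over planted hyper probes ≈ the configured effect."""
        cfg = SyntheticConfig(seed=8, n_case=20, n_control=20)
        manifest, _, _ = gen_manifest(cfg)
        truth = select_planted_probes(manifest, cfg)
        X, y, n_clipped = gen_beta_matrix(manifest, truth, cfg)
        case = X.loc[:, y == "case"].mean(axis=1)
        ctrl = X.loc[:, y == "control"].mean(axis=1)
        delta = (case - ctrl).loc[truth.planted_hyper_probe_ids]
        assert abs(delta.mean() - cfg.effect_delta) < 0.03
        delta_hypo = (case - ctrl).loc[truth.planted_hypo_probe_ids]
        assert abs(delta_hypo.mean() + cfg.effect_delta) < 0.03
        assert n_clipped < 0.05 * (len(truth.planted_hyper_probe_ids) + len(truth.planted_hypo_probe_ids))

    def test_null_generator_produces_no_effect(self):
        cfg = SyntheticConfig(seed=9, frac_hyper=0.0, frac_hypo=0.0, n_case=20, n_control=20,
                              n_probes=2_000)
        manifest, _, _ = gen_manifest(cfg)
        truth = select_planted_probes(manifest, cfg)
        assert not truth.planted_hyper_probe_ids and not truth.planted_hypo_probe_ids
        X, y, _ = gen_beta_matrix(manifest, truth, cfg)
        delta = X.loc[:, y == "case"].mean(axis=1) - X.loc[:, y == "control"].mean(axis=1)
        assert abs(delta.mean()) < 0.01


class TestFeatureSets:
    def test_enriched_coverage_rates(self, bundle):
        """Planted-hyper coverage ≈ base_rate × fold; background ≈ base_rate."""
        cfg = bundle.config
        enriched = next(
            f for f in bundle.feature_sets if f.name in bundle.truth.planted_enriched_feature_names
        )
        mask = _overlap_mask(bundle.manifest, enriched)
        ids = bundle.manifest.probe_ids.to_numpy()
        hyper = np.isin(ids, bundle.truth.planted_hyper_probe_ids)
        rate_hyper = mask[hyper].mean()
        rate_bg = mask[~hyper].mean()
        target = cfg.feature_base_rate * cfg.enrichment_fold
        assert abs(rate_hyper - target) < 4 * np.sqrt(target * (1 - target) / hyper.sum())
        assert abs(rate_bg - cfg.feature_base_rate) < 0.02

    def test_infeasible_fold_errors(self):
        with pytest.raises(ValueError):
            SyntheticConfig(feature_base_rate=0.3, enrichment_fold=5.0)

    def test_intervals_non_overlapping_within_set(self, bundle):
        for fs in bundle.feature_sets:
            ivs = fs.intervals
            assert all(a.end <= b.start for a, b in zip(ivs, ivs[1:]))


class TestSignal:
    def test_planted_pair_correlation_near_target(self, bundle):
        """Empirical anchor-target r across cell lines is close to the design value."""
        sig = bundle.signal
        site_index = {(s.chrom, s.start, s.end): i for i, s in enumerate(sig.sites)}
        rs = []
        for link in bundle.truth.planted_links:
            ia = site_index[tuple(link["enhancer"])]
            it = site_index[tuple(link["target_dhs"])]
            rs.append(np.corrcoef(sig.values[ia], sig.values[it])[0, 1])
        assert 0.85 <= np.mean(rs) <= 0.95

    def test_decoy_rarely_crosses_threshold(self, bundle):
        sig = bundle.signal
        planted = {tuple(l["target_dhs"]) for l in bundle.truth.planted_links}
        planted |= {tuple(l["enhancer"]) for l in bundle.truth.planted_links}
        anchors = {tuple(l["enhancer"]): i for l in bundle.truth.planted_links
                   for i, s in enumerate(sig.sites) if (s.chrom, s.start, s.end) == tuple(l["enhancer"])}
        n_cross = n_decoy = 0
        for i, s in enumerate(sig.sites):
            key = (s.chrom, s.start, s.end)
            if key in planted:
                continue
            # compare against the nearest anchor (the one whose window holds the decoy)
            nearest = min(anchors.values(), key=lambda ia: abs(sig.sites[ia].start - s.start))
            r = np.corrcoef(sig.values[nearest], sig.values[i])[0, 1]
            n_decoy += 1
            n_cross += r * r >= 0.7
        assert n_decoy > 0
        assert n_cross / n_decoy < 0.01


class TestRrbs:
    def test_exclusivity_off_gives_matching_distributions(self):
        cfg = SyntheticConfig(seed=12, exclusivity_strength=0.0, n_rrbs=10_000)
        peaks = gen_binding_peaks(cfg)
        records = filter_coverage(gen_rrbs(peaks, cfg))
        betas_in, betas_out = partition_by_peaks(records, peaks)
        assert ks_two_sample(betas_in, betas_out).D < 0.05

    def test_full_exclusivity_suppresses_in_peak_methylation(self, bundle):
        records = filter_coverage(bundle.rrbs)
        betas_in, betas_out = partition_by_peaks(records, bundle.binding_peaks)
        assert betas_in.mean() < 0.2
        assert ks_two_sample(betas_in, betas_out).p < 1e-6

    def test_low_coverage_fraction_calibrated(self, bundle):
        cfg = bundle.config
        frac = np.mean([r.coverage < 5 for r in bundle.rrbs])
        se = np.sqrt(cfg.frac_low_coverage * (1 - cfg.frac_low_coverage) / cfg.n_rrbs)
        assert abs(frac - cfg.frac_low_coverage) < 4 * se


class TestExpression:
    def test_covers_every_gene(self, bundle):
        all_genes = {g.gene_id for g in bundle.genes} | {g.gene_id for g in bundle.target_genes}
        assert set(bundle.expression["gene_id"]) == all_genes

    def test_planted_genes_significant_others_uniform(self, bundle):
        expr = bundle.expression.set_index("gene_id")
        planted = bundle.truth.planted_downregulated_genes
        assert (expr.loc[planted, "p_adj"] < 0.05).mean() >= 0.9
        assert (expr.loc[planted, "fold_change"] < 1).all()
        others = expr.drop(index=planted)
        assert (others["p_adj"] < 0.05).mean() < 0.15


class TestDeterminism:
    def test_byte_identical_emitted_files(self, tmp_path):
        cfg = SyntheticConfig(seed=5, n_probes=1_000, n_cgis=60, n_genes=30,
                              n_planted_links=5, n_decoy_dhs=20, n_rrbs=500,
                              n_binding_peaks=50, n_cell_lines=20)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_bundle(generate_bundle(cfg), d1)
        write_bundle(generate_bundle(cfg), d2)
        files = [p.relative_to(d1) for p in d1.rglob("*") if p.is_file()]
        assert files
        for f in files:
            assert filecmp.cmp(d1 / f, d2 / f, shallow=False), f

    def test_truth_round_trip_json(self, tmp_path, bundle):
        path = tmp_path / "truth.json"
        bundle.truth.to_json(path)
        back = TruthSet.from_json(path)
        assert back == bundle.truth
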