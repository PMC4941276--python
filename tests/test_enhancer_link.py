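"""Enhancer calling and correlation-based target linking."""

import math

import numpy as np
import pandas as pd
import pytest

from inflammeth.enhancer_link import (
    EnhancerLinker,
    LinkConfig,
    SignalMatrix,
    call_putative_enhancers,
    hypermethylated_enhancers,
    link_enhancer_targets,
    pearson_r,
    read_signal_matrix,
    write_signal_matrix,
)
from inflammeth.genomic_core import FeatureSet, GeneModel, Interval, ProbeManifest


class TestPutativeEnhancers:
    def test_overlapping_dhs_excluded(self):
        dhs = FeatureSet("dhs", [("chr1", 100, 200), ("chr1", 400, 500)])
        h3k4me3 = FeatureSet("h3k4me3", [("chr1", 150, 250)])
        out = call_putative_enhancers(dhs, h3k4me3)
        assert out.intervals == [Interval("chr1", 400, 500)]

    def test_empty_promoter_mark_passes_everything(self):
        dhs = FeatureSet("dhs", [("chr1", 0, 10), ("chr2", 5, 9)])
        out = call_putative_enhancers(dhs, FeatureSet("h3k4me3"))
        assert out.intervals == dhs.intervals

    def test_matches_brute_force_and_is_idempotent_subset(self, rng):
        dhs_ivs = [("chr1", int(s), int(s) + int(rng.integers(50, 300))) for s in rng.integers(0, 50_000, 80)]
        k4_ivs = [("chr1", int(s), int(s) + int(rng.integers(50, 300))) for s in rng.integers(0, 50_000, 30)]
        dhs, k4 = FeatureSet("dhs", dhs_ivs), FeatureSet("k4", k4_ivs)
        out = call_putative_enhancers(dhs, k4)
        naive = [
            iv for iv in dhs.intervals
            if not any(c == iv.chrom and s < iv.end and e > iv.start for c, s, e in k4_ivs)
        ]
        assert out.intervals == naive
        assert set(out.intervals) <= set(dhs.intervals)
        assert call_putative_enhancers(out, k4).intervals == out.intervals


class TestHypermethylatedEnhancers:
    @pytest.fixture()
    def manifest(self):
        return ProbeManifest(
            pd.DataFrame({"probe_id": ["a", "b", "c"], "chrom": "chr1", "pos": [110, 120, 900]})
        )

    def test_enhancer_with_probes_kept_once(self, manifest):
        enh = FeatureSet("e", [("chr1", 100, 200)])
        out = hypermethylated_enhancers(enh, ["a", "b"], manifest)
        assert out.intervals == [Interval("chr1", 100, 200)]

    def test_no_probe_inside_gives_empty(self, manifest):
        enh = FeatureSet("e", [("chr1", 300, 400)])
        assert len(hypermethylated_enhancers(enh, ["a", "b", "c"], manifest)) == 0

    def test_matches_brute_force(self, rng):
        positions = rng.choice(20_000, size=200, replace=False)
        manifest = ProbeManifest(
            pd.DataFrame({"probe_id": [f"p{i}" for i in range(200)], "chrom": "chr1",
                          "pos": positions})
        )
        enh_ivs = [("chr1", int(s), int(s) + 150) for s in rng.integers(0, 20_000, 40)]
        enh = FeatureSet("e", enh_ivs)
        hyper = [f"p{i}" for i in rng.choice(200, size=60, replace=False)]
        hyper_pos = {positions[int(p[1:])] for p in hyper}
        naive = [iv for iv in enh.intervals if any(iv.start <= q < iv.end for q in hyper_pos)]
        assert hypermethylated_enhancers(enh, hyper, manifest).intervals == naive


class TestPearson:
    def test_perfect_and_reversed(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert pearson_r(x, [2 * v for v in x]) == pytest.approx(1.0)
        assert pearson_r(x, [-3 * v + 10 for v in x]) == pytest.approx(-1.0)

    def test_hand_computation(self):
        # cov = 1.0, sd_x = sd_y = sqrt(1.25) -> r = 0.8
        assert pearson_r([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_zero_variance_returns_none(self):
        assert pearson_r([1, 1, 1], [1, 2, 3]) is None

    def test_length_contract(self):
        with pytest.raises(ValueError):
            pearson_r([1, 2], [1, 2])


def make_signal(rng, n_cells=100, r_true=0.95):
    """Anchor + correlated partner + two decoys inside the window, one outside."""
    latent = rng.gamma(4.0, 1.0, size=n_cells)
    noise = lambda: rng.gamma(4.0, math.sqrt(4 * (1 - r_true) / r_true / 4), size=n_cells)
    sites = [
        Interval("chr1", 1_000_000, 1_000_200),  # anchor
        Interval("chr1", 1_200_000, 1_200_200),  # planted partner
        Interval("chr1", 900_000, 900_200),  # decoy in window
        Interval("chr1", 1_400_000, 1_400_200),  # decoy in window
        Interval("chr1", 1_501_200, 1_501_400),  # outside +/-500 kb (midpoint distance 501,100)
    ]
    values = np.vstack(
        [
            latent + noise(),
            latent + noise(),
            rng.gamma(4.0, 1.0, size=n_cells) + noise(),
            rng.gamma(4.0, 1.0, size=n_cells) + noise(),
            latent + noise(),  # perfectly correlated but out of range
        ]
    )
    return SignalMatrix(sites, [f"c{i}" for i in range(n_cells)], values)


class TestLinking:
    def test_planted_pair_only(self, rng):
        sig = make_signal(rng)
        links = link_enhancer_targets(sig.sites[0], sig, [], LinkConfig())
        assert [l.target_dhs for l in links] == [sig.sites[1]]
        assert links[0].r2 >= 0.7

    def test_window_excludes_far_site_regardless_of_r(self, rng):
        sig = make_signal(rng, r_true=0.999)
        links = link_enhancer_targets(sig.sites[0], sig, [])
        assert all(l.distance <= 500_000 for l in links)
        assert sig.sites[4] not in [l.target_dhs for l in links]

    def test_r2_threshold_boundary(self):
        # two deterministic partner profiles with known correlation against the anchor
        anchor = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        included = anchor.copy()  # r = 1
        sites = [
            Interval("chr1", 100_000, 100_200),
            Interval("chr1", 150_000, 150_200),
        ]
        sig = SignalMatrix(sites, [f"c{i}" for i in range(6)], np.vstack([anchor, included]))
        assert len(link_enhancer_targets(sites[0], sig, [], LinkConfig(r2_min=0.7))) == 1
        assert len(link_enhancer_targets(sites[0], sig, [], LinkConfig(r2_min=1.0))) == 1

    def test_gene_assignment_nearest_tss_ties_by_id(self, rng):
        sig = make_signal(rng)
        target_mid = 1_200_100
        genes = [
            GeneModel("gB", "chr1", "+", target_mid + 1000, [(target_mid + 1000, target_mid + 2000)]),
            GeneModel("gA", "chr1", "+", target_mid - 1000, [(target_mid - 1000, target_mid - 500)]),
            GeneModel("gFar", "chr1", "+", target_mid + 100_000, [(target_mid + 100_000, target_mid + 101_000)]),
        ]
        links = link_enhancer_targets(sig.sites[0], sig, genes)
        assert links[0].gene_id == "gA"  # equidistant with gB: lexicographic tie-break

    def test_anchor_not_in_matrix_errors(self, rng):
        sig = make_signal(rng)
        with pytest.raises(ValueError):
            link_enhancer_targets(Interval("chr2", 0, 100), sig, [])

    def test_emitted_links_satisfy_invariants(self, bundle):
        linker = EnhancerLinker().fit(bundle.anchors, bundle.signal, bundle.target_genes)
        links = linker.links_
        assert (links["distance"] <= 500_000).all()
        assert (links["r2"] >= 0.7).all()
        assert np.allclose(links["r2"], links["r"] ** 2)

    def test_planted_link_recovery(self, bundle):
        linker = EnhancerLinker().fit(bundle.anchors, bundle.signal, bundle.target_genes)
        planted = {
            (tuple(l["enhancer"]), tuple(l["target_dhs"])) for l in bundle.truth.planted_links
        }
        emitted = {
            ((r.enh_chrom, r.enh_start, r.enh_end), (r.dhs_chrom, r.dhs_start, r.dhs_end))
            for r in linker.links_.itertuples()
        }
        hit = planted & emitted
        assert len(hit) / len(planted) >= 0.95
        assert (len(emitted) - len(hit)) / max(1, len(emitted)) <= 0.05

    def test_signal_matrix_round_trip(self, tmp_path, rng):
        sig = make_signal(rng, n_cells=5)
        path = tmp_path / "sig.tsv"
        write_signal_matrix(sig, path)
        back = read_signal_matrix(path)
        assert back.sites == sig.sites
        assert back.cell_lines == sig.cell_lines
        assert np.allclose(back.values, sig.values)

    def test_negative_signal_rejected(self):
        with pytest.raises(ValueError):
            SignalMatrix([Interval("chr1", 0, 10)], ["a"], [[-1.0]])
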