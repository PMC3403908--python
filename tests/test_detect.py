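"""Built-in matcher vs brute-force oracle, pair merging, external parsers."""

import numpy as np
import pytest

from ibdbench.core import IBDSegment, uniform_map
from ibdbench.detect import (
    MatchDetectorConfig,
    detect_ibd_matches,
    merge_to_individual_pairs,
    oracle_shared_segments,
    parse_external_segments,
)
from ibdbench.construct import Region, SpikeDesign, spike_ibd
from ibdbench.simulate import PanelSimConfig, simulate_panel

from conftest import make_panel


def segs_by_hap_pair(segments):
    out = {}
    for s in segments:
        key = (s.sample_i, s.hap_i, s.sample_j, s.hap_j)
        out.setdefault(key, []).append((s.start_site, s.end_site))
    return {k: sorted(v) for k, v in out.items()}


class TestOracle:
    def test_full_identity_single_segment(self):
        m = 200
        H = np.zeros((4, m), dtype=np.uint8)
        H[0] = H[2] = np.tile([0, 1], m // 2)
        panel = make_panel(H, cm=np.linspace(0.05, 10.0, m))
        segs = oracle_shared_segments(H[0], H[2], panel, min_length_cm=1.0)
        assert len(segs) == 1
        assert (segs[0].start_site, segs[0].end_site) == (0, m)

    def test_all_different_empty(self):
        H = np.zeros((4, 50), dtype=np.uint8)
        H[2] = 1
        panel = make_panel(H)
        assert oracle_shared_segments(H[0], H[2], panel, 0.01) == []

    def test_one_middle_mismatch_splits_in_two(self):
        """200 identical sites over 2 cM with one central mismatch yield
        exactly the two flanking runs at min_length 0.5."""
        m = 200
        a = np.tile([0, 1], m // 2).astype(np.uint8)
        b = a.copy()
        b[100] ^= 1
        panel = make_panel(np.vstack([a, a, b, b]), cm=np.linspace(0.01, 2.0, m))
        segs = oracle_shared_segments(a, b, panel, min_length_cm=0.5)
        assert [(s.start_site, s.end_site) for s in segs] == [(0, 100), (101, 200)]

    def test_length_mismatch_rejected(self):
        panel = make_panel(np.zeros((2, 10)))
        with pytest.raises(ValueError):
            oracle_shared_segments(np.zeros(10), np.zeros(9), panel, 0.1)


class TestDetector:
    def test_duplicated_individual_whole_chromosome(self):
        cfg = PanelSimConfig(n_samples=4, chrom_length_cm=5, sites_per_cm=100,
                             seed=40)
        panel = simulate_panel(cfg)
        panel.haplotypes[2:4] = panel.haplotypes[0:2]  # S0001 := S0000
        segs = detect_ibd_matches(panel, MatchDetectorConfig())
        full = [s for s in segs
                if s.pair == ("S0000", "S0001")
                and s.start_site == 0 and s.end_site == panel.n_sites]
        assert len(full) >= 2  # both haplotype copies span everything

    def test_spiked_segment_recovered(self):
        cfg = PanelSimConfig(n_samples=10, chrom_length_cm=10,
                             sites_per_cm=100, seed=41)
        panel = simulate_panel(cfg)
        design = SpikeDesign(0, Region(3.0, 6.0), "S0002", 0, "S0007", 1,
                             4.0, 5.0)
        spiked, truth = spike_ibd(panel, design)
        segs = detect_ibd_matches(spiked, MatchDetectorConfig())
        ours = [s for s in segs if s.pair == truth.pair
                and s.hap_i == truth.hap_i and s.hap_j == truth.hap_j]
        covering = [s for s in ours
                    if s.start_site <= truth.start_site
                    and s.end_site >= truth.end_site]
        assert len(covering) == 1

    def test_oracle_equivalence_on_random_panels(self):
        """Zero-mismatch detector output == oracle on every haplotype pair."""
        det = MatchDetectorConfig(min_length_cm=0.1, min_snps=10)
        for seed in range(5):
            cfg = PanelSimConfig(n_samples=10, chrom_length_cm=3,
                                 sites_per_cm=100, switch_rate_per_cm=2.0,
                                 seed=500 + seed)
            panel = simulate_panel(cfg)
            got = segs_by_hap_pair(detect_ibd_matches(panel, det))
            H = panel.haplotypes
            for ha in range(H.shape[0]):
                for hb in range(ha + 1, H.shape[0]):
                    if ha // 2 == hb // 2:
                        continue
                    want = oracle_shared_segments(
                        H[ha], H[hb], panel, det.min_length_cm,
                        min_snps=det.min_snps)
                    key = (panel.samples[ha // 2], ha % 2,
                           panel.samples[hb // 2], hb % 2)
                    assert got.get(key, []) == sorted(
                        (s.start_site, s.end_site) for s in want)

    def test_chance_matches_negligible_on_dense_ld_free_panel(self):
        """500 sites packed into 1 cM, independent: a qualifying chance run
        needs ~50 identical sites — effectively impossible."""
        cfg = PanelSimConfig(n_samples=20, chrom_length_cm=1, sites_per_cm=500,
                             independent_sites=True, maf_min=0.2, seed=42)
        panel = simulate_panel(cfg)
        segs = detect_ibd_matches(panel, MatchDetectorConfig(min_length_cm=0.1))
        assert len(segs) == 0

    def test_thresholds_respected(self):
        cfg = PanelSimConfig(n_samples=10, chrom_length_cm=5, sites_per_cm=80,
                             seed=43)
        panel = simulate_panel(cfg)
        det = MatchDetectorConfig(min_length_cm=0.3, min_snps=15)
        for s in detect_ibd_matches(panel, det):
            assert s.length_cm >= det.min_length_cm
            assert s.n_snps >= det.min_snps

    def test_sample_order_invariance(self):
        cfg = PanelSimConfig(n_samples=8, chrom_length_cm=5, sites_per_cm=80,
                             seed=44)
        panel = simulate_panel(cfg)
        rng = np.random.default_rng(1)
        perm = rng.permutation(panel.n_samples)
        shuffled = panel.subset_samples(list(perm))
        det = MatchDetectorConfig()

        def norm(segs):
            # pair orientation follows panel order; compare unordered
            return {(frozenset([(s.sample_i, s.hap_i), (s.sample_j, s.hap_j)]),
                     s.start_site, s.end_site) for s in segs}

        assert norm(detect_ibd_matches(panel, det)) == \
            norm(detect_ibd_matches(shuffled, det))

    def test_word_longer_than_panel_warns_empty(self, caplog):
        panel = make_panel(np.zeros((4, 8), dtype=np.uint8))
        det = MatchDetectorConfig(word_size_snps=20, min_snps=20)
        with caplog.at_level("WARNING"):
            assert detect_ibd_matches(panel, det) == []

    def test_mismatch_tolerance_bridges_single_error(self):
        """One flipped allele inside a long shared stretch: exact matching
        splits the report, one allowed mismatch restores a single segment."""
        m = 300
        rng = np.random.default_rng(9)
        a = rng.integers(0, 2, m).astype(np.uint8)
        b = a.copy()
        b[150] ^= 1
        other = rng.integers(0, 2, (2, m)).astype(np.uint8)
        panel = make_panel(np.vstack([a, other[0], b, other[1]]),
                           cm=np.linspace(0.01, 3.0, m))
        exact = detect_ibd_matches(panel, MatchDetectorConfig(
            min_length_cm=0.5, min_snps=10))
        tol = detect_ibd_matches(panel, MatchDetectorConfig(
            min_length_cm=0.5, min_snps=10, max_mismatch_snps=1))
        exact_pairs = [s for s in exact if s.hap_i == 0 and s.hap_j == 0]
        tol_pairs = [s for s in tol if s.hap_i == 0 and s.hap_j == 0]
        assert len(exact_pairs) == 2
        assert len(tol_pairs) == 1
        assert (tol_pairs[0].start_site, tol_pairs[0].end_site) == (0, m)


class TestMergeToIndividualPairs:
    def test_overlapping_intervals_merge(self):
        panel = make_panel(np.zeros((4, 150), dtype=np.uint8),
                           cm=np.linspace(0.01, 1.5, 150))
        seg = lambda s, e, hi, hj: IBDSegment(
            "S0000", "S0001", hi, hj, "1", int(panel.bp[s]),
            int(panel.bp[e - 1]), s, e, float(panel.cm[s]),
            float(panel.cm[e - 1]), e - s)
        merged = merge_to_individual_pairs(
            [seg(0, 100, 0, 0), seg(50, 150, 1, 0)], panel)
        assert [(m.start_site, m.end_site) for m in merged] == [(0, 150)]
        assert merged[0].hap_i is None

    def test_different_pairs_never_merge(self):
        panel = make_panel(np.zeros((6, 100), dtype=np.uint8))
        a = IBDSegment("S0000", "S0001", 0, 0, "1", 1, 2, 0, 50, 0.0, 0.5, 50)
        b = IBDSegment("S0001", "S0002", 0, 0, "1", 1, 2, 0, 50, 0.0, 0.5, 50)
        merged = merge_to_individual_pairs([a, b], panel)
        assert len(merged) == 2

    def test_union_length_bounds(self):
        """|union| >= max component and <= sum of components."""
        rng = np.random.default_rng(3)
        panel = make_panel(np.zeros((4, 200), dtype=np.uint8))
        for _ in range(20):
            parts = []
            for _ in range(rng.integers(1, 8)):
                s = int(rng.integers(0, 150))
                e = s + int(rng.integers(1, 50))
                parts.append(IBDSegment(
                    "S0000", "S0001", int(rng.integers(2)), int(rng.integers(2)),
                    "1", 1, 2, s, min(e, 200), 0.0, 0.5, min(e, 200) - s))
            merged = merge_to_individual_pairs(parts, panel)
            union = sum(m.end_site - m.start_site for m in merged)
            assert union >= max(p.end_site - p.start_site for p in parts)
            assert union <= sum(p.end_site - p.start_site for p in parts)


class TestExternalParsers:
    @pytest.fixture
    def panel(self):
        gmap = uniform_map("1", 10.0)
        cfg = PanelSimConfig(n_samples=5, chrom_length_cm=10, sites_per_cm=100,
                             seed=50)
        return simulate_panel(cfg)

    def test_fastibd_site_span(self, panel, tmp_path):
        path = tmp_path / "f.fibd"
        path.write_text("S0000 S0001 10 50 1e-10\n")
        segs = parse_external_segments(path, "fastibd", panel)
        assert len(segs) == 1
        assert segs[0].n_snps == 40
        assert segs[0].origin == "imported"

    def test_fastibd_score_threshold(self, panel, tmp_path):
        path = tmp_path / "f.fibd"
        path.write_text("S0000 S0001 10 50 1e-10\nS0000 S0002 10 50 1e-3\n")
        segs = parse_external_segments(path, "fastibd", panel,
                                       score_threshold=1e-8)
        assert len(segs) == 1 and segs[0].pair == ("S0000", "S0001")

    def test_unknown_sample_named_in_error(self, panel, tmp_path):
        path = tmp_path / "f.fibd"
        path.write_text("S0000 NOPE 10 50 1e-10\n")
        with pytest.raises(ValueError, match="NOPE"):
            parse_external_segments(path, "fastibd", panel)

    def test_germline_length_round_trip_on_uniform_map(self, panel, tmp_path):
        """On a 1 cM/Mb map, a 250 kb match spans ~0.25 cM after lookup."""
        s_bp = int(panel.bp[100])
        e_bp = s_bp + 250_000
        path = tmp_path / "g.match"
        path.write_text(
            f"FAM S0000.0 FAM S0001.1 1 {s_bp} {e_bp} rs1 rs2 30 0.25 cM 0 0 0\n")
        segs = parse_external_segments(path, "germline_match", panel)
        assert len(segs) == 1
        assert segs[0].hap_i == 0 and segs[0].hap_j == 1
        assert segs[0].end_cm - segs[0].start_cm == pytest.approx(0.25, abs=1e-9)

    def test_malformed_line_reports_lineno(self, panel, tmp_path):
        path = tmp_path / "bad.fibd"
        path.write_text("S0000 S0001 10 50 1e-10\nS0000 S0001 xx yy zz\n")
        with pytest.raises(ValueError, match=":2"):
            parse_external_segments(path, "fastibd", panel)

    def test_unknown_dialect(self, panel, tmp_path):
        with pytest.raises(ValueError, match="dialect"):
            parse_external_segments(tmp_path / "x", "plink", panel)
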