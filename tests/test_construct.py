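"""Spike-in truth construction and composite-individual nulls."""

import numpy as np
import pytest

from ibdbench.core import sites_in_interval, uniform_map
from ibdbench.construct import (
    Region,
    SpikeDesign,
    build_composites,
    build_spike_cohort,
    choose_regions,
    spike_ibd,
)
from ibdbench.simulate import PanelSimConfig, simulate_panel


@pytest.fixture(scope="module")
def panel():
    return simulate_panel(PanelSimConfig(
        n_samples=110, chrom_length_cm=10, sites_per_cm=100, seed=30))


class TestChooseRegions:
    def test_regions_fit_on_chromosome(self):
        gmap = uniform_map("1", 10.0)
        regions = choose_regions(gmap, n_regions=50, region_length_cm=3.0,
                                 seed=1)
        assert len(regions) == 50
        for r in regions:
            assert 0 <= r.start_cm <= 7.0
            assert r.length_cm == pytest.approx(3.0)

    def test_too_short_chromosome_rejected(self):
        with pytest.raises(ValueError):
            choose_regions(uniform_map("1", 2.0), 5, region_length_cm=3.0)

    def test_seed_reproducible(self):
        gmap = uniform_map("1", 10.0)
        assert choose_regions(gmap, 10, seed=3) == choose_regions(gmap, 10, seed=3)


class TestSpikeIbd:
    def _design(self, start=2.0, length=0.4):
        region = Region(1.5, 4.5)
        return SpikeDesign(
            region_index=0, region=region,
            donor_sample="S0000", donor_hap=1,
            recipient_sample="S0001", recipient_hap=0,
            start_cm=start, end_cm=start + length)

    def test_recipient_equals_donor_on_segment(self, panel):
        design = self._design()
        spiked, truth = spike_ibd(panel, design)
        sr = sites_in_interval(spiked, design.start_cm, design.end_cm)
        donor = spiked.hap(0, 1)[sr.start:sr.stop]
        recip = spiked.hap(1, 0)[sr.start:sr.stop]
        assert (donor == recip).all()

    def test_everything_else_untouched(self, panel):
        design = self._design()
        spiked, truth = spike_ibd(panel, design)
        mask = np.ones(panel.n_sites, dtype=bool)
        mask[truth.start_site:truth.end_site] = False
        np.testing.assert_array_equal(
            spiked.haplotypes[:, mask], panel.haplotypes[:, mask])
        # only the recipient haplotype row may change at all
        rows = np.ones(2 * panel.n_samples, dtype=bool)
        rows[2 * 1 + 0] = False
        np.testing.assert_array_equal(
            spiked.haplotypes[rows], panel.haplotypes[rows])

    def test_truth_snp_count_matches_independent_scan(self, panel):
        """0.4 cM at 100 sites/cM: n_snps equals a direct cm scan."""
        design = self._design(start=2.3, length=0.4)
        _, truth = spike_ibd(panel, design)
        expected = int(np.sum((panel.cm >= design.start_cm)
                              & (panel.cm < design.end_cm)))
        assert truth.n_snps == expected
        assert 25 <= truth.n_snps <= 55  # ~40 up to placement effects

    def test_zero_site_segment_flagged(self, panel, caplog):
        # interval squeezed between two adjacent sites
        gap_idx = int(np.argmax(np.diff(panel.cm)))
        lo = float(panel.cm[gap_idx]) + 1e-6
        hi = float(panel.cm[gap_idx + 1]) - 1e-6
        region = Region(max(0.0, lo - 1.0), min(10.0, hi + 1.0))
        design = SpikeDesign(0, region, "S0000", 0, "S0001", 1, lo, hi)
        with caplog.at_level("WARNING"):
            _, truth = spike_ibd(panel, design)
        assert truth.n_snps == 0


class TestBuildSpikeCohort:
    def test_pairs_disjoint_and_counts(self, panel):
        regions = choose_regions(panel.gmap, 4, region_length_cm=3.0, seed=2)
        designs, panels = build_spike_cohort(panel, regions, 0.4,
                                             n_pairs=30, seed=3)
        assert len(designs) == 4 * 30
        assert len(panels) == 4
        for r_idx in range(4):
            names = []
            for d in designs:
                if d.region_index == r_idx:
                    names += [d.donor_sample, d.recipient_sample]
            assert len(names) == len(set(names)) == 60

    def test_insufficient_samples_rejected(self, panel):
        regions = choose_regions(panel.gmap, 1, seed=2)
        with pytest.raises(ValueError):
            build_spike_cohort(panel, regions, 0.4, n_pairs=60, seed=3)

    def test_truths_recorded_per_design(self, panel):
        regions = choose_regions(panel.gmap, 2, seed=4)
        designs, _ = build_spike_cohort(panel, regions, 1.0, n_pairs=5, seed=5)
        for d in designs:
            assert d.truth is not None
            assert d.truth.length_cm == pytest.approx(1.0)
            assert d.region.start_cm <= d.start_cm
            assert d.end_cm <= d.region.end_cm

    def test_one_panel_per_pair_mode(self, panel):
        regions = choose_regions(panel.gmap, 2, seed=6)
        designs, panels = build_spike_cohort(
            panel, regions, 0.4, n_pairs=3, seed=7, one_panel_per_pair=True)
        assert len(panels) == 2 * 3


class TestBuildComposites:
    def test_piece_tiling_counts(self, panel):
        region = Region(2.0, 5.0)
        pool = panel.samples[:100]
        design, comp = build_composites(panel, region, 0.2, pool, seed=1)
        assert design.n_pieces == 10
        design2, _ = build_composites(panel, region, 2.0, pool, seed=1)
        assert design2.n_pieces == 100
        # pieces tile the segment exactly (independent interval scan)
        lo, hi = design2.piece_interval(0)[0], design2.piece_interval(99)[1]
        assert lo == pytest.approx(design2.segment_start_cm)
        assert hi == pytest.approx(design2.segment_start_cm + 2.0)

    def test_distinct_donors_per_piece_position(self, panel):
        region = Region(2.0, 5.0)
        design, _ = build_composites(panel, region, 2.0,
                                     panel.samples[:100], seed=2)
        for row in design.donor_assignment:
            donors = [d for d, _ in row]
            assert len(set(donors)) == 10

    def test_small_pool_rejected(self, panel):
        with pytest.raises(ValueError):
            build_composites(panel, Region(2.0, 5.0), 0.2,
                             panel.samples[:50], seed=3)

    def test_no_shared_stretch_longer_than_piece(self, panel):
        """Two composites never carry the same donor at co-located pieces,
        so any exactly-shared run inside the segment is confined to
        background agreement, never to construction."""
        region = Region(2.0, 5.0)
        design, comp = build_composites(panel, region, 1.0,
                                        panel.samples[:100], seed=4)
        for p, row in enumerate(design.donor_assignment):
            donors = [d for d, _ in row]
            assert len(set(donors)) == len(donors)
        # consecutive pieces of one composite come from different donors
        for c in range(design.n_composites):
            for p in range(design.n_pieces - 1):
                assert (design.donor_assignment[p][c][0]
                        != design.donor_assignment[p + 1][c][0])

    def test_backbone_outside_segment(self, panel):
        region = Region(2.0, 5.0)
        design, comp = build_composites(panel, region, 0.4,
                                        panel.samples[:100], seed=5)
        sr = sites_in_interval(panel, design.segment_start_cm,
                               design.segment_end_cm)
        outside = np.ones(panel.n_sites, dtype=bool)
        outside[sr.start:sr.stop] = False
        for c, backbone in enumerate(design.backbone_samples):
            b_idx = panel.sample_index(backbone)
            np.testing.assert_array_equal(
                comp.haplotypes[2 * c][outside],
                panel.hap(b_idx, 0)[outside])
            np.testing.assert_array_equal(
                comp.haplotypes[2 * c + 1], panel.hap(b_idx, 1))

    def test_deterministic(self, panel):
        region = Region(2.0, 5.0)
        d1, c1 = build_composites(panel, region, 0.4, panel.samples[:100], seed=6)
        d2, c2 = build_composites(panel, region, 0.4, panel.samples[:100], seed=6)
        assert d1 == d2 and c1 == c2
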