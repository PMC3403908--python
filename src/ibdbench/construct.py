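"""Ground-truth IBD construction by haplotype spike-in, and non-IBD null
construction by composite individuals.

Two complementary simulation designs drive the benchmark:

* **Spike-in (power):** within a randomly chosen region, a segment of one
  individual's haplotype is copied into another individual at the same
  location.  The two then share that segment identically — artificial IBD
  whose location, length and SNP content are known exactly.

* **Composite individuals (false positives):** a segment is tiled with
  consecutive 0.02 cM pieces, and each of 10 simulated individuals receives
  its pieces from distinct donors — at every piece position the 10
  composites use 10 different donors.  No two composites can share a
  stretch longer than one piece by descent, so any detected segment longer
  than 0.02 cM among them is a false positive.  Longer composite segments
  (0.4/0.6/1/2 cM) concatenate 2/3/5/10 consecutive 0.2 cM composite
  blocks.

Both constructions are deterministic given (panel, seed).
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .core import (
    GeneticMap,
    HaplotypePanel,
    IBDSegment,
    ORIGIN_TRUTH,
    sites_in_interval,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Region",
    "SpikeDesign",
    "CompositeDesign",
    "choose_regions",
    "spike_ibd",
    "build_spike_cohort",
    "build_composites",
]

#: standard segment lengths evaluated, cM
SEGMENT_LENGTHS_CM = (0.2, 0.4, 0.6, 1.0, 2.0)

#: composite-piece length, cM
PIECE_LENGTH_CM = 0.02

#: composite-block length (one fully tiled unit), cM
BLOCK_LENGTH_CM = 0.2


@dataclasses.dataclass(frozen=True)
class Region:
    """A half-open cM interval of fixed length on the chromosome."""

    start_cm: float
    end_cm: float

    def __post_init__(self) -> None:
        if not self.start_cm < self.end_cm:
            raise ValueError("region must have positive length")

    @property
    def length_cm(self) -> float:
        return self.end_cm - self.start_cm


@dataclasses.dataclass(frozen=True)
class SpikeDesign:
    """Provenance of one spiked-in IBD segment.

    The donor's haplotype ``donor_hap`` is copied into the recipient's
    haplotype ``recipient_hap`` over ``[start_cm, end_cm)``.  ``truth`` is
    filled in once the spike has been applied to a panel (it records the
    SNP count of the segment on that panel).
    """

    region_index: int
    region: Region
    donor_sample: str
    donor_hap: int
    recipient_sample: str
    recipient_hap: int
    start_cm: float
    end_cm: float
    truth: IBDSegment | None = None

    def __post_init__(self) -> None:
        if self.donor_sample == self.recipient_sample:
            raise ValueError("donor and recipient must differ")
        if not (self.region.start_cm <= self.start_cm
                and self.end_cm <= self.region.end_cm):
            raise ValueError("segment must lie inside its region")

    @property
    def segment_length_cm(self) -> float:
        return self.end_cm - self.start_cm


@dataclasses.dataclass(frozen=True)
class CompositeDesign:
    """Provenance of one region's composite individuals.

    ``donor_assignment[p][c]`` is the ``(donor_sample, donor_hap)`` whose
    material composite ``c`` carries at piece position ``p``; pieces tile
    ``[segment_start_cm, segment_start_cm + segment_length_cm)`` exactly.
    ``backbone_samples[c]`` provides composite ``c``'s haplotypes outside
    the segment (its first-piece donor, untouched).
    """

    region_index: int
    region: Region
    segment_start_cm: float
    segment_length_cm: float
    piece_length_cm: float
    n_composites: int
    donor_assignment: tuple[tuple[tuple[str, int], ...], ...]
    backbone_samples: tuple[str, ...]

    @property
    def n_pieces(self) -> int:
        return len(self.donor_assignment)

    @property
    def segment_end_cm(self) -> float:
        return self.segment_start_cm + self.segment_length_cm

    def piece_interval(self, p: int) -> tuple[float, float]:
        s = self.segment_start_cm + p * self.piece_length_cm
        return (s, s + self.piece_length_cm)


# ---------------------------------------------------------------------------
# regions
# ---------------------------------------------------------------------------

def choose_regions(gmap: GeneticMap, n_regions: int = 100,
                   region_length_cm: float = 3.0, seed: int = 0) -> list[Region]:
    """Uniformly random fixed-length regions on the chromosome (seeded)."""
    lo, hi = gmap.start_cm, gmap.end_cm
    if hi - lo < region_length_cm:
        raise ValueError(
            f"chromosome span {hi - lo:.3f} cM shorter than region "
            f"length {region_length_cm} cM")
    rng = np.random.default_rng(seed)
    starts = lo + rng.random(n_regions) * (hi - lo - region_length_cm)
    return [Region(float(s), float(s + region_length_cm)) for s in starts]


# ---------------------------------------------------------------------------
# spike-in
# ---------------------------------------------------------------------------

def _truth_segment(panel: HaplotypePanel, design: SpikeDesign) -> IBDSegment:
    sr = sites_in_interval(panel, design.start_cm, design.end_cm)
    if len(sr) == 0:
        logger.warning(
            "spiked segment [%.4f, %.4f) cM contains no sites; truth "
            "record will be excluded from power averaging",
            design.start_cm, design.end_cm)
    i_idx = panel.sample_index(design.donor_sample)
    j_idx = panel.sample_index(design.recipient_sample)
    if i_idx <= j_idx:
        si, hi = design.donor_sample, design.donor_hap
        sj, hj = design.recipient_sample, design.recipient_hap
    else:
        si, hi = design.recipient_sample, design.recipient_hap
        sj, hj = design.donor_sample, design.donor_hap
    if len(sr):
        start_bp, end_bp = int(panel.bp[sr.start]), int(panel.bp[sr.stop - 1])
    else:
        start_bp = end_bp = 0
    return IBDSegment(
        sample_i=si, sample_j=sj, hap_i=hi, hap_j=hj,
        chrom=panel.chrom,
        start_bp=start_bp, end_bp=end_bp,
        start_site=sr.start, end_site=sr.stop,
        start_cm=design.start_cm, end_cm=design.end_cm,
        n_snps=len(sr), origin=ORIGIN_TRUTH,
    )


def spike_ibd(panel: HaplotypePanel, design: SpikeDesign,
              inplace: bool = False) -> tuple[HaplotypePanel, IBDSegment]:
    """Copy the donor haplotype into the recipient over the design interval.

    Returns the modified panel (a copy unless ``inplace``) and the truth
    segment recording both (sample, haplotype) pairs and the SNP count.
    Every panel entry outside the segment's site range is unchanged.
    """
    out = panel if inplace else panel.copy()
    sr = sites_in_interval(out, design.start_cm, design.end_cm)
    donor = out.hap(out.sample_index(design.donor_sample), design.donor_hap)
    recip = out.hap(out.sample_index(design.recipient_sample),
                    design.recipient_hap)
    recip[sr.start:sr.stop] = donor[sr.start:sr.stop]
    return out, _truth_segment(out, design)


def build_spike_cohort(panel: HaplotypePanel, regions: list[Region],
                       segment_length_cm: float, n_pairs: int = 30,
                       seed: int = 0, one_panel_per_pair: bool = False):
    """Spike one segment per (region, pair) into fresh panel copies.

    Samples are partitioned into ``n_pairs`` disjoint pairs (seeded random
    partition, fixed across regions).  By default all pairs of a region are
    spiked into one shared panel copy; ``one_panel_per_pair`` instead gives
    every (region, pair) its own copy.

    Returns
    -------
    designs : list[SpikeDesign]
        With ``truth`` filled in; ``len == len(regions) * n_pairs``.
    panels : list[HaplotypePanel]
        One per region (or per (region, pair) in row-major order when
        ``one_panel_per_pair``).
    """
    if panel.n_samples < 2 * n_pairs:
        raise ValueError(
            f"panel has {panel.n_samples} samples; need >= {2 * n_pairs}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(panel.n_samples)[: 2 * n_pairs]
    pairs = [(int(perm[2 * k]), int(perm[2 * k + 1])) for k in range(n_pairs)]
    designs: list[SpikeDesign] = []
    panels: list[HaplotypePanel] = []
    for r_idx, region in enumerate(regions):
        if not one_panel_per_pair:
            region_panel = panel.copy()
            panels.append(region_panel)
        for a, b in pairs:
            start = region.start_cm + float(rng.random()) * (
                region.length_cm - segment_length_cm)
            design = SpikeDesign(
                region_index=r_idx,
                region=region,
                donor_sample=panel.samples[a],
                donor_hap=int(rng.integers(2)),
                recipient_sample=panel.samples[b],
                recipient_hap=int(rng.integers(2)),
                start_cm=start,
                end_cm=start + segment_length_cm,
            )
            if one_panel_per_pair:
                region_panel = panel.copy()
                panels.append(region_panel)
            _, truth = spike_ibd(region_panel, design, inplace=True)
            designs.append(dataclasses.replace(design, truth=truth))
    return designs, panels


# ---------------------------------------------------------------------------
# composite individuals
# ---------------------------------------------------------------------------

def build_composites(panel: HaplotypePanel, region: Region,
                     segment_length_cm: float, donor_pool: list[str],
                     seed: int = 0, region_index: int = 0,
                     n_composites: int = 10,
                     piece_length_cm: float = PIECE_LENGTH_CM,
                     block_length_cm: float = BLOCK_LENGTH_CM,
                     ) -> tuple[CompositeDesign, HaplotypePanel]:
    """Build the composite individuals for one region and segment length.

    The segment (placed uniformly at random inside the region) is tiled by
    consecutive ``piece_length_cm`` pieces grouped into
    ``block_length_cm`` blocks; at each piece position the composites draw
    material from pairwise-distinct donors, cycling a seeded permutation of
    the pool so that consecutive pieces of one composite also come from
    different donors.  Outside the segment each composite carries its
    backbone sample's haplotypes unchanged (backbone = first-piece donor).

    Returns the design and a new panel containing only the composite
    individuals (samples ``C00``, ``C01``, ...), on the same sites as the
    input panel.
    """
    if len(donor_pool) < 100:
        raise ValueError(
            f"donor pool has {len(donor_pool)} samples; need >= 100")
    pieces_per_block = int(round(block_length_cm / piece_length_cm))
    n_pieces = int(round(segment_length_cm / piece_length_cm))
    if abs(n_pieces * piece_length_cm - segment_length_cm) > 1e-9:
        raise ValueError("segment length must be a multiple of piece length")
    if region.length_cm < segment_length_cm:
        raise ValueError("segment longer than region")
    rng = np.random.default_rng(seed)
    start = region.start_cm + float(rng.random()) * (
        region.length_cm - segment_length_cm)
    pool = [donor_pool[i] for i in rng.permutation(len(donor_pool))]
    P = len(pool)
    assignment: list[tuple[tuple[str, int], ...]] = []
    for p in range(n_pieces):
        block, q = divmod(p, pieces_per_block)
        row = []
        for c in range(n_composites):
            donor = pool[(pieces_per_block * q + c + block) % P]
            row.append((donor, int(rng.integers(2))))
        assignment.append(tuple(row))
    backbones = tuple(assignment[0][c][0] for c in range(n_composites))

    # assemble the composite panel: backbone haplotypes, then piece overwrites
    donor_idx = [panel.sample_index(s) for s in backbones]
    names = [f"C{c:02d}" for c in range(n_composites)]
    comp = panel.subset_samples(donor_idx, rename=names)
    for p in range(n_pieces):
        lo_cm, hi_cm = start + p * piece_length_cm, start + (p + 1) * piece_length_cm
        sr = sites_in_interval(panel, lo_cm, hi_cm)
        if len(sr) == 0:
            continue
        for c in range(n_composites):
            donor, hap = assignment[p][c]
            src = panel.hap(panel.sample_index(donor), hap)
            comp.haplotypes[2 * c, sr.start:sr.stop] = src[sr.start:sr.stop]
    design = CompositeDesign(
        region_index=region_index,
        region=region,
        segment_start_cm=start,
        segment_length_cm=segment_length_cm,
        piece_length_cm=piece_length_cm,
        n_composites=n_composites,
        donor_assignment=tuple(assignment),
        backbone_samples=backbones,
    )
    _check_composite_design(design)
    return design, comp


def _check_composite_design(design: CompositeDesign) -> None:
    """Construction guarantees, asserted on every build."""
    for p, row in enumerate(design.donor_assignment):
        donors = [d for d, _ in row]
        if len(set(donors)) != len(donors):
            raise AssertionError(f"piece {p}: donors not pairwise distinct")
    for c in range(design.n_composites):
        for p in range(design.n_pieces - 1):
            if design.donor_assignment[p][c][0] == design.donor_assignment[p + 1][c][0]:
                raise AssertionError(
                    f"composite {c}: consecutive pieces {p},{p + 1} share a donor")
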