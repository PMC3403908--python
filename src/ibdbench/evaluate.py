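"""Power, false-positive-rate, and background IBD statistics.

Scoring is SNP-proportional and per individual pair:

* **power** of one (region, pair) record is the fraction of SNPs inside the
  spiked truth segment that the detector covers with reported IBD;
* **FPR** of one (region, composite-pair) record is the fraction of SNPs
  inside the composite segment covered by reported segments *longer than*
  the piece length (0.02 cM, strict inequality) — shorter matches can arise
  by legitimate chance sharing of a single piece;
* aggregates are unweighted means over (region, pair) records (an optional
  SNP-weighted mean is exposed);
* the **background distribution** of an all-pairs run is the histogram of
  detected segment lengths together with the total detected length, with
  counts rescaled by C(n_reference, 2) / C(n, 2) so runs on cohorts of
  different sizes are comparable.

The expected genetic length of an IBD segment inherited from a common
ancestor ``n`` generations back is ``1 / (2n)`` Morgans (the ancestral
haplotype survives ``2n`` meioses), which anchors what segment lengths a
given variant density must resolve.
"""

from __future__ import annotations

import dataclasses
import math
from collections import defaultdict

import numpy as np
import pandas as pd

from .core import HaplotypePanel, IBDSegment, merge_site_intervals
from .construct import CompositeDesign, PIECE_LENGTH_CM

__all__ = [
    "PowerRecord",
    "FprRecord",
    "LengthDistribution",
    "snp_power",
    "aggregate_power",
    "snp_fpr",
    "aggregate_fpr",
    "background_distribution",
    "expected_ibd_length",
]


@dataclasses.dataclass(frozen=True)
class PowerRecord:
    """Detection power for one spiked segment (one region x pair)."""

    region_index: int
    sample_i: str
    sample_j: str
    segment_length_cm: float
    n_snps_in_truth: int
    n_snps_detected: int
    excluded: bool = False

    @property
    def power(self) -> float:
        if self.excluded:
            return float("nan")
        return self.n_snps_detected / self.n_snps_in_truth


@dataclasses.dataclass(frozen=True)
class FprRecord:
    """False-positive rate for one composite pair (one region x pair)."""

    region_index: int
    sample_i: str
    sample_j: str
    segment_length_cm: float
    n_snps_in_segment: int
    n_snps_falsely_detected: int
    excluded: bool = False

    @property
    def fpr(self) -> float:
        if self.excluded:
            return float("nan")
        return self.n_snps_falsely_detected / self.n_snps_in_segment


@dataclasses.dataclass(frozen=True)
class LengthDistribution:
    """Histogram of detected segment lengths with pair-count normalization."""

    bin_edges_cm: np.ndarray
    counts: np.ndarray            # raw counts per bin
    scaled_counts: np.ndarray     # counts x normalization_factor
    total_length_cm: float
    n_individuals: int
    normalization_factor: float


# ---------------------------------------------------------------------------
# power
# ---------------------------------------------------------------------------

def _covered_snps(truth: IBDSegment, detected: list[IBDSegment]) -> int:
    """Truth-interval SNPs covered by the union of detected site ranges,
    clipped to the truth interval."""
    clipped = []
    for seg in detected:
        s = max(seg.start_site, truth.start_site)
        e = min(seg.end_site, truth.end_site)
        if e > s:
            clipped.append((s, e))
    return sum(e - s for s, e in merge_site_intervals(clipped))


def snp_power(truth: IBDSegment, detected: list[IBDSegment],
              region_index: int = 0,
              segment_length_cm: float | None = None) -> PowerRecord:
    """Score one truth segment against the detected segments of its pair.

    ``detected`` must already be restricted to the truth's sample pair
    (typically individual-pair merged segments).  A truth segment with zero
    SNPs yields a record flagged ``excluded``.  ``segment_length_cm``
    overrides the recorded length with the nominal design length (the
    float difference ``end_cm - start_cm`` carries rounding jitter).
    """
    length = (truth.length_cm if segment_length_cm is None
              else segment_length_cm)
    if truth.n_snps == 0:
        return PowerRecord(region_index, truth.sample_i, truth.sample_j,
                           length, 0, 0, excluded=True)
    for seg in detected:
        if seg.pair != truth.pair:
            raise ValueError(
                f"detected segment for pair {seg.pair} scored against "
                f"truth pair {truth.pair}")
    covered = _covered_snps(truth, detected)
    return PowerRecord(region_index, truth.sample_i, truth.sample_j,
                       length, truth.n_snps, covered)


_DEFAULT_SNP_BINS = (1, 5, 10, 20, 40, 80, 160, 320, 640, 1280, 2560)


def aggregate_power(records: list[PowerRecord], weighted: bool = False,
                    snp_bins=_DEFAULT_SNP_BINS):
    """Mean power over included records, plus grouped tables.

    Returns ``(mean, per_length, curve)`` where ``per_length`` is a
    DataFrame indexed by segment length and ``curve`` bins records by
    truth SNP count (the power-vs-SNP-count curves).  ``weighted=True``
    weights each record by its truth SNP count instead of equally.
    """
    included = [r for r in records if not r.excluded]
    if not included:
        raise ValueError("no included power records to aggregate")
    df = pd.DataFrame({
        "region_index": [r.region_index for r in included],
        "segment_length_cm": [r.segment_length_cm for r in included],
        "n_snps_in_truth": [r.n_snps_in_truth for r in included],
        "n_snps_detected": [r.n_snps_detected for r in included],
        "power": [r.power for r in included],
    })
    if weighted:
        mean = df["n_snps_detected"].sum() / df["n_snps_in_truth"].sum()
        per_length = df.groupby("segment_length_cm").apply(
            lambda g: g["n_snps_detected"].sum() / g["n_snps_in_truth"].sum(),
            include_groups=False).rename("power").to_frame()
        per_length["n_records"] = df.groupby("segment_length_cm").size()
    else:
        mean = float(df["power"].mean())
        per_length = df.groupby("segment_length_cm")["power"].agg(
            power="mean", n_records="size")
    edges = list(snp_bins) + [np.inf]
    df["snp_bin"] = pd.cut(df["n_snps_in_truth"], bins=edges, right=False)
    curve = (df.groupby(["segment_length_cm", "snp_bin"], observed=True)
               ["power"].agg(power="mean", n_records="size").reset_index())
    curve["snp_bin"] = curve["snp_bin"].astype(str)
    return float(mean), per_length, curve


# ---------------------------------------------------------------------------
# false positives
# ---------------------------------------------------------------------------

def snp_fpr(design: CompositeDesign, detected: list[IBDSegment],
            panel: HaplotypePanel,
            min_fp_length_cm: float = PIECE_LENGTH_CM) -> list[FprRecord]:
    """FPR records for every pair of the design's composite individuals.

    ``detected`` should be the individual-pair merged segments of the
    composite panel; only those strictly longer than ``min_fp_length_cm``
    count as false positives.  Pairs with no detected sharing contribute
    records with FPR 0.
    """
    from .core import sites_in_interval
    sr = sites_in_interval(panel, design.segment_start_cm, design.segment_end_cm)
    n_total = len(sr)
    by_pair: dict[tuple[str, str], list[IBDSegment]] = defaultdict(list)
    for seg in detected:
        if seg.length_cm > min_fp_length_cm:
            by_pair[seg.pair].append(seg)
    records = []
    names = panel.samples
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            pair = (names[a], names[b])
            if n_total == 0:
                records.append(FprRecord(design.region_index, *pair,
                                         design.segment_length_cm, 0, 0,
                                         excluded=True))
                continue
            clipped = []
            for seg in by_pair.get(pair, []):
                s = max(seg.start_site, sr.start)
                e = min(seg.end_site, sr.stop)
                if e > s:
                    clipped.append((s, e))
            covered = sum(e - s for s, e in merge_site_intervals(clipped))
            records.append(FprRecord(design.region_index, *pair,
                                     design.segment_length_cm,
                                     n_total, covered))
    return records


def aggregate_fpr(records: list[FprRecord]):
    """Unweighted mean FPR over included records, plus a per-length table."""
    included = [r for r in records if not r.excluded]
    if not included:
        raise ValueError("no included FPR records to aggregate")
    df = pd.DataFrame({
        "segment_length_cm": [r.segment_length_cm for r in included],
        "fpr": [r.fpr for r in included],
    })
    per_length = df.groupby("segment_length_cm")["fpr"].agg(
        fpr="mean", n_records="size")
    return float(df["fpr"].mean()), per_length


# ---------------------------------------------------------------------------
# background distribution
# ---------------------------------------------------------------------------

def background_distribution(detected: list[IBDSegment], n_individuals: int,
                            n_reference_individuals: int | None = None,
                            bin_width_cm: float = 0.25,
                            max_length_cm: float | None = None,
                            ) -> LengthDistribution:
    """Length histogram and total detected IBD of an all-pairs run.

    Counts are multiplied by ``C(n_reference, 2) / C(n, 2)`` so cohorts of
    different sizes plot on a common scale (factor 1 when the counts
    match).
    """
    if n_individuals < 2:
        raise ValueError("need at least 2 individuals")
    if n_reference_individuals is None:
        n_reference_individuals = n_individuals
    lengths = np.array([seg.length_cm for seg in detected], dtype=float)
    factor = (math.comb(n_reference_individuals, 2)
              / math.comb(n_individuals, 2))
    if max_length_cm is None:
        max_length_cm = float(lengths.max()) if lengths.size else bin_width_cm
    n_bins = max(1, int(np.ceil(max_length_cm / bin_width_cm)))
    edges = np.arange(n_bins + 1) * bin_width_cm
    counts, _ = np.histogram(lengths, bins=edges)
    return LengthDistribution(
        bin_edges_cm=edges,
        counts=counts,
        scaled_counts=counts * factor,
        total_length_cm=float(lengths.sum()),
        n_individuals=n_individuals,
        normalization_factor=factor,
    )


def expected_ibd_length(n_generations: int) -> float:
    """Expected IBD segment length, in Morgans, for a common ancestor
    ``n_generations`` back: ``1 / (2 n)`` (i.e. ``50 / n`` cM)."""
    if not isinstance(n_generations, (int, np.integer)) or n_generations < 1:
        raise ValueError("n_generations must be an integer >= 1")
    return 1.0 / (2 * n_generations)
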