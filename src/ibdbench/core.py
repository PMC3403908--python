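"""Core data model for phased haplotype panels.

A :class:`HaplotypePanel` holds a phased binary haplotype matrix (two rows
per diploid sample, one column per biallelic site), the ordered site table
(bp and interpolated cM positions, alleles), and optionally the
:class:`GeneticMap` that defined the cM coordinates.  An
:class:`IBDSegment` is a pairwise shared interval, either ground truth
(spiked-in), detected by the built-in matcher, or imported from an external
tool's output.

Conventions used throughout the package:

* site indices are 0-based and site ranges are half-open ``[start, end)``;
* cM intervals are half-open ``[start_cm, end_cm)``;
* genetic positions outside the map's range clamp to the terminal cM values
  rather than extrapolate.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

HAP_UNSPECIFIED = None  # hap index when a segment is not tied to a haplotype


class MapError(ValueError):
    """Raised for an invalid genetic map (non-monotone, too short, ...)."""


class PanelError(ValueError):
    """Raised for invalid panel contents (unphased, missing calls, ...)."""


@dataclasses.dataclass(eq=False)
class GeneticMap:
    """Monotone bp <-> cM coordinate table for one chromosome.

    Parameters
    ----------
    chrom
        Chromosome label.
    bp
        Strictly increasing integer base-pair positions (>= 2 points).
    cm
        Non-decreasing, finite, non-negative centiMorgan positions, one per
        bp point.
    """

    chrom: str
    bp: np.ndarray
    cm: np.ndarray

    def __post_init__(self) -> None:
        bp = np.asarray(self.bp, dtype=np.int64)
        cm = np.asarray(self.cm, dtype=np.float64)
        if bp.ndim != 1 or cm.ndim != 1 or bp.shape != cm.shape:
            raise MapError("bp and cm must be 1-D arrays of equal length")
        if bp.size < 2:
            raise MapError("a genetic map needs at least 2 points")
        if not np.all(np.diff(bp) > 0):
            raise MapError("bp positions must be strictly increasing")
        if not np.all(np.isfinite(cm)):
            raise MapError("cM positions must be finite")
        if np.any(cm < 0):
            raise MapError("cM positions must be non-negative")
        if not np.all(np.diff(cm) >= 0):
            raise MapError("cM positions must be non-decreasing")
        self.bp = bp
        self.cm = cm

    # -- coordinate transforms -------------------------------------------

    def interpolate(self, bp):
        """Piecewise-linear bp -> cM; clamps outside the map's bp range."""
        return np.interp(bp, self.bp, self.cm)

    def interpolate_bp(self, cm):
        """Approximate cM -> bp inverse (first bp attaining the cM value)."""
        return np.interp(cm, self.cm, self.bp)

    @property
    def start_cm(self) -> float:
        return float(self.cm[0])

    @property
    def end_cm(self) -> float:
        return float(self.cm[-1])

    @property
    def span_cm(self) -> float:
        return float(self.cm[-1] - self.cm[0])

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, GeneticMap)
            and self.chrom == other.chrom
            and np.array_equal(self.bp, other.bp)
            and np.array_equal(self.cm, other.cm)
        )


def interpolate_cm(gmap: GeneticMap, bp) -> float:
    """cM position of ``bp`` under ``gmap`` (linear interpolation, clamped)."""
    val = gmap.interpolate(bp)
    return float(val) if np.ndim(val) == 0 else val


def uniform_map(chrom: str, length_cm: float, bp_per_cm: int = 1_000_000) -> GeneticMap:
    """A two-point uniform-rate map covering ``[0, length_cm]`` cM."""
    end_bp = int(round(length_cm * bp_per_cm))
    return GeneticMap(chrom, np.array([0, end_bp]), np.array([0.0, length_cm]))


@dataclasses.dataclass(frozen=True)
class Site:
    """A single biallelic site (0-based ordinal, bp, interpolated cM)."""

    index: int
    bp: int
    cm: float
    ref_allele: str = "A"
    alt_allele: str = "G"


@dataclasses.dataclass(eq=False)
class HaplotypePanel:
    """Phased binary haplotype matrix over ordered biallelic sites.

    ``haplotypes`` has shape ``(2 * n_samples, n_sites)`` with entries in
    {0, 1}: row ``2*k`` is sample ``k``'s haplotype 0, row ``2*k + 1`` its
    haplotype 1.  Sites are ordered by bp and columns match that order.
    """

    chrom: str
    samples: list[str]
    bp: np.ndarray
    cm: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    haplotypes: np.ndarray
    gmap: GeneticMap | None = None

    def __post_init__(self) -> None:
        self.bp = np.asarray(self.bp, dtype=np.int64)
        self.cm = np.asarray(self.cm, dtype=np.float64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        H = np.asarray(self.haplotypes, dtype=np.uint8)
        if H.ndim != 2:
            raise PanelError("haplotypes must be a 2-D matrix")
        if H.shape[0] != 2 * len(self.samples):
            raise PanelError(
                f"haplotype matrix has {H.shape[0]} rows for "
                f"{len(self.samples)} samples (need 2 per sample)"
            )
        if H.shape[1] != self.bp.size:
            raise PanelError("haplotype columns must match site count")
        if H.size and H.max() > 1:
            raise PanelError("haplotype entries must be 0/1")
        if self.bp.size > 1 and not np.all(np.diff(self.bp) > 0):
            raise PanelError("site bp positions must be strictly increasing")
        self.haplotypes = H

    # -- basic accessors --------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return int(self.bp.size)

    @property
    def span_cm(self) -> float:
        """Nominal cM extent: the map's span if present, else the site span."""
        if self.gmap is not None:
            return self.gmap.span_cm
        if self.n_sites < 2:
            return 0.0
        return float(self.cm[-1] - self.cm[0])

    def site(self, index: int) -> Site:
        return Site(
            index=index,
            bp=int(self.bp[index]),
            cm=float(self.cm[index]),
            ref_allele=str(self.ref[index]),
            alt_allele=str(self.alt[index]),
        )

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise PanelError(f"sample {sample!r} not in panel") from None

    def hap(self, sample_index: int, hap_index: int) -> np.ndarray:
        """View of one haplotype row."""
        return self.haplotypes[2 * sample_index + hap_index]

    def copy(self) -> "HaplotypePanel":
        return HaplotypePanel(
            chrom=self.chrom,
            samples=list(self.samples),
            bp=self.bp.copy(),
            cm=self.cm.copy(),
            ref=self.ref.copy(),
            alt=self.alt.copy(),
            haplotypes=self.haplotypes.copy(),
            gmap=self.gmap,
        )

    def subset_sites(self, site_indices: np.ndarray) -> "HaplotypePanel":
        idx = np.asarray(site_indices, dtype=np.intp)
        return HaplotypePanel(
            chrom=self.chrom,
            samples=list(self.samples),
            bp=self.bp[idx],
            cm=self.cm[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
            haplotypes=self.haplotypes[:, idx],
            gmap=self.gmap,
        )

    def subset_samples(self, sample_indices: Sequence[int],
                       rename: Sequence[str] | None = None) -> "HaplotypePanel":
        rows = np.concatenate([[2 * i, 2 * i + 1] for i in sample_indices])
        names = ([self.samples[i] for i in sample_indices]
                 if rename is None else list(rename))
        return HaplotypePanel(
            chrom=self.chrom,
            samples=names,
            bp=self.bp.copy(),
            cm=self.cm.copy(),
            ref=self.ref.copy(),
            alt=self.alt.copy(),
            haplotypes=self.haplotypes[rows].copy(),
            gmap=self.gmap,
        )

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, HaplotypePanel)
            and self.chrom == other.chrom
            and self.samples == other.samples
            and np.array_equal(self.bp, other.bp)
            and np.array_equal(self.cm, other.cm)
            and np.array_equal(self.haplotypes, other.haplotypes)
        )


def sites_in_interval(panel: HaplotypePanel, start_cm: float, end_cm: float) -> range:
    """Half-open site-index range with cM position in ``[start_cm, end_cm)``.

    May be empty; requires ``start_cm < end_cm``.
    """
    if not start_cm < end_cm:
        raise ValueError("start_cm must be < end_cm")
    lo = int(np.searchsorted(panel.cm, start_cm, side="left"))
    hi = int(np.searchsorted(panel.cm, end_cm, side="left"))
    return range(lo, hi)


# ---------------------------------------------------------------------------
# IBD segments
# ---------------------------------------------------------------------------

ORIGIN_TRUTH = "truth"
ORIGIN_DETECTED = "detected"
ORIGIN_IMPORTED = "imported"


@dataclasses.dataclass(frozen=True)
class IBDSegment:
    """A pairwise shared interval, in both cM and site-index coordinates.

    ``start_site``/``end_site`` is half-open; ``hap_i``/``hap_j`` are 0/1 or
    ``None`` when the segment is not attributed to specific haplotypes
    (e.g. after merging to individual pairs).  ``n_snps`` is the number of
    panel sites the segment covers.  Truth segments from spike designs may
    legitimately carry ``n_snps == 0`` at very low variant density; they are
    flagged and excluded from power averaging downstream.
    """

    sample_i: str
    sample_j: str
    hap_i: int | None
    hap_j: int | None
    chrom: str
    start_bp: int
    end_bp: int
    start_site: int
    end_site: int
    start_cm: float
    end_cm: float
    n_snps: int
    score: float | None = None
    origin: str = ORIGIN_DETECTED

    def __post_init__(self) -> None:
        if self.sample_i == self.sample_j:
            raise ValueError("an IBD segment needs two distinct samples")
        if self.start_cm > self.end_cm:
            raise ValueError("start_cm must be <= end_cm")
        if self.end_site < self.start_site:
            raise ValueError("site range must be non-negative")

    @property
    def length_cm(self) -> float:
        return self.end_cm - self.start_cm

    @property
    def pair(self) -> tuple[str, str]:
        return (self.sample_i, self.sample_j)

    @property
    def site_range(self) -> range:
        return range(self.start_site, self.end_site)


def ordered_pair(panel: HaplotypePanel, a: str, b: str) -> tuple[str, str]:
    """Return (a, b) ordered by their position in the panel's sample list."""
    if panel.sample_index(a) <= panel.sample_index(b):
        return (a, b)
    return (b, a)


def merge_site_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open integer intervals: sorted, disjoint, merged when
    overlapping or touching."""
    ivs = sorted((s, e) for s, e in intervals if e > s)
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged
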