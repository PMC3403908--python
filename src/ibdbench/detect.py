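"""Haplotype-matching IBD detection.

The built-in detector follows the direct haplotype-matching (seed-and-
extend) strategy used by hash-based IBD tools: identical fixed-width SNP
words at the same site positions are hashed across all haplotypes; any two
haplotypes of different samples sharing a word become a candidate pair, and
each candidate pair's matches are then resolved exactly — with zero allowed
mismatches every maximal run of identical alleles is reported, so the
detector provably agrees with the brute-force oracle
(:func:`oracle_shared_segments`) after thresholding.  With a positive
mismatch budget, maximal stretches containing at most ``max_mismatch_snps``
mismatching sites (and at least one full seed word) are reported instead,
with overlapping reports merged.

Reported segments must span at least ``min_length_cm`` (genetic length) and
contain at least ``min_snps`` sites.  The effective seed width is
``min(word_size_snps, min_snps)`` so that no run passing the SNP-count
threshold can be missed for lack of a seed.

Parsers for two external pairwise-segment dialects (``germline_match`` and
``fastibd``) normalize third-party calls into panel coordinates; see
``docs/formats.md`` for the column tables.
"""

from __future__ import annotations

import dataclasses
import logging
from collections import defaultdict

import numpy as np

from .core import (
    GeneticMap,
    HaplotypePanel,
    IBDSegment,
    ORIGIN_DETECTED,
    ORIGIN_IMPORTED,
    merge_site_intervals,
)

logger = logging.getLogger(__name__)

__all__ = [
    "MatchDetectorConfig",
    "oracle_shared_segments",
    "detect_ibd_matches",
    "merge_to_individual_pairs",
    "parse_external_segments",
]


@dataclasses.dataclass(frozen=True)
class MatchDetectorConfig:
    """Thresholds and matching parameters of the built-in detector.

    ``min_length_cm`` defaults to 0.1 cM — the minimum-length setting used
    when hunting small segments with haplotype-matching tools.  ``min_snps``
    (default 10) is this package's own floor on segment SNP content.
    """

    min_length_cm: float = 0.1
    min_snps: int = 10
    word_size_snps: int = 16
    max_mismatch_snps: int = 0

    def __post_init__(self) -> None:
        if self.min_length_cm <= 0:
            raise ValueError("min_length_cm must be > 0")
        if self.word_size_snps < 1 or self.word_size_snps > 63:
            raise ValueError("word_size_snps must be in [1, 63]")
        if self.min_snps < 1:
            raise ValueError("min_snps must be >= 1")
        if self.max_mismatch_snps < 0:
            raise ValueError("max_mismatch_snps must be >= 0")

    @property
    def effective_word(self) -> int:
        return min(self.word_size_snps, self.min_snps)


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------

def _identical_runs(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Maximal runs of equality: (starts, ends half-open, mismatch positions)."""
    mism = np.flatnonzero(a != b)
    m = a.size
    starts = np.concatenate(([0], mism + 1))
    ends = np.concatenate((mism, [m]))
    keep = ends > starts
    return starts[keep], ends[keep], mism


def oracle_shared_segments(hap_a: np.ndarray, hap_b: np.ndarray,
                           panel: HaplotypePanel, min_length_cm: float,
                           min_snps: int = 1,
                           sample_i: str = "hapA", sample_j: str = "hapB",
                           hap_i: int | None = None, hap_j: int | None = None,
                           ) -> list[IBDSegment]:
    """Exact linear scan: all maximal runs of identical alleles between two
    haplotypes whose cM span is >= ``min_length_cm`` (and SNP count >=
    ``min_snps``).

    Independent of the seed-and-extend machinery; used as its oracle.
    """
    hap_a = np.asarray(hap_a)
    hap_b = np.asarray(hap_b)
    if hap_a.shape != hap_b.shape:
        raise ValueError("haplotypes must have equal length")
    if hap_a.size != panel.n_sites:
        raise ValueError("haplotype length must match panel site count")
    starts, ends, _ = _identical_runs(hap_a, hap_b)
    out = []
    for s, e in zip(starts, ends):
        seg = _segment_from_run(panel, int(s), int(e), sample_i, sample_j,
                                hap_i, hap_j, ORIGIN_DETECTED)
        if seg.length_cm >= min_length_cm and seg.n_snps >= min_snps:
            out.append(seg)
    return out


def _segment_from_run(panel: HaplotypePanel, s: int, e: int,
                      sample_i: str, sample_j: str,
                      hap_i: int | None, hap_j: int | None,
                      origin: str, score: float | None = None) -> IBDSegment:
    return IBDSegment(
        sample_i=sample_i, sample_j=sample_j, hap_i=hap_i, hap_j=hap_j,
        chrom=panel.chrom,
        start_bp=int(panel.bp[s]), end_bp=int(panel.bp[e - 1]),
        start_site=s, end_site=e,
        start_cm=float(panel.cm[s]), end_cm=float(panel.cm[e - 1]),
        n_snps=e - s, score=score, origin=origin,
    )


# ---------------------------------------------------------------------------
# seed-and-extend detector
# ---------------------------------------------------------------------------

def _window_keys(H: np.ndarray, w: int) -> np.ndarray:
    """Exact uint64 content keys of every width-``w`` window (stride 1)."""
    n_hap, m = H.shape
    P = m - w + 1
    K = np.zeros((n_hap, P), dtype=np.uint64)
    for k in range(w):
        K += H[:, k:k + P].astype(np.uint64) << np.uint64(k)
    return K


def _candidate_pairs(K: np.ndarray) -> np.ndarray:
    """Boolean (n_hap, n_hap) matrix: haplotypes sharing a word at some
    aligned position."""
    n_hap = K.shape[0]
    cand = np.zeros((n_hap, n_hap), dtype=bool)
    order = np.argsort(K, axis=0, kind="stable")
    S = np.take_along_axis(K, order, axis=0)
    eq = S[1:] == S[:-1]
    cols = np.flatnonzero(eq.any(axis=0))
    # once every haplotype pair is a candidate nothing more can be learned
    full = n_hap * n_hap
    for ci, p in enumerate(cols):
        col = eq[:, p]
        idx = order[:, p]
        # runs of True in `col` mark duplicate groups in sorted order
        boundaries = np.flatnonzero(np.diff(col))
        edges = np.concatenate(([0], boundaries + 1, [col.size]))
        for a, b in zip(edges[:-1], edges[1:]):
            if col[a]:
                g = idx[a:b + 1]
                cand[g[:, None], g] = True
        if ci % 64 == 0 and int(cand.sum()) == full:
            break
    return cand


def _mismatch_tolerant_runs(mism: np.ndarray, m: int, k: int,
                            min_gap: int) -> tuple[np.ndarray, np.ndarray]:
    """Maximal half-open windows containing <= k mismatches and at least one
    exact run of >= min_gap sites (so a seed word exists inside)."""
    if mism.size <= k:
        return np.array([0]), np.array([m])
    bounds = np.concatenate(([-1], mism, [m]))
    n = mism.size
    starts = bounds[: n - k + 1] + 1   # just after the preceding mismatch
    ends = bounds[k + 1:]              # up to (excl.) the next mismatch
    gaps = np.diff(bounds) - 1         # exact-run lengths between mismatches
    from numpy.lib.stride_tricks import sliding_window_view
    max_gap = sliding_window_view(gaps, k + 1).max(axis=1)
    keep = (ends > starts) & (max_gap >= min_gap)
    return starts[keep], ends[keep]


def _merge_sorted_intervals(starts: np.ndarray,
                            ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Union of half-open intervals already sorted by start (vectorized)."""
    if starts.size == 0:
        return starts, ends
    cummax = np.maximum.accumulate(ends)
    new_group = np.concatenate(
        ([True], starts[1:] > cummax[:-1]))
    group_starts = starts[new_group]
    last_of_group = np.concatenate(
        (np.flatnonzero(new_group)[1:] - 1, [starts.size - 1]))
    return group_starts, cummax[last_of_group]


def detect_ibd_matches(panel: HaplotypePanel,
                       config: MatchDetectorConfig | None = None,
                       ) -> list[IBDSegment]:
    """Seed-and-extend haplotype matching over all cross-sample haplotype
    pairs of the panel.

    Returns haplotype-level segments sorted by (sample_i, sample_j,
    start_cm, hap_i, hap_j); every one satisfies the config thresholds.
    With ``max_mismatch_snps == 0`` the output on each haplotype pair
    equals :func:`oracle_shared_segments` filtered by ``min_snps``.
    """
    if config is None:
        config = MatchDetectorConfig()
    if panel.n_samples < 2:
        raise ValueError("need at least 2 samples")
    w = config.effective_word
    H = panel.haplotypes
    if w > panel.n_sites:
        logger.warning("word size %d exceeds site count %d; no matches",
                       w, panel.n_sites)
        return []
    K = _window_keys(H, w)
    cand = _candidate_pairs(K)
    segments: list[IBDSegment] = []
    n_hap = H.shape[0]
    for ha in range(n_hap):
        for hb in range(ha + 1, n_hap):
            if ha // 2 == hb // 2 or not cand[ha, hb]:
                continue
            ia, ib = ha // 2, hb // 2
            si, sj = panel.samples[ia], panel.samples[ib]
            hi, hj = ha % 2, hb % 2
            starts, ends, mism = _identical_runs(H[ha], H[hb])
            if config.max_mismatch_snps > 0:
                starts, ends = _mismatch_tolerant_runs(
                    mism, panel.n_sites, config.max_mismatch_snps, w)
            keep = ends - starts >= config.min_snps
            starts, ends = starts[keep], ends[keep]
            if starts.size:
                spans = panel.cm[ends - 1] - panel.cm[starts]
                keep = spans >= config.min_length_cm
                starts, ends = starts[keep], ends[keep]
            if config.max_mismatch_snps > 0:
                starts, ends = _merge_sorted_intervals(starts, ends)
            for s, e in zip(starts.tolist(), ends.tolist()):
                segments.append(_segment_from_run(
                    panel, s, e, si, sj, hi, hj, ORIGIN_DETECTED))
    segments.sort(key=lambda g: (panel.sample_index(g.sample_i),
                                 panel.sample_index(g.sample_j),
                                 g.start_cm, g.hap_i, g.hap_j))
    return segments


def merge_to_individual_pairs(segments: list[IBDSegment],
                              panel: HaplotypePanel) -> list[IBDSegment]:
    """Union of haplotype-level intervals per sample pair.

    Power and FPR are scored per individual pair: a truth SNP counts as
    detected if any of the four haplotype pairings covers it.  Merged
    segments carry ``hap = None``; intervals are disjoint and sorted.
    """
    by_pair: dict[tuple[str, str], list[tuple[int, int]]] = defaultdict(list)
    origins: dict[tuple[str, str], str] = {}
    for seg in segments:
        by_pair[seg.pair].append((seg.start_site, seg.end_site))
        origins.setdefault(seg.pair, seg.origin)
    out: list[IBDSegment] = []
    for pair in sorted(by_pair, key=lambda p: (panel.sample_index(p[0]),
                                               panel.sample_index(p[1]))):
        for s, e in merge_site_intervals(by_pair[pair]):
            out.append(_segment_from_run(
                panel, s, e, pair[0], pair[1], None, None, origins[pair]))
    return out


# ---------------------------------------------------------------------------
# external-detector output parsers
# ---------------------------------------------------------------------------

def _resolve_sample(panel: HaplotypePanel, raw: str,
                    path, lineno: int) -> tuple[str, int | None]:
    """Strip an optional '.0'/'.1' haplotype tag and check panel membership."""
    hap: int | None = None
    name = raw
    if raw.endswith((".0", ".1")):
        name, tag = raw.rsplit(".", 1)
        hap = int(tag)
    if name not in panel.samples:
        raise ValueError(
            f"{path}:{lineno}: sample {name!r} not present in panel")
    return name, hap


def parse_external_segments(path, dialect: str, panel: HaplotypePanel,
                            gmap: GeneticMap | None = None,
                            score_threshold: float | None = None,
                            ) -> list[IBDSegment]:
    """Normalize an external tool's pairwise-segment list into panel
    coordinates (``origin="imported"``).

    ``germline_match``: whitespace columns
    ``fam_i id_i fam_j id_j chrom start_bp end_bp snp_id_start snp_id_end
    n_snps length unit [...]`` with ids optionally tagged ``.0``/``.1``.
    bp spans are closed; cM positions come from ``gmap`` (or the panel's
    own map / site cM values).

    ``fastibd``: columns ``sample_i sample_j start_site end_site score``
    with a half-open site-index span.  ``score_threshold`` keeps only
    segments whose score is <= the threshold (smaller = stronger support),
    mirroring how HMM-based callers threshold their reported scores.
    """
    if dialect not in ("germline_match", "fastibd"):
        raise ValueError(f"unknown dialect {dialect!r}")
    gmap = gmap or panel.gmap
    segments: list[IBDSegment] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            f = line.split()
            if not f or f[0].startswith("#"):
                continue
            try:
                if dialect == "germline_match":
                    seg = _parse_germline_line(f, panel, gmap, path, lineno)
                else:
                    seg = _parse_fastibd_line(f, panel, path, lineno)
            except (IndexError, ValueError) as exc:
                if isinstance(exc, ValueError) and "not present in panel" in str(exc):
                    raise
                raise ValueError(
                    f"{path}:{lineno}: malformed {dialect} line: {line!r}"
                ) from exc
            if seg is None:
                continue
            if (dialect == "fastibd" and score_threshold is not None
                    and (seg.score is None or seg.score > score_threshold)):
                continue
            segments.append(seg)
    return segments


def _parse_germline_line(f, panel, gmap, path, lineno) -> IBDSegment:
    name_i, hap_i = _resolve_sample(panel, f[1], path, lineno)
    name_j, hap_j = _resolve_sample(panel, f[3], path, lineno)
    start_bp, end_bp = int(f[5]), int(f[6])
    start_site = int(np.searchsorted(panel.bp, start_bp, side="left"))
    end_site = int(np.searchsorted(panel.bp, end_bp, side="right"))
    if gmap is not None:
        start_cm = float(gmap.interpolate(start_bp))
        end_cm = float(gmap.interpolate(end_bp))
    else:
        start_cm = float(panel.cm[start_site]) if start_site < panel.n_sites else 0.0
        end_cm = float(panel.cm[max(end_site - 1, 0)])
    if panel.sample_index(name_i) > panel.sample_index(name_j):
        name_i, name_j, hap_i, hap_j = name_j, name_i, hap_j, hap_i
    return IBDSegment(
        sample_i=name_i, sample_j=name_j, hap_i=hap_i, hap_j=hap_j,
        chrom=f[4], start_bp=start_bp, end_bp=end_bp,
        start_site=start_site, end_site=end_site,
        start_cm=start_cm, end_cm=end_cm,
        n_snps=end_site - start_site, origin=ORIGIN_IMPORTED,
    )


def _parse_fastibd_line(f, panel, path, lineno) -> IBDSegment:
    name_i, _ = _resolve_sample(panel, f[0], path, lineno)
    name_j, _ = _resolve_sample(panel, f[1], path, lineno)
    start_site, end_site = int(f[2]), int(f[3])
    score = float(f[4])
    if not 0 <= start_site < end_site <= panel.n_sites:
        raise ValueError("site span out of panel range")
    if panel.sample_index(name_i) > panel.sample_index(name_j):
        name_i, name_j = name_j, name_i
    return IBDSegment(
        sample_i=name_i, sample_j=name_j, hap_i=None, hap_j=None,
        chrom=panel.chrom,
        start_bp=int(panel.bp[start_site]), end_bp=int(panel.bp[end_site - 1]),
        start_site=start_site, end_site=end_site,
        start_cm=float(panel.cm[start_site]),
        end_cm=float(panel.cm[end_site - 1]),
        n_snps=end_site - start_site, score=score, origin=ORIGIN_IMPORTED,
    )
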