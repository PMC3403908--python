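"""Synthetic phased haplotype panels with controllable variant density.

Real IBD benchmarks span platforms from sparse genotyping arrays to deep
whole-genome sequencing; what varies between them, for a fixed genetic map,
is the number of assayed sites per cM and the allele-frequency spectrum
(arrays are ascertained toward common variants).  This module emulates that
axis without any data download:

* site positions are uniform on a synthetic chromosome with a uniform
  bp<->cM map;
* per-site minor-allele frequencies follow a 1/f spectrum truncated to
  ``[maf_min, 0.5]`` — lowering ``maf_min`` enriches rare variants, as
  sequencing panels are relative to arrays;
* linkage disequilibrium comes from a founder-mosaic (copying) process:
  each sample haplotype copies founder haplotypes, switching its copying
  source along the chromosome as a Poisson process with intensity
  ``switch_rate_per_cm``;
* optional per-allele genotype error flips alleles independently.

``independent_sites=True`` disables the copying process entirely and draws
every haplotype i.i.d. from the frequency spectrum — an LD-free panel used
for null calibration, where any detected sharing is pure chance.

This is deliberately not a coalescent: the benchmark needs a realistic
shared-haplotype background at desk scale, not a demographic model.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .core import GeneticMap, HaplotypePanel, uniform_map

__all__ = [
    "PanelSimConfig",
    "simulate_founders",
    "simulate_panel",
    "simulate_panel_with_provenance",
    "thin_panel",
]


@dataclasses.dataclass(frozen=True)
class PanelSimConfig:
    """Parameters of the synthetic-panel generator.

    Attributes
    ----------
    n_samples
        Diploid samples to emit (2 haplotypes each).
    chrom_length_cm
        Genetic length of the synthetic chromosome, cM.
    sites_per_cm
        Variant density — the experimental axis of the benchmark.
    n_founders
        Founder haplotypes the mosaic process copies from.
    switch_rate_per_cm
        Poisson intensity of copying-source switches; higher = shorter
        shared tracts (weaker long-range LD).
    maf_min
        Lower truncation of the 1/f allele-frequency spectrum, in (0, 0.5].
    genotype_error_rate
        Per-allele flip probability applied after copying.
    independent_sites
        Draw haplotypes i.i.d. per site instead of copying founders
        (LD-free null panel).
    bp_per_cm
        Physical scale of the uniform map.
    """

    n_samples: int
    chrom_length_cm: float = 50.0
    sites_per_cm: float = 200.0
    n_founders: int = 100
    switch_rate_per_cm: float = 1.0
    maf_min: float = 0.05
    genotype_error_rate: float = 0.0
    independent_sites: bool = False
    bp_per_cm: int = 1_000_000
    chrom: str = "1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_founders < 1:
            raise ValueError("counts must be >= 1")
        if self.chrom_length_cm <= 0 or self.sites_per_cm <= 0:
            raise ValueError("lengths and densities must be positive")
        if not 0 < self.maf_min <= 0.5:
            raise ValueError("maf_min must be in (0, 0.5]")
        if self.switch_rate_per_cm < 0 or self.genotype_error_rate < 0:
            raise ValueError("rates must be >= 0")

    @property
    def n_sites(self) -> int:
        return int(round(self.sites_per_cm * self.chrom_length_cm))


def _rng(config: PanelSimConfig, stream: int) -> np.random.Generator:
    # separate streams so simulate_founders(config) yields exactly the
    # founders simulate_panel(config) copies from
    return np.random.default_rng([config.seed, stream])


def _site_positions(config: PanelSimConfig, rng: np.random.Generator) -> np.ndarray:
    """Sorted unique uniform bp positions (1-based) for config.n_sites sites."""
    length_bp = int(round(config.chrom_length_cm * config.bp_per_cm))
    n = config.n_sites
    if n > length_bp:
        raise ValueError("more sites requested than bp positions available")
    pos = np.unique(rng.integers(1, length_bp + 1, size=n))
    while pos.size < n:  # top up collisions
        extra = rng.integers(1, length_bp + 1, size=n - pos.size)
        pos = np.unique(np.concatenate([pos, extra]))
    return pos.astype(np.int64)


def _allele_frequencies(config: PanelSimConfig, rng: np.random.Generator,
                        n: int) -> np.ndarray:
    # density proportional to 1/f on [maf_min, 0.5]  =>  log-uniform draw
    u = rng.random(n)
    return config.maf_min * (0.5 / config.maf_min) ** u


def simulate_founders(config: PanelSimConfig):
    """Founder haplotypes plus the site table and genetic map.

    Returns
    -------
    founders : ndarray, shape (n_founders, n_sites), uint8
        Alleles sampled independently per site from the 1/f-spectrum
        frequency of that site.
    bp, cm, freq : ndarray
        Site positions (bp and cM under the uniform map) and the per-site
        alternate-allele frequencies.
    gmap : GeneticMap
    """
    rng = _rng(config, 0)
    bp = _site_positions(config, rng)
    gmap = uniform_map(config.chrom, config.chrom_length_cm, config.bp_per_cm)
    cm = gmap.interpolate(bp)
    freq = _allele_frequencies(config, rng, bp.size)
    founders = (rng.random((config.n_founders, bp.size)) < freq).astype(np.uint8)
    return founders, bp, cm, freq, gmap


def simulate_panel_with_provenance(config: PanelSimConfig,
                                   ) -> tuple[HaplotypePanel, np.ndarray]:
    """Like :func:`simulate_panel`, also returning the per-haplotype count
    of copying-source switch events (all zeros for ``independent_sites``)."""
    founders, bp, cm, freq, gmap = simulate_founders(config)
    rng = _rng(config, 1)
    n_hap = 2 * config.n_samples
    m = bp.size
    switch_counts = np.zeros(n_hap, dtype=np.int64)
    if config.independent_sites:
        H = (rng.random((n_hap, m)) < freq).astype(np.uint8)
    else:
        H = np.empty((n_hap, m), dtype=np.uint8)
        rate = config.switch_rate_per_cm * config.chrom_length_cm
        for h in range(n_hap):
            n_switch = rng.poisson(rate)
            switch_counts[h] = n_switch
            cuts = np.sort(rng.random(n_switch) * config.chrom_length_cm)
            sources = rng.integers(0, config.n_founders, size=n_switch + 1)
            tract = np.searchsorted(cuts, cm, side="right")
            H[h] = founders[sources[tract], np.arange(m)]
    if config.genotype_error_rate > 0:
        flips = rng.random((n_hap, m)) < config.genotype_error_rate
        H ^= flips.astype(np.uint8)
    samples = [f"S{i:04d}" for i in range(config.n_samples)]
    ref = np.full(m, "A", dtype=object)
    alt = np.full(m, "G", dtype=object)
    panel = HaplotypePanel(
        chrom=config.chrom, samples=samples, bp=bp, cm=cm,
        ref=ref, alt=alt, haplotypes=H, gmap=gmap,
    )
    return panel, switch_counts


def simulate_panel(config: PanelSimConfig) -> HaplotypePanel:
    """Generate a phased panel under ``config`` (bit-reproducible per seed)."""
    panel, _ = simulate_panel_with_provenance(config)
    return panel


def thin_panel(panel: HaplotypePanel, target_sites_per_cm: float,
               seed: int) -> HaplotypePanel:
    """Uniformly subsample site columns down to a target density.

    Thinning is *nested*: for a fixed seed, the site set kept at a lower
    target density is a subset of the set kept at any higher density (each
    site gets a random priority; the lowest-priority sites are kept).  Site
    order and haplotype rows are untouched at kept sites.
    """
    span = panel.span_cm
    if span <= 0:
        raise ValueError("panel has no cM extent to thin over")
    current = panel.n_sites / span
    if target_sites_per_cm > current * (1 + 1e-12):
        raise ValueError(
            f"target density {target_sites_per_cm}/cM exceeds current "
            f"{current:.3f}/cM")
    n_keep = int(round(target_sites_per_cm * span))
    n_keep = min(n_keep, panel.n_sites)
    priority = np.random.default_rng(seed).permutation(panel.n_sites)
    keep = np.sort(np.argsort(priority)[:n_keep])
    return panel.subset_sites(keep)
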