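# Methods

## Scope and model

`ibdbench` evaluates pairwise IBD-segment detection on phased diploid
panels.  The unit of data is a binary haplotype matrix (2 rows per sample,
1 column per biallelic SNP) with bp positions mapped to centiMorgans by a
monotone genetic map.  All site ranges and cM intervals are half-open
`[start, end)`; cM lookups outside the map clamp to the terminal values
rather than extrapolate (this avoids negative or runaway positions and
matters only for segments touching chromosome ends).

Missing genotypes are rejected, never imputed, and unphased genotypes are
an error: the evaluation is defined over fully called, phased haplotypes.
Multi-allelic sites are dropped with a warning.

## Synthetic panels

The generator emulates one experimental axis — variant density (sites per
cM) with realistic shared-haplotype background — without any real data:

* **Sites**: `n = sites_per_cm x chrom_length_cm` positions drawn
  uniformly on a chromosome with a uniform map (default 1 cM/Mb).
* **Frequencies**: per-site alternate-allele frequency with density
  proportional to 1/f, truncated to `[maf_min, 0.5]` (log-uniform draw).
  Lower `maf_min` enriches rare variants, as sequencing panels are
  relative to arrays.
* **LD**: each sample haplotype copies from `n_founders` founder
  haplotypes, switching its copying source along the chromosome as a
  Poisson process with intensity `switch_rate_per_cm` (default 1/cM).
  This founder-mosaic process yields long shared tracts between samples —
  the background an IBD detector must discriminate against — at desk
  scale.  It is deliberately *not* a coalescent: no demographic history,
  no recombination hotspots, no realistic site-frequency correlations.
* **Genotype error**: independent per-allele flips at
  `genotype_error_rate`.
* **`independent_sites=True`** disables copying entirely (haplotypes
  i.i.d. from the spectrum): an LD-free panel in which *any* detected
  sharing is chance, used for null calibration.  Random founder
  assignment with the switch rate set to zero would not serve here —
  birthday collisions would duplicate whole haplotypes, i.e. inject real
  IBD into the null.

`thin_panel` subsamples columns to a target density using per-site random
priorities, so site sets are nested across densities under a shared seed:
thinned panels are true subsets of the deep panel, which makes density
comparisons paired rather than independent.

Density presets (`array_low` 15/cM maf>=0.10, `array_dense` 40/cM >=0.05,
`seq_low` 120/cM >=0.02, `seq_deep` 250/cM >=0.01) are **this package's own
calibration-free choices** to span the array-to-sequencing ladder; they are
not measurements of any platform.

What passing tests on these panels do show: the detector's calibration,
its oracle-exactness, and the direction and rough magnitude of density and
error effects.  What they do not show: absolute power/FPR on any real
platform, phasing-error effects, or behavior under realistic demographic
LD.

## Truth construction (spike-in)

One donor haplotype segment is copied into one recipient haplotype at the
same location.  Regions (default 100, each 3 cM) are uniform on the map;
the segment start is uniform inside its region (the placement is otherwise
unconstrained, avoiding systematic edge effects); donor and recipient
haplotype indices are drawn uniformly and recorded.  Samples are
partitioned into disjoint pairs (default 30).  All of a region's spikes
land in one fresh panel copy (regions never interfere); a
`one_panel_per_pair` switch isolates single spikes instead.  The truth
record stores both (sample, haplotype) coordinates and the segment's SNP
count; truth segments that contain zero SNPs (possible at very low
density) are flagged, excluded from power denominators, and counted in
reports.

## Null construction (composites)

A composite segment of length 0.2 cM is tiled by ten 0.02 cM pieces;
longer segments (0.4/0.6/1/2 cM) concatenate 2/3/5/10 consecutive 0.2 cM
blocks.  From a 100-donor pool, a seeded permutation is cycled so that at
every piece position the 10 composites carry material from 10 pairwise
distinct donors, and consecutive pieces within one composite come from
different donors (both properties are asserted on every build).  Hence no
two composites share more than one co-located piece by construction, and
a reported segment longer than 0.02 cM (strict inequality) among them is a
false positive.  Outside the segment each composite carries its
first-piece donor's haplotypes unchanged; the backbone choice is
immaterial to scoring (only segment SNPs are counted) but is deterministic.

Detection for the FPR runs on a panel holding only the 10 composites: the
direct matcher needs no surrounding cohort, unlike frequency-model callers
that require population haplotype context.

## Detector

Seed-and-extend over all cross-sample haplotype pairs:

* windows of `effective_word = min(word_size_snps, min_snps)` consecutive
  alleles (stride 1, exact uint64 content keys) are grouped per site
  column; haplotypes sharing any aligned window become candidate pairs.
  Clamping the seed width to `min_snps` guarantees that every run long
  enough to be reportable contains a seed, so hashing can never lose a
  qualifying segment;
* with `max_mismatch_snps = 0`, each candidate pair's maximal runs of
  identical alleles are enumerated exactly — the output equals the
  brute-force oracle after thresholding, by construction;
* with a positive mismatch budget, maximal windows containing at most
  that many mismatching sites *and* at least one full seed word are
  reported, with overlapping reports merged per haplotype pair.  (With a
  zero budget, runs separated by a single mismatch are deliberately not
  merged, preserving oracle equality.)

Reported segments must span `min_length_cm` (default 0.1 cM, the
minimum-length setting used when hunting small segments) and contain
`min_snps` sites (default 10, this package's own floor).  A segment's cM
span is measured between its first and last site, which slightly
under-states the covering interval; the strict `> 0.02 cM` false-positive
rule therefore errs conservative.  Word size defaults to 16 SNPs and is
capped at 63 (exact bit-packed keys).

Power and FPR scoring first merge haplotype-level segments into
individual-pair unions (any of the four haplotype pairings counts), then
count covered SNPs clipped to the truth/composite interval.  Aggregates
are unweighted means over (region, pair) records; a SNP-weighted mean is
available (`aggregate_power(..., weighted=True)`).

## Genotype error and power

Spiking copies the *assayed* haplotype, so error present in the panel
before the spike leaves the truth pair byte-identical and cannot degrade
power.  Experiments therefore expose `post_spike_error_rate`: independent
per-allele flips applied to the region panels after spiking, modeling
assay noise hitting the two individuals independently.  With exact
matching, error fragments dense segments into sub-threshold runs; density
comparisons under error are run with a small mismatch budget
(`max_mismatch_snps = 2`), as matchers designed for real data tolerate
isolated mismatches during extension.

## Null-calibration conditions

The LD-free null panel uses 100 samples, 200 sites/cM, `maf_min = 0.2`.
The spectrum choice is substantive, not cosmetic.  For two unrelated
haplotypes the per-site agreement probability is
`p = 1 - 2E[f] + 2E[f^2]`; under the 1/f spectrum truncated at 0.05,
`p ~ 0.72`, and chance runs of the ~20 identical SNPs that fill 0.1 cM at
this density occur at rate `~p^20 ~ 1e-3` per site — yielding a *genuine*
chance-identity FPR near 0.04.  This is the same mechanism that makes
direct haplotype matching error-prone on rare-variant-dense sequence
data.  Truncating at 0.2 gives `p ~ 0.57` and a chance-run rate of
`~1e-5`, so the calibration isolates algorithmic false positives;
measured FPR is ~1e-3.  Both regimes are real; the calibration uses the
common-variant one and this note records the other.

The null must also be built on an **LD-free** panel.  On a founder-mosaic
panel the composite guarantee ("10 distinct donors per piece position")
does not imply absence of sharing: distinct donors routinely copy the same
founder over long tracts, so composite pairs carry genuine identity that
scores as a false positive (measured FPR can reach ~0.4 with 100
founders).  Real panels sit between the two extremes — their background
sharing is what the composite design was invented to control for — but a
100-founder mosaic grossly overstates it.

## Problem sizes

Test and script runs are scaled to single-CPU desk use, chosen as the
package's own defaults for its checks: oracle-equivalence sweeps use 200
panels of 10 samples x 300 sites; calibration experiments use a 50 cM
chromosome, 20 samples (10 pairs), 10–20 regions; the null uses 100
donors, 10–20 regions x 45 composite pairs; the density sweep thins one
200 sites/cM panel to 25/50/100/200.  The canonical full design (100
regions x 30 pairs) runs through the same code paths via the defaults of
`ExperimentConfig`.

## Numerical and degenerate-input choices

* Determinism: every stage derives child seeds from one `SeedSequence`;
  identical config + seed reproduces panels bit-for-bit and report files
  byte-for-byte.  Floats in text outputs are written with full `repr`
  precision so segment TSVs round-trip losslessly.
* Ties in the map (zero-recombination stretches) are legal (cM
  non-decreasing); site bp positions must strictly increase.
* `thin_panel` with the target equal to the current density returns an
  identical panel; targets above it are an error.
* Empty panels (0 sites) load validly and fail fast downstream.
* Region choice requires the chromosome to be at least one region long.

## Known limitations

* The founder-mosaic background is stationary and uniform; real genomes
  have hotspots, variable map density, and population structure.
* The built-in matcher models the direct-matching family of detectors
  only; probabilistic (HMM) callers are supported solely through file
  import, and their score thresholds are applied as an import-time filter,
  not reimplemented.
* Phasing is assumed perfect; phase-switch errors, a major practical
  issue, are out of scope.
* Power at very low density is partly carried by chance extension into
  background sharing — visible in the per-SNP-count curves, and a real
  phenomenon of direct matchers, but it means low-density power figures
  are generous for this detector class.
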