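# File formats

## Phased VCF

Single-chromosome VCF 4.x with phased diploid `GT` (`a|b`).  Unphased
separators (`/`) and missing alleles (`.`) are errors; multi-allelic
records are skipped with a warning.  The writer emits a minimal header
(`##contig`, `GT` format) readable by standard tools.

## Genetic maps

Whitespace tables, dialect auto-detected by column count; one optional
header line is tolerated.

| dialect | columns |
|---|---|
| 3-column | `chrom  bp  cM` |
| PLINK `.map` | `chrom  id  cM  bp` |

## Native segment TSV

Tab-separated, one segment per row, header required.  `hap_*` and `score`
use `.` when absent; floats carry full precision so files round-trip
losslessly.

| column | meaning |
|---|---|
| `sample_i`, `sample_j` | sample IDs, ordered by panel position |
| `hap_i`, `hap_j` | haplotype index 0/1, or `.` for pair-merged segments |
| `chrom` | chromosome label |
| `start_bp`, `end_bp` | bp of first and last covered site |
| `start_site`, `end_site` | half-open 0-based site-index range |
| `start_cm`, `end_cm` | cM of first and last covered site (truth segments: the design interval) |
| `n_snps` | covered site count |
| `score` | detector score or `.` |
| `origin` | `truth`, `detected`, or `imported` |

## Imported dialects (`parse_external_segments`)

### `germline_match`

Whitespace columns, GERMLINE `.match` layout.  Sample IDs may carry a
haplotype tag (`ID.0` / `ID.1`).  The bp span is closed; site indices are
resolved against the panel and cM positions via the genetic map.

| # | column |
|---|---|
| 0, 1 | family and sample ID of individual 1 |
| 2, 3 | family and sample ID of individual 2 |
| 4 | chromosome |
| 5, 6 | start bp, end bp |
| 7, 8 | first / last SNP identifier (ignored) |
| 9 | SNP count (ignored; recomputed from the panel) |
| 10, 11 | length and unit (ignored; recomputed from the map) |
| 12+ | extra columns ignored |

### `fastibd`

Beagle-fastIBD-style pairwise list; the site span is half-open.

| # | column |
|---|---|
| 0, 1 | sample IDs |
| 2, 3 | start site index, end site index (half-open) |
| 4 | score (smaller = stronger support) |

`score_threshold` keeps only segments with `score <= threshold` (the
conventional default for such callers is 1e-8).
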