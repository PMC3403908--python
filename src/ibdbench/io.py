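"""Readers and writers for the formats the pipeline touches.

* phased single-chromosome VCF (read via pysam, written as plain text);
* genetic maps: 3-column ``chrom bp cM`` tables and the PLINK ``.map``
  dialect (``chrom id cM bp``), auto-detected by column count;
* the native IBD-segment TSV (lossless round trip).

Missing genotype calls and unphased separators are rejected outright — the
evaluation is defined over fully called, phased haplotypes.  Multi-allelic
sites are dropped with a warning.
"""

from __future__ import annotations

import logging

import numpy as np
import pysam

from .core import (
    GeneticMap,
    HaplotypePanel,
    IBDSegment,
    MapError,
    PanelError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_genetic_map",
    "write_genetic_map",
    "read_phased_vcf",
    "write_phased_vcf",
    "read_segments",
    "write_segments",
]


# ---------------------------------------------------------------------------
# genetic maps
# ---------------------------------------------------------------------------

def read_genetic_map(path, chrom: str | None = None) -> GeneticMap:
    """Read a genetic map from a whitespace table.

    Two dialects, auto-detected by column count:

    * 3 columns: ``chrom  bp  cM``
    * 4 columns (PLINK ``.map``): ``chrom  id  cM  bp``

    A single non-numeric header line is tolerated.  ``chrom`` filters a
    multi-chromosome file down to one chromosome; without it the file must
    contain exactly one chromosome.
    """
    rows: list[tuple[str, int, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields or fields[0].startswith("#"):
                continue
            try:
                if len(fields) == 3:
                    rows.append((fields[0], int(fields[1]), float(fields[2])))
                elif len(fields) == 4:
                    rows.append((fields[0], int(fields[3]), float(fields[2])))
                else:
                    raise ValueError("expected 3 or 4 columns")
            except ValueError:
                if lineno == 1:  # header line
                    continue
                raise MapError(f"{path}: malformed map line {lineno}: {line!r}")
    if chrom is not None:
        rows = [r for r in rows if r[0] == chrom]
    chroms = {r[0] for r in rows}
    if len(chroms) > 1:
        raise MapError(f"{path}: multiple chromosomes {sorted(chroms)}; pass chrom=")
    if not rows:
        raise MapError(f"{path}: no usable map rows")
    rows.sort(key=lambda r: r[1])
    return GeneticMap(
        chrom=rows[0][0],
        bp=np.array([r[1] for r in rows], dtype=np.int64),
        cm=np.array([r[2] for r in rows], dtype=np.float64),
    )


def write_genetic_map(gmap: GeneticMap, path, dialect: str = "tsv") -> None:
    """Write a map in the 3-column (``tsv``) or PLINK (``plink``) dialect."""
    with open(path, "w") as fh:
        if dialect == "tsv":
            for b, c in zip(gmap.bp, gmap.cm):
                fh.write(f"{gmap.chrom}\t{int(b)}\t{float(c)!r}\n")
        elif dialect == "plink":
            for i, (b, c) in enumerate(zip(gmap.bp, gmap.cm)):
                fh.write(f"{gmap.chrom}\tpt{i}\t{float(c)!r}\t{int(b)}\n")
        else:
            raise ValueError(f"unknown map dialect {dialect!r}")


# ---------------------------------------------------------------------------
# phased VCF
# ---------------------------------------------------------------------------

def read_phased_vcf(path, gmap: GeneticMap | None = None) -> HaplotypePanel:
    """Load a phased, fully called, single-chromosome VCF into a panel.

    Multi-allelic records are skipped with a warning.  Unphased ("/") or
    missing (".") genotypes raise :class:`PanelError` — no imputation.  cM
    positions come from ``gmap`` when given, else from a uniform 1 cM/Mb
    assumption.
    """
    bps: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    cols: list[np.ndarray] = []
    chrom: str | None = None
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            if chrom is None:
                chrom = rec.chrom
            elif rec.chrom != chrom:
                raise PanelError(
                    f"{path}: multiple chromosomes ({chrom}, {rec.chrom})")
            if rec.alts is None or len(rec.alts) != 1:
                logger.warning(
                    "%s: skipping non-biallelic site %s:%d", path, rec.chrom, rec.pos)
                continue
            col = np.empty(2 * len(samples), dtype=np.uint8)
            for k, sample in enumerate(samples):
                sv = rec.samples[sample]
                gt = sv["GT"]
                if gt is None or any(a is None for a in gt):
                    raise PanelError(
                        f"{path}: missing genotype for {sample} at "
                        f"{rec.chrom}:{rec.pos}")
                if len(gt) != 2:
                    raise PanelError(
                        f"{path}: non-diploid genotype for {sample} at "
                        f"{rec.chrom}:{rec.pos}")
                if not sv.phased:
                    raise PanelError(
                        f"{path}: unphased genotype for {sample} at "
                        f"{rec.chrom}:{rec.pos}")
                col[2 * k] = gt[0]
                col[2 * k + 1] = gt[1]
            bps.append(rec.pos)
            refs.append(rec.ref or "N")
            alts.append(rec.alts[0])
            cols.append(col)
    if chrom is None:
        chrom = "1"
    bp = np.array(bps, dtype=np.int64)
    if gmap is not None:
        cm = gmap.interpolate(bp).astype(np.float64)
    else:
        cm = bp.astype(np.float64) * 1e-6
    H = (np.stack(cols, axis=1) if cols
         else np.zeros((2 * len(samples), 0), dtype=np.uint8))
    return HaplotypePanel(
        chrom=chrom,
        samples=samples,
        bp=bp,
        cm=cm,
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        haplotypes=H,
        gmap=gmap,
    )


def write_phased_vcf(panel: HaplotypePanel, path) -> None:
    """Write a panel as a minimal phased VCF 4.2 text file."""
    contig_len = int(panel.bp[-1]) + 1 if panel.n_sites else 1
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={panel.chrom},length={contig_len}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(panel.samples) + "\n")
        H = panel.haplotypes
        for j in range(panel.n_sites):
            gts = "\t".join(
                f"{H[2 * k, j]}|{H[2 * k + 1, j]}"
                for k in range(panel.n_samples)
            )
            fh.write(
                f"{panel.chrom}\t{int(panel.bp[j])}\t.\t{panel.ref[j]}\t"
                f"{panel.alt[j]}\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# segment TSV
# ---------------------------------------------------------------------------

_SEGMENT_COLUMNS = [
    "sample_i", "sample_j", "hap_i", "hap_j", "chrom",
    "start_bp", "end_bp", "start_site", "end_site",
    "start_cm", "end_cm", "n_snps", "score", "origin",
]


def _fmt_opt(x) -> str:
    return "." if x is None else repr(float(x)) if isinstance(x, float) else str(x)


def write_segments(segments, path) -> None:
    """Write segments as TSV (one row each, ``.`` for absent hap/score).

    Floats are written with full precision so that
    ``read_segments(write_segments(x)) == x``.
    """
    with open(path, "w") as fh:
        fh.write("\t".join(_SEGMENT_COLUMNS) + "\n")
        for s in segments:
            fh.write("\t".join([
                s.sample_i, s.sample_j,
                _fmt_opt(s.hap_i), _fmt_opt(s.hap_j),
                s.chrom,
                str(s.start_bp), str(s.end_bp),
                str(s.start_site), str(s.end_site),
                repr(float(s.start_cm)), repr(float(s.end_cm)),
                str(s.n_snps),
                _fmt_opt(s.score),
                s.origin,
            ]) + "\n")


def read_segments(path) -> list[IBDSegment]:
    """Read the native segment TSV written by :func:`write_segments`."""
    segments: list[IBDSegment] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _SEGMENT_COLUMNS:
            raise ValueError(f"{path}: unexpected segment TSV header")
        for lineno, line in enumerate(fh, 2):
            f = line.rstrip("\n").split("\t")
            if len(f) != len(_SEGMENT_COLUMNS):
                raise ValueError(f"{path}: malformed segment line {lineno}")
            segments.append(IBDSegment(
                sample_i=f[0], sample_j=f[1],
                hap_i=None if f[2] == "." else int(f[2]),
                hap_j=None if f[3] == "." else int(f[3]),
                chrom=f[4],
                start_bp=int(f[5]), end_bp=int(f[6]),
                start_site=int(f[7]), end_site=int(f[8]),
                start_cm=float(f[9]), end_cm=float(f[10]),
                n_snps=int(f[11]),
                score=None if f[12] == "." else float(f[12]),
                origin=f[13],
            ))
    return segments
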