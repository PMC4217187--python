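"""Genome coordinate model: gene annotations, SNP loci, distances and 1-Mb windows.

Internal convention: 1-based, fully-closed intervals (the dbSNP/GTF
convention). BED input is converted at the boundary. Windows are 0-based
half-open 1-Mb bins, ``[k*10^6, (k+1)*10^6)``, so a 1-based position ``p``
falls in bin ``(p - 1) // 10^6``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

WINDOW_SIZE = 1_000_000

_RSID_RE = re.compile(r"rs\d+\Z")


class InputFormatError(ValueError):
    """A record in an input file violates its declared format."""


def normalize_chrom(name: str) -> str:
    """Normalize a chromosome name to the ``chrN`` dialect (``1`` -> ``chr1``)."""
    name = name.strip()
    if not name:
        raise InputFormatError("empty chromosome name")
    if name.lower().startswith("chr"):
        return "chr" + name[3:]
    return "chr" + name


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene: stable identifier, display symbol and a 1-based closed interval."""

    gene_id: str
    symbol: str
    chrom: str
    start: int
    end: int
    strand: str = "unknown"

    def __post_init__(self) -> None:
        if not self.chrom:
            raise InputFormatError("gene %r has an empty chromosome" % self.gene_id)
        if self.start < 1 or self.end < 1:
            raise InputFormatError(
                "gene %s has non-positive coordinates" % self.gene_id
            )
        if self.start > self.end:
            raise InputFormatError(
                "gene %s has start > end (%d > %d)" % (self.gene_id, self.start, self.end)
            )
        if self.strand not in ("+", "-", "unknown"):
            raise InputFormatError("gene %s has invalid strand %r" % (self.gene_id, self.strand))

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class SnpLocus:
    """A dbSNP-style locus: rsID, 1-based position and intergenic status."""

    rsid: str
    chrom: str
    position: int
    is_intergenic: bool = True

    def __post_init__(self) -> None:
        if not _RSID_RE.match(self.rsid):
            raise InputFormatError("invalid rsID %r (expected rs<digits>)" % self.rsid)
        if not self.chrom:
            raise InputFormatError("SNP %s has an empty chromosome" % self.rsid)
        if self.position < 1:
            raise InputFormatError("SNP %s has non-positive position" % self.rsid)


@dataclass(frozen=True, order=True)
class GenomicWindow:
    """A 1-Mb genomic bin: spans [bin_index*10^6, (bin_index+1)*10^6) 0-based."""

    chrom: str
    bin_index: int

    def __post_init__(self) -> None:
        if self.bin_index < 0:
            raise InputFormatError("negative bin index %d" % self.bin_index)

    def label(self) -> str:
        """Human-readable form used in output tables, e.g. ``chr1:11M-12M``."""
        return f"{self.chrom}:{self.bin_index}M-{self.bin_index + 1}M"


def genomic_distance(snp: SnpLocus, gene: GeneAnnotation) -> Optional[int]:
    """Number of intervening base pairs between a SNP and a gene.

    Returns ``None`` (the undefined marker) when the two lie on different
    chromosomes, ``0`` when the SNP position falls inside the gene body, and
    otherwise the minimum absolute difference between the SNP position and
    the nearer interval boundary.
    """
    if snp.chrom != gene.chrom:
        return None
    if gene.start <= snp.position <= gene.end:
        if snp.is_intergenic:
            logger.warning(
                "SNP %s flagged intergenic but lies inside gene %s", snp.rsid, gene.gene_id
            )
        return 0
    return min(abs(snp.position - gene.start), abs(snp.position - gene.end))


def window_of(chrom: str, position: int, resolution: int = WINDOW_SIZE) -> GenomicWindow:
    """The 1-Mb window containing a 1-based position."""
    if position < 1:
        raise InputFormatError("position must be >= 1, got %d" % position)
    return GenomicWindow(chrom, (position - 1) // resolution)


def windows_of_gene(gene: GeneAnnotation, resolution: int = WINDOW_SIZE) -> list[GenomicWindow]:
    """All 1-Mb windows overlapped by the gene body, in genomic order."""
    first = (gene.start - 1) // resolution
    last = (gene.end - 1) // resolution
    return [GenomicWindow(gene.chrom, b) for b in range(first, last + 1)]


class GeneIndex:
    """Interval index over a gene set, for overlap queries and intergenic checks."""

    def __init__(self, genes: Iterable[GeneAnnotation]):
        self.genes = list(genes)
        self._trees: dict[str, IntervalTree] = {}
        for g in self.genes:
            # closed interval [start, end] -> half-open [start, end + 1)
            self._trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end + 1, g)

    def overlapping(self, chrom: str, position: int) -> list[GeneAnnotation]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted((iv.data for iv in tree.at(position)), key=lambda g: g.gene_id)

    def is_intergenic(self, chrom: str, position: int) -> bool:
        return not self.overlapping(chrom, position)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_GTF_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _infer_format(path: Path, choices: dict[str, str]) -> str:
    suffix = path.suffix.lower().lstrip(".")
    if suffix in choices:
        return choices[suffix]
    raise InputFormatError(
        "cannot infer format of %s; pass format= explicitly" % path.name
    )


def read_annotations(path, format: Optional[str] = None) -> list[GeneAnnotation]:
    """Read gene annotations from BED4+ (0-based half-open) or GTF (gene features).

    Coordinates are normalized to 1-based closed intervals. Duplicate
    ``gene_id`` values raise; an unparseable line raises with its number.
    """
    path = Path(path)
    fmt = (format or _infer_format(path, {"bed": "BED", "gtf": "GTF", "gff": "GTF"})).upper()
    genes: list[GeneAnnotation] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            try:
                gene = _parse_bed_line(line) if fmt == "BED" else _parse_gtf_line(line)
            except InputFormatError as exc:
                raise InputFormatError(f"{path.name}:{lineno}: {exc}") from None
            if gene is None:  # non-gene GTF feature
                continue
            if gene.gene_id in seen:
                raise InputFormatError(
                    f"{path.name}:{lineno}: duplicate gene_id {gene.gene_id!r}"
                )
            seen.add(gene.gene_id)
            genes.append(gene)
    return genes


def _parse_bed_line(line: str) -> GeneAnnotation:
    fields = line.split("\t")
    if len(fields) < 4:
        raise InputFormatError("BED4+ requires at least 4 columns")
    chrom, start, end, name = fields[0], fields[1], fields[2], fields[3]
    strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else "unknown"
    # optional 7th column carries a display symbol distinct from the name
    symbol = fields[6] if len(fields) >= 7 and fields[6] else name
    try:
        start_i, end_i = int(start), int(end)
    except ValueError:
        raise InputFormatError("non-integer coordinates %r/%r" % (start, end)) from None
    # BED is 0-based half-open; internal is 1-based closed.
    return GeneAnnotation(
        gene_id=name, symbol=symbol, chrom=normalize_chrom(chrom),
        start=start_i + 1, end=end_i, strand=strand,
    )


def _parse_gtf_line(line: str) -> Optional[GeneAnnotation]:
    fields = line.split("\t")
    if len(fields) < 9:
        raise InputFormatError("GTF requires 9 columns")
    if fields[2] != "gene":
        return None
    attrs = dict(_GTF_ATTR_RE.findall(fields[8]))
    if "gene_id" not in attrs:
        raise InputFormatError("gene feature without gene_id attribute")
    try:
        start_i, end_i = int(fields[3]), int(fields[4])
    except ValueError:
        raise InputFormatError("non-integer coordinates") from None
    strand = fields[6] if fields[6] in ("+", "-") else "unknown"
    return GeneAnnotation(
        gene_id=attrs["gene_id"],
        symbol=attrs.get("gene_name", attrs["gene_id"]),
        chrom=normalize_chrom(fields[0]),
        start=start_i, end=end_i, strand=strand,
    )


def write_annotations_bed(genes: Iterable[GeneAnnotation], path) -> None:
    """Write genes as BED6+1 (0-based half-open, symbol in the 7th column),
    the inverse of the BED reader."""
    with open(path, "w") as fh:
        for g in genes:
            strand = g.strand if g.strand in ("+", "-") else "."
            fh.write(f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.gene_id}\t0\t{strand}"
                     f"\t{g.symbol}\n")


def read_snps(path, format: Optional[str] = None,
              gene_index: Optional[GeneIndex] = None) -> list[SnpLocus]:
    """Read SNP loci from a header-bearing TSV (rsid/chrom/pos/is_intergenic) or VCF.

    VCF carries no intergenic flag; if ``gene_index`` is given the flag is
    computed from gene overlap, otherwise VCF records default to intergenic.
    """
    path = Path(path)
    fmt = (format or _infer_format(path, {"tsv": "TSV", "txt": "TSV", "vcf": "VCF"})).upper()
    if fmt == "TSV":
        return _read_snps_tsv(path)
    if fmt == "VCF":
        return _read_snps_vcf(path, gene_index)
    raise InputFormatError("unknown SNP format %r" % fmt)


def _read_snps_tsv(path: Path) -> list[SnpLocus]:
    snps: list[SnpLocus] = []
    with open(path) as fh:
        header = fh.readline()
        if not header:
            return snps
        cols = header.rstrip("\n").split("\t")
        try:
            idx = {name: cols.index(name) for name in ("rsid", "chrom", "pos")}
        except ValueError:
            raise InputFormatError(
                f"{path.name}:1: expected header with rsid/chrom/pos columns"
            ) from None
        flag_idx = cols.index("is_intergenic") if "is_intergenic" in cols else None
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            try:
                flag = True
                if flag_idx is not None:
                    flag = fields[flag_idx].strip().lower() in ("1", "true", "yes")
                snps.append(SnpLocus(
                    rsid=fields[idx["rsid"]],
                    chrom=normalize_chrom(fields[idx["chrom"]]),
                    position=int(fields[idx["pos"]]),
                    is_intergenic=flag,
                ))
            except (IndexError, ValueError, InputFormatError) as exc:
                raise InputFormatError(f"{path.name}:{lineno}: {exc}") from None
    return snps


def _read_snps_vcf(path: Path, gene_index: Optional[GeneIndex]) -> list[SnpLocus]:
    from cyvcf2 import VCF

    snps: list[SnpLocus] = []
    for variant in VCF(str(path)):
        rsid = variant.ID
        if rsid is None or not _RSID_RE.match(rsid):
            continue
        chrom = normalize_chrom(variant.CHROM)
        pos = variant.POS
        flag = gene_index.is_intergenic(chrom, pos) if gene_index is not None else True
        snps.append(SnpLocus(rsid=rsid, chrom=chrom, position=pos, is_intergenic=flag))
    return snps


def write_snps_tsv(snps: Iterable[SnpLocus], path) -> None:
    with open(path, "w") as fh:
        fh.write("rsid\tchrom\tpos\tis_intergenic\n")
        for s in snps:
            fh.write(f"{s.rsid}\t{s.chrom}\t{s.position}\t{int(s.is_intergenic)}\n")
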