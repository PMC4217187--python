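"""HiC contact-map loading and spatial (3D) gene scoring.

The map is the normalized output of a HiC experiment binned at 1 Mb: for
each pair of genomic windows, the log2 ratio of observed over expected read
counts. A gene's spatial association with a SNP is the contact log-ratio
between the SNP's window and the gene's window(s); the candidate genes are
then ranked by that score, strongest contact first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

from .genome import (
    GeneAnnotation,
    GenomicWindow,
    SnpLocus,
    WINDOW_SIZE,
    normalize_chrom,
    window_of,
    windows_of_gene,
)
from .ranking import DESCENDING, RankedList, fractional_rank


class ContactMapFormatError(ValueError):
    """The bin-pair file violates the contact-map format or symmetry."""


_Key = tuple[tuple[str, int], tuple[str, int]]


def _key(a: GenomicWindow, b: GenomicWindow) -> _Key:
    ka, kb = (a.chrom, a.bin_index), (b.chrom, b.bin_index)
    return (ka, kb) if ka <= kb else (kb, ka)


@dataclass
class ContactMap:
    """Symmetric mapping (window, window) -> log2 observed/expected contact ratio."""

    resolution: int = WINDOW_SIZE
    _entries: dict[_Key, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")

    def set(self, a: GenomicWindow, b: GenomicWindow, value: float,
            tol: float = 1e-9, force: bool = False) -> None:
        """Store a symmetric entry; ``force`` overwrites (used for planted contacts)."""
        if not math.isfinite(value):
            raise ContactMapFormatError(
                "non-finite contact score for %s/%s" % (a.label(), b.label())
            )
        k = _key(a, b)
        existing = None if force else self._entries.get(k)
        if existing is not None and abs(existing - value) > tol:
            raise ContactMapFormatError(
                "conflicting symmetric entries for %s/%s: %r vs %r"
                % (a.label(), b.label(), existing, value)
            )
        self._entries[k] = value

    def get(self, a: GenomicWindow, b: GenomicWindow) -> Optional[float]:
        return self._entries.get(_key(a, b))

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[tuple[GenomicWindow, GenomicWindow, float]]:
        for ((ca, ba), (cb, bb)), v in self._entries.items():
            yield GenomicWindow(ca, ba), GenomicWindow(cb, bb), v


def load_contact_map(path, resolution: int = WINDOW_SIZE) -> ContactMap:
    """Load a bin-pair TSV: chromA, binA, chromB, binB, log2ratio.

    A header line is optional. Symmetric duplicates must agree within 1e-9;
    disagreement or a non-numeric score is a format error.
    """
    cmap = ContactMap(resolution=resolution)
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[:2] == ["chromA", "binA"]:
                continue
            if len(fields) < 5:
                raise ContactMapFormatError(
                    f"{path.name}:{lineno}: expected 5 columns, got {len(fields)}"
                )
            try:
                a = GenomicWindow(normalize_chrom(fields[0]), int(fields[1]))
                b = GenomicWindow(normalize_chrom(fields[2]), int(fields[3]))
                value = float(fields[4])
            except ValueError as exc:
                raise ContactMapFormatError(f"{path.name}:{lineno}: {exc}") from None
            try:
                cmap.set(a, b, value)
            except ContactMapFormatError as exc:
                raise ContactMapFormatError(f"{path.name}:{lineno}: {exc}") from None
    return cmap


def write_contact_map(cmap: ContactMap, path) -> None:
    """Write the canonical (sorted) bin-pair TSV with a header line."""
    rows = sorted(cmap, key=lambda t: (t[0], t[1]))
    with open(path, "w") as fh:
        fh.write("chromA\tbinA\tchromB\tbinB\tlog2ratio\n")
        for a, b, v in rows:
            fh.write(f"{a.chrom}\t{a.bin_index}\t{b.chrom}\t{b.bin_index}\t{v:.6f}\n")


def gene_contact_score(snp: SnpLocus, gene: GeneAnnotation,
                       cmap: ContactMap) -> Optional[float]:
    """Contact log-ratio between the SNP's window and the gene.

    A gene spanning several windows takes the maximum entry; ``None`` (the
    undefined marker) when no overlapped window of the gene has an entry
    against the SNP's window. Missing data is not an error.
    """
    snp_win = window_of(snp.chrom, snp.position, cmap.resolution)
    scores = [
        v for w in windows_of_gene(gene, cmap.resolution)
        if (v := cmap.get(snp_win, w)) is not None
    ]
    return max(scores) if scores else None


def best_contact_window(snp: SnpLocus, gene: GeneAnnotation,
                        cmap: ContactMap) -> GenomicWindow:
    """The gene window realizing `gene_contact_score` (first window if none)."""
    snp_win = window_of(snp.chrom, snp.position, cmap.resolution)
    windows = windows_of_gene(gene, cmap.resolution)
    scored = [(cmap.get(snp_win, w), w) for w in windows]
    defined = [(v, w) for v, w in scored if v is not None]
    if not defined:
        return windows[0]
    return max(defined, key=lambda t: t[0])[1]


def rank_by_contact(snp: SnpLocus, genes: Iterable[GeneAnnotation],
                    cmap: ContactMap) -> RankedList:
    """Fractional ranks of candidate genes by descending contact with the SNP.

    Genes with no contact entry share the bottom tie block.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("candidate gene set is empty")
    scores = {g.gene_id: gene_contact_score(snp, g, cmap) for g in genes}
    return fractional_rank(scores, direction=DESCENDING)
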