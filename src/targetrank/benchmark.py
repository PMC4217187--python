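"""Evaluation filters, eQTL gold-standard benchmarking and the discovery protocol.

The benchmark treats eQTL associations (SNP, target gene, p-value) as a
gold-standard proxy for SNP -> gene impact: for each gold instance it compares
the fractional rank the hybrid method gives the target gene with the rank
each single channel gives it; the hybrid "wins" against a channel when its
rank is strictly smaller. SNP pairs in tight LD (within a small proximity)
that received identical spatial and literature scores collapse to a single
evaluation instance so they are not double counted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .associations import AssociationRecord
from .genome import GeneAnnotation, SnpLocus, genomic_distance

#: Validation excludes SNP-proximal genes: the method targets long-range,
#: enhancer-like relationships, and at 1-Mb HiC resolution anything nearer
#: is unresolvable anyway.
DEFAULT_EXCLUSION_RADIUS_BP = 500_000

#: SNPs closer than this with identical channel scores count as one instance.
DEFAULT_MERGE_PROXIMITY_BP = 2_000


@dataclass(frozen=True)
class EqtlPair:
    """A gold-standard eQTL association between a SNP and a gene."""

    rsid: str
    gene_id: str
    p_value: float

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(
                f"eQTL p-value for {self.rsid}/{self.gene_id} outside (0, 1]"
            )


@dataclass(frozen=True)
class BenchmarkCase:
    """One gold instance: the target gene's scores and ranks in its universe."""

    rsid: str
    disease: str
    gene_id: str
    symbol: str
    snp_pos: int
    hic_log_ratio: Optional[float]
    lit_t: Optional[float]
    rank_gen_dist: Optional[float]
    rank_spatial: float
    rank_literature: float
    rank_hybrid: float
    universe_size: int


@dataclass
class BenchmarkResult:
    cases: list[BenchmarkCase]
    wins_vs_distance: int
    wins_vs_spatial: int
    wins_vs_literature: int
    n_instances: int
    pct_vs_distance: int
    unmatched_gold: list[EqtlPair] = field(default_factory=list)

    def summary(self) -> str:
        lines = [
            f"instances: {self.n_instances}",
            f"hybrid beats distance:   {self.wins_vs_distance}/{self.n_instances}"
            f" ({self.pct_vs_distance}%)",
            f"hybrid beats spatial:    {self.wins_vs_spatial}/{self.n_instances}",
            f"hybrid beats literature: {self.wins_vs_literature}/{self.n_instances}",
        ]
        if self.unmatched_gold:
            lines.append(
                "unmatched gold pairs: "
                + ", ".join(f"{p.rsid}/{p.gene_id}" for p in self.unmatched_gold)
            )
        return "\n".join(lines)


def validation_filter(
    snp: SnpLocus,
    candidates: Iterable[GeneAnnotation],
    exclusion_radius_bp: int = DEFAULT_EXCLUSION_RADIUS_BP,
) -> list[GeneAnnotation]:
    """Same-chromosome genes farther than the exclusion radius from the SNP."""
    kept = []
    for gene in candidates:
        d = genomic_distance(snp, gene)
        if d is not None and d > exclusion_radius_bp:
            kept.append(gene)
    return kept


def discovery_filter(
    records: Iterable[AssociationRecord],
    hic_threshold: float = 1.0,
    top_k: int = 10,
) -> list[AssociationRecord]:
    """Top cross-chromosome candidates with convincing HiC contact.

    ``records`` must be ranked in discovery mode. Keeps records whose gene
    lies on a different chromosome than the SNP and whose contact log-ratio
    exceeds the threshold, merges across diseases, and returns the ``top_k``
    by hybrid rank.
    """
    eligible = [
        r for r in records
        if r.gene_chrom != r.snp_chrom
        and r.hic_log_ratio is not None
        and r.hic_log_ratio > hic_threshold
    ]
    eligible.sort(key=lambda r: (r.rank_hybrid, r.rsid, r.gene_id, r.disease))
    return eligible[:top_k]


def _scores_equal(a: Optional[float], b: Optional[float]) -> bool:
    if a is None or (isinstance(a, float) and math.isnan(a)):
        return b is None or (isinstance(b, float) and math.isnan(b))
    if b is None or (isinstance(b, float) and math.isnan(b)):
        return False
    return a == b


def merge_equivalent_instances(
    cases: Sequence[BenchmarkCase],
    proximity_bp: int = DEFAULT_MERGE_PROXIMITY_BP,
) -> list[BenchmarkCase]:
    """Collapse near-duplicate instances from SNPs in tight LD.

    Cases sharing target gene and disease, with identical spatial and
    literature scores, whose SNPs lie within ``proximity_bp`` of each other,
    count as one instance (the first encountered is kept).
    """
    groups: list[list[BenchmarkCase]] = []
    for case in cases:
        placed = False
        for group in groups:
            rep = group[0]
            if (
                rep.gene_id == case.gene_id
                and rep.disease == case.disease
                and _scores_equal(rep.hic_log_ratio, case.hic_log_ratio)
                and _scores_equal(rep.lit_t, case.lit_t)
                and any(abs(m.snp_pos - case.snp_pos) <= proximity_bp for m in group)
            ):
                group.append(case)
                placed = True
                break
        if not placed:
            groups.append([case])
    return [g[0] for g in groups]


def case_from_record(record: AssociationRecord) -> BenchmarkCase:
    return BenchmarkCase(
        rsid=record.rsid, disease=record.disease, gene_id=record.gene_id,
        symbol=record.symbol, snp_pos=record.snp_pos,
        hic_log_ratio=record.hic_log_ratio, lit_t=record.lit_t,
        rank_gen_dist=record.rank_gen_dist, rank_spatial=record.rank_spatial,
        rank_literature=record.rank_literature, rank_hybrid=record.rank_hybrid,
        universe_size=record.universe_size,
    )


def benchmark(
    records: Sequence[AssociationRecord] | Sequence[BenchmarkCase],
    gold: Iterable[EqtlPair],
    merge: bool = True,
    proximity_bp: int = DEFAULT_MERGE_PROXIMITY_BP,
) -> BenchmarkResult:
    """Score the hybrid ranking against eQTL gold pairs matched on (rsid, gene).

    A win against a channel requires the hybrid rank to be *strictly*
    smaller than that channel's rank; ties count as no win. The headline
    percentage is truncated to a whole percent. Gold pairs absent from the
    record universe are reported as unmatched and excluded from counts.
    """
    gold = list(gold)
    gold_keys = {(p.rsid, p.gene_id) for p in gold}
    cases = [
        r if isinstance(r, BenchmarkCase) else case_from_record(r)
        for r in records
        if (r.rsid, r.gene_id) in gold_keys
    ]
    matched_keys = {(c.rsid, c.gene_id) for c in cases}
    unmatched = [p for p in gold if (p.rsid, p.gene_id) not in matched_keys]
    if merge:
        cases = merge_equivalent_instances(cases, proximity_bp)

    wins_d = sum(
        1 for c in cases
        if c.rank_gen_dist is not None and c.rank_hybrid < c.rank_gen_dist
    )
    wins_s = sum(1 for c in cases if c.rank_hybrid < c.rank_spatial)
    wins_l = sum(1 for c in cases if c.rank_hybrid < c.rank_literature)
    n = len(cases)
    pct = int(100 * wins_d / n) if n else 0
    return BenchmarkResult(
        cases=cases,
        wins_vs_distance=wins_d,
        wins_vs_spatial=wins_s,
        wins_vs_literature=wins_l,
        n_instances=n,
        pct_vs_distance=pct,
        unmatched_gold=unmatched,
    )


def read_gold_tsv(path) -> list[EqtlPair]:
    """Gold TSV with header rsid/gene_id/p_value."""
    import pandas as pd

    frame = pd.read_csv(path, sep="\t", comment="#", dtype={"gene_id": str})
    return [
        EqtlPair(row.rsid, str(row.gene_id), float(row.p_value))
        for row in frame.itertuples(index=False)
    ]


def write_gold_tsv(pairs: Iterable[EqtlPair], path) -> None:
    with open(path, "w") as fh:
        fh.write("rsid\tgene_id\tp_value\n")
        for p in pairs:
            fh.write(f"{p.rsid}\t{p.gene_id}\t{p.p_value:.3e}\n")
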