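"""Per SNP-disease candidate ranking across the three evidence channels.

For one (SNP, disease) pair and a candidate gene universe, each gene gets a
genomic-distance score (bp to the nearer gene boundary), a spatial score
(HiC contact log-ratio between 1-Mb windows) and a literature score (the
gene-disease t statistic). Each channel is converted to fractional ranks
over the same universe and fused into the hybrid rank: in validation mode
the product of all three ranks, in discovery mode (cross-chromosome work,
where linear distance is meaningless) the product of the spatial and
literature ranks only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .genome import GeneAnnotation, SnpLocus, genomic_distance, window_of
from .ranking import ASCENDING, DESCENDING, fractional_rank, hybrid_rank
from .spatial import ContactMap, best_contact_window, gene_contact_score

VALIDATION = "validation"
DISCOVERY = "discovery"


@dataclass(frozen=True)
class AssociationRecord:
    """One (SNP, disease, gene) candidate with channel scores and ranks."""

    rsid: str
    disease: str
    gene_id: str
    symbol: str
    snp_chrom: str
    snp_pos: int
    gene_chrom: str
    gene_window: str
    dist_bp: Optional[int]
    hic_log_ratio: Optional[float]
    lit_t: Optional[float]
    rank_gen_dist: Optional[float]
    rank_spatial: float
    rank_literature: float
    rank_hybrid: float
    universe_size: int


def rank_associations(
    snp: SnpLocus,
    disease: str,
    candidates: Sequence[GeneAnnotation],
    cmap: ContactMap,
    lit_scores: Mapping[str, Optional[float]],
    mode: str = VALIDATION,
) -> list[AssociationRecord]:
    """Rank a candidate universe for one (SNP, disease) pair.

    ``lit_scores`` maps gene_id to the disease's t-score (absent or ``None``
    means no literature evidence). ``candidates`` must already be filtered
    for the chosen mode (same-chromosome/500-kbp exclusion for validation;
    see `targetrank.benchmark.validation_filter`).
    """
    if not candidates:
        raise ValueError(
            f"empty candidate universe for {snp.rsid} / {disease}"
        )
    if mode not in (VALIDATION, DISCOVERY):
        raise ValueError("unknown mode %r" % mode)
    ids = [g.gene_id for g in candidates]
    dist = {g.gene_id: genomic_distance(snp, g) for g in candidates}
    hic = {g.gene_id: gene_contact_score(snp, g, cmap) for g in candidates}
    lit = {g.gene_id: lit_scores.get(g.gene_id) for g in candidates}

    r_spatial = fractional_rank(hic, direction=DESCENDING)
    r_lit = fractional_rank(lit, direction=DESCENDING)
    if mode == VALIDATION:
        r_dist = fractional_rank(dist, direction=ASCENDING)
        r_hybrid = hybrid_rank([r_dist, r_spatial, r_lit])
        dist_ranks = r_dist.as_dict()
    else:
        r_hybrid = hybrid_rank([r_spatial, r_lit])
        dist_ranks = {}

    spatial_ranks = r_spatial.as_dict()
    lit_ranks = r_lit.as_dict()
    hybrid_ranks = r_hybrid.as_dict()
    n = len(candidates)

    records = []
    for g in candidates:
        records.append(AssociationRecord(
            rsid=snp.rsid,
            disease=disease,
            gene_id=g.gene_id,
            symbol=g.symbol,
            snp_chrom=snp.chrom,
            snp_pos=snp.position,
            gene_chrom=g.chrom,
            gene_window=best_contact_window(snp, g, cmap).label(),
            dist_bp=dist[g.gene_id],
            hic_log_ratio=hic[g.gene_id],
            lit_t=lit[g.gene_id],
            rank_gen_dist=dist_ranks.get(g.gene_id),
            rank_spatial=spatial_ranks[g.gene_id],
            rank_literature=lit_ranks[g.gene_id],
            rank_hybrid=hybrid_ranks[g.gene_id],
            universe_size=n,
        ))
    records.sort(key=lambda r: (r.rank_hybrid, r.gene_id))
    return records


# Output table mirrors the validation-table layout: one row per candidate,
# channel scores then channel ranks then the hybrid rank and universe size.
_COLUMNS = [
    "rsid", "disease", "chrom", "location", "gene", "gene_id", "gene_chrom",
    "gene_window", "GD", "HiC", "Lit", "rD", "rHiC", "rL", "rHy", "Total",
]


def records_to_frame(records: Iterable[AssociationRecord]) -> pd.DataFrame:
    rows = [
        {
            "rsid": r.rsid, "disease": r.disease, "chrom": r.snp_chrom,
            "location": r.snp_pos, "gene": r.symbol, "gene_id": r.gene_id,
            "gene_chrom": r.gene_chrom, "gene_window": r.gene_window,
            "GD": r.dist_bp, "HiC": r.hic_log_ratio, "Lit": r.lit_t,
            "rD": r.rank_gen_dist, "rHiC": r.rank_spatial,
            "rL": r.rank_literature, "rHy": r.rank_hybrid,
            "Total": r.universe_size,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=_COLUMNS)


def frame_to_records(frame: pd.DataFrame) -> list[AssociationRecord]:
    records = []
    for row in frame.itertuples(index=False):
        records.append(AssociationRecord(
            rsid=row.rsid, disease=row.disease, gene_id=str(row.gene_id),
            symbol=row.gene, snp_chrom=row.chrom, snp_pos=int(row.location),
            gene_chrom=row.gene_chrom, gene_window=row.gene_window,
            dist_bp=None if pd.isna(row.GD) else int(row.GD),
            hic_log_ratio=None if pd.isna(row.HiC) else float(row.HiC),
            lit_t=None if pd.isna(row.Lit) else float(row.Lit),
            rank_gen_dist=None if pd.isna(row.rD) else float(row.rD),
            rank_spatial=float(row.rHiC),
            rank_literature=float(row.rL),
            rank_hybrid=float(row.rHy),
            universe_size=int(row.Total),
        ))
    return records


def write_records_tsv(records: Iterable[AssociationRecord], path,
                      header_lines: Sequence[str] = ()) -> None:
    frame = records_to_frame(records)
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        frame.to_csv(fh, sep="\t", index=False, float_format="%.6g", lineterminator="\n")


def read_records_tsv(path) -> list[AssociationRecord]:
    frame = pd.read_csv(path, sep="\t", comment="#")
    return frame_to_records(frame)
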