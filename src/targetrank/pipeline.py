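"""End-to-end orchestration: mine a corpus, rank candidates, assess recovery.

Thin glue over the per-stage modules so the CLI, the test-bench and the
synthetic recovery experiments all run through one code path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .associations import DISCOVERY, VALIDATION, AssociationRecord, rank_associations
from .benchmark import DEFAULT_EXCLUSION_RADIUS_BP, validation_filter
from .genome import GeneAnnotation, SnpLocus
from .litscore import (
    CooccurrenceCounts,
    GeneDiseaseScore,
    comention_counts,
    count_cooccurrences,
    score_all_pairs,
    snp_disease_relations,
)
from .mining import AnnotatedDocument, Document, GeneDictionary, annotate_corpus
from .spatial import ContactMap

logger = logging.getLogger(__name__)


@dataclass
class MiningResult:
    """Everything the literature stages derive from one corpus."""

    annotated: list[AnnotatedDocument]
    counts: CooccurrenceCounts
    scores: dict[tuple[str, str], GeneDiseaseScore]
    relations: set[tuple[str, str]]
    comentions: dict[tuple[str, str], int] = field(default_factory=dict)


def mine_corpus(
    documents: Sequence[Document],
    dictionary: GeneDictionary,
    catalog: Sequence[SnpLocus] | Mapping[str, SnpLocus],
    mesh_table: Mapping[str, Sequence[str]],
    subtree_prefix: str = "C04",
) -> MiningResult:
    """Annotate a corpus and compute every literature statistic in one pass."""
    annotated = annotate_corpus(documents, dictionary, catalog, mesh_table,
                                subtree_prefix)
    counts = count_cooccurrences(annotated)
    return MiningResult(
        annotated=annotated,
        counts=counts,
        scores=score_all_pairs(counts),
        relations=snp_disease_relations(annotated),
        comentions=comention_counts(annotated),
    )


def scores_for_disease(
    scores: Mapping[tuple[str, str], GeneDiseaseScore], disease: str,
) -> dict[str, float]:
    """gene_id -> t lookup for one disease (defined scores only)."""
    return {
        g: s.t for (g, d), s in scores.items() if d == disease and s.defined
    }


def rank_study(
    genes: Sequence[GeneAnnotation],
    snps: Sequence[SnpLocus],
    cmap: ContactMap,
    relations: set[tuple[str, str]],
    scores: Mapping[tuple[str, str], GeneDiseaseScore],
    mode: str = VALIDATION,
    exclusion_radius_bp: int = DEFAULT_EXCLUSION_RADIUS_BP,
) -> list[AssociationRecord]:
    """Rank candidates for every (SNP, disease) pair with a literature relation.

    Validation mode restricts the universe to same-chromosome genes beyond
    the exclusion radius; discovery mode ranks the whole gene universe (the
    cross-chromosome filter is applied downstream). SNPs with no disease
    relation are skipped with a warning.
    """
    records: list[AssociationRecord] = []
    for snp in sorted(snps, key=lambda s: s.rsid):
        diseases = sorted(d for (r, d) in relations if r == snp.rsid)
        if not diseases:
            logger.warning("skipping %s: no disease relation mined", snp.rsid)
            continue
        if mode == VALIDATION:
            candidates = validation_filter(snp, genes, exclusion_radius_bp)
        else:
            candidates = list(genes)
        if not candidates:
            raise ValueError(
                f"empty candidate universe for SNP {snp.rsid} in {mode} mode"
            )
        for disease in diseases:
            records.extend(rank_associations(
                snp, disease, candidates, cmap,
                scores_for_disease(scores, disease), mode,
            ))
    return records


def planted_recovery(
    study,
    records: Optional[Sequence[AssociationRecord]] = None,
    top_fraction: float = 0.05,
) -> tuple[int, int]:
    """How many planted targets the hybrid puts in the top fraction of candidates.

    Runs the full mine-and-rank pipeline on the study's rendered documents
    unless precomputed records are supplied. Returns (recovered, planted);
    a planted SNP whose disease relation failed to surface in the corpus
    counts as not recovered.
    """
    from .mining import build_dictionary

    if records is None:
        dictionary = build_dictionary((g.gene_id, [g.symbol]) for g in study.genes)
        mined = mine_corpus(study.documents, dictionary, study.snps,
                            study.mesh_table)
        records = rank_study(study.genes, study.snps, study.contact_map,
                             mined.relations, mined.scores, VALIDATION)
    by_key = {(r.rsid, r.disease, r.gene_id): r for r in records}
    recovered = 0
    for rsid, gene_id in study.planted_targets.items():
        disease = study.planted_diseases.get(rsid)
        rec = by_key.get((rsid, disease, gene_id))
        if rec is not None and rec.rank_hybrid <= top_fraction:
            recovered += 1
    return recovered, len(study.planted_targets)
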