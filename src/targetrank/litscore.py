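"""Literature association statistics over an annotated corpus.

The gene-disease association score is a one-sample t statistic comparing the
observed per-citation co-occurrence rate of a gene and a disease against the
rate expected under independence of the two concepts:

    x_bar = n_gd / N            observed P(gene, disease)
    mu    = (n_g / N)(n_d / N)  expected under independence
    s^2   = x_bar (1 - x_bar)   Bernoulli variance of the observed indicator
    t     = (x_bar - mu) / sqrt(s^2 / N)

where N is the corpus size and n_g, n_d, n_gd are citation-level counts
(a concept counts once per citation regardless of mention multiplicity).
t is positive when the pair co-occurs more often than chance, negative when
less often, and *undefined* when the pair never co-occurs — no evidence is
deliberately distinct from evidence of no association, so downstream ranking
can place no-evidence genes in the bottom tie block.

SNP-disease relations and SNP-gene co-mention counts are simple citation-level
set and count reductions over the same annotated corpus.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from .genome import GeneAnnotation, SnpLocus
from .mining import AnnotatedDocument

logger = logging.getLogger(__name__)


@dataclass
class CooccurrenceCounts:
    """Citation-level marginal and joint counts for genes and diseases."""

    N: int = 0
    n_g: Counter = field(default_factory=Counter)
    n_d: Counter = field(default_factory=Counter)
    n_gd: Counter = field(default_factory=Counter)  # keyed by (gene_id, disease)


@dataclass(frozen=True)
class GeneDiseaseScore:
    gene_id: str
    disease: str
    t: float
    defined: bool


def count_cooccurrences(annotated_docs: Iterable[AnnotatedDocument]) -> CooccurrenceCounts:
    """Document-level counts; each concept counts once per citation."""
    counts = CooccurrenceCounts()
    for doc in annotated_docs:
        counts.N += 1
        for g in doc.gene_ids:
            counts.n_g[g] += 1
        for d in doc.disease_terms:
            counts.n_d[d] += 1
        for g in doc.gene_ids:
            for d in doc.disease_terms:
                counts.n_gd[(g, d)] += 1
    return counts


def gene_disease_tscore(counts: CooccurrenceCounts, gene_id: str,
                        disease: str) -> GeneDiseaseScore:
    """The t statistic for one (gene, disease) pair; undefined when n_gd = 0."""
    if counts.N == 0:
        raise ValueError("cannot score against an empty corpus")
    n_gd = counts.n_gd.get((gene_id, disease), 0)
    if n_gd == 0:
        return GeneDiseaseScore(gene_id, disease, math.nan, defined=False)
    N = counts.N
    x_bar = n_gd / N
    # observed-minus-expected gap in integer arithmetic so that exact
    # independence (n_gd * N == n_g * n_d) yields exactly zero
    gap = (n_gd * N - counts.n_g[gene_id] * counts.n_d[disease]) / (N * N)
    s2 = x_bar * (1.0 - x_bar)
    if s2 == 0.0:
        # x_bar is 0 or 1 exactly; only x_bar == 1 reaches here (n_gd == N)
        t = 0.0 if gap == 0.0 else math.copysign(math.inf, gap)
    else:
        t = gap / math.sqrt(s2 / N)
    return GeneDiseaseScore(gene_id, disease, t, defined=True)


def score_all_pairs(counts: CooccurrenceCounts) -> dict[tuple[str, str], GeneDiseaseScore]:
    """t-scores for every pair with at least one co-occurrence."""
    return {
        (g, d): gene_disease_tscore(counts, g, d)
        for (g, d) in counts.n_gd
    }


def snp_disease_relations(
    annotated_docs: Iterable[AnnotatedDocument],
) -> set[tuple[str, str]]:
    """(rsid, disease) pairs co-occurring in at least one citation (set semantics)."""
    relations: set[tuple[str, str]] = set()
    for doc in annotated_docs:
        for rsid in doc.rsids:
            for disease in doc.disease_terms:
                relations.add((rsid, disease))
    return relations


@dataclass(frozen=True)
class AssociationStub:
    """A (SNP, disease, gene) candidate carrying its literature score."""

    rsid: str
    disease: str
    gene_id: str
    lit_t: Optional[float]  # None = no literature evidence for the pair


def assemble_associations(
    snp: SnpLocus,
    relations: set[tuple[str, str]],
    scores: Mapping[tuple[str, str], GeneDiseaseScore],
    genes: Iterable[GeneAnnotation],
) -> list[AssociationStub]:
    """Cartesian (snp, disease, gene) records over the SNP's related diseases.

    Each record carries the t-score of the underlying (gene, disease) pair;
    unscored genes carry ``None``. A SNP with no disease relation yields an
    empty list with a warning.
    """
    diseases = sorted(d for (r, d) in relations if r == snp.rsid)
    if not diseases:
        logger.warning("SNP %s has no disease relation in the corpus", snp.rsid)
        return []
    stubs = []
    for disease in diseases:
        for gene in genes:
            score = scores.get((gene.gene_id, disease))
            lit_t = score.t if score is not None and score.defined else None
            stubs.append(AssociationStub(snp.rsid, disease, gene.gene_id, lit_t))
    return stubs


def comention_counts(
    annotated_docs: Iterable[AnnotatedDocument],
) -> dict[tuple[str, str], int]:
    """Number of abstracts co-mentioning each (rsid, gene_id) pair (count >= 1)."""
    counts: Counter = Counter()
    for doc in annotated_docs:
        for rsid in doc.rsids:
            for gene_id in doc.gene_ids:
                counts[(rsid, gene_id)] += 1
    return dict(counts)


def filter_comentions(counts: Mapping[tuple[str, str], int],
                      min_count: int) -> dict[tuple[str, str], int]:
    """Keep pairs co-mentioned at least ``min_count`` times."""
    return {k: v for k, v in counts.items() if v >= min_count}
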