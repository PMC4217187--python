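"""Synthetic genomes, contact maps, corpora and eQTL truth with planted signal.

The generator emulates the statistical structure the ranking method assumes:

* a multi-chromosome gene layout with strictly intergenic SNPs;
* a symmetric 1-Mb contact map whose intra-chromosomal baseline decays
  linearly (in log2 units) with bin separation plus Gaussian noise, with
  planted long-range (and optionally trans) contacts overwriting the
  baseline;
* a citation corpus in which every concept (gene, rsID, disease) is
  mentioned independently at a background rate, except for planted
  gene-disease and SNP-disease pairs whose *joint* probability is multiplied
  by an enrichment factor (marginal rates are preserved by adjusting the
  conditional probabilities), and planted eQTL pairs whose gene is boosted
  in abstracts already mentioning the rsID;
* an eQTL truth table naming the planted target genes.

Everything is a pure function of the seed: two runs with the same config are
bit-identical. The planted scenario built by `auto_plant` places each target
gene on the SNP's chromosome, 2-12 Mb away and never the nearest gene, so
recovering it genuinely requires the spatial and literature channels.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .benchmark import EqtlPair, write_gold_tsv
from .genome import (
    GeneAnnotation,
    GeneIndex,
    GenomicWindow,
    SnpLocus,
    WINDOW_SIZE,
    window_of,
    windows_of_gene,
    write_annotations_bed,
    write_snps_tsv,
)
from .mining import (
    AnnotatedDocument,
    Document,
    MeshTerm,
    write_corpus_jsonl,
    write_dictionary_tsv,
    write_mesh_tsv,
)
from .spatial import ContactMap, write_contact_map

logger = logging.getLogger(__name__)

PlantedContact = tuple[tuple[str, int], tuple[str, int], float]


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset.

    ``background_mention_prob`` is the per-document probability that any one
    concept (gene, rsID or disease) is mentioned; ``enrichment_factor``
    multiplies the joint probability of every planted pair.
    ``contact_decay_rate`` is log2 units of contact lost per Mb of bin
    separation from a baseline of ``contact_baseline`` on the diagonal.
    """

    seed: int = 0
    n_chromosomes: int = 3
    chrom_length_bp: int = 60_000_000
    genes_per_chromosome: int = 80
    n_snps: int = 5
    n_diseases: int = 4
    n_documents: int = 2_000
    background_mention_prob: float = 0.01
    enrichment_factor: float = 15.0
    contact_decay_rate: float = 0.05
    contact_baseline: float = 2.0
    contact_noise_sd: float = 0.3
    planted_log_ratio: float = 6.0
    planted_contacts: list[PlantedContact] = field(default_factory=list)
    planted_eqtls: list[tuple[str, str]] = field(default_factory=list)
    planted_gene_disease: list[tuple[str, str]] = field(default_factory=list)
    planted_snp_disease: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.0 <= self.background_mention_prob <= 1.0:
            raise ValueError("background_mention_prob must lie in [0, 1]")
        if self.enrichment_factor < 0:
            raise ValueError("enrichment_factor must be non-negative")
        for name in ("n_chromosomes", "chrom_length_bp", "genes_per_chromosome",
                     "n_documents"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")

    @property
    def chromosomes(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    @property
    def bins_per_chromosome(self) -> int:
        return math.ceil(self.chrom_length_bp / WINDOW_SIZE)


@dataclass(frozen=True)
class MentionSample:
    """Ground-truth concept sets sampled for one synthetic citation."""

    doc_id: str
    gene_ids: frozenset[str]
    rsids: frozenset[str]
    diseases: frozenset[str]  # all sampled MeSH labels, cancer or not


@dataclass
class SyntheticStudy:
    """One fully generated dataset plus its planted truth."""

    config: SimConfig
    genes: list[GeneAnnotation]
    snps: list[SnpLocus]
    diseases: list[MeshTerm]
    mesh_table: dict[str, tuple[str, ...]]
    contact_map: ContactMap
    samples: list[MentionSample]
    documents: list[Document]
    gold: list[EqtlPair]
    planted_targets: dict[str, str]  # rsid -> gene_id
    planted_diseases: dict[str, str]  # rsid -> disease label

    @property
    def cancer_labels(self) -> set[str]:
        return {
            t.label for t in self.diseases
            if any(n.startswith("C04") for n in t.tree_numbers)
        }


def _streams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(6)
    names = ("genome", "plant", "contacts", "corpus", "render", "gold")
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

_MIN_GENE_BP = 10_000
_MAX_GENE_BP = 100_000


def generate_genome(config: SimConfig,
                    rng: Optional[np.random.Generator] = None,
                    ) -> tuple[list[GeneAnnotation], list[SnpLocus]]:
    """Non-overlapping genes on every chromosome and strictly intergenic SNPs.

    Each chromosome is divided into one slot per gene and a gene is placed at
    a random offset inside its slot, which guarantees disjoint gene bodies
    with intergenic gaps between them. SNPs are rejection-sampled until they
    overlap no gene body.
    """
    rng = rng if rng is not None else _streams(config.seed)["genome"]
    slot = config.chrom_length_bp // config.genes_per_chromosome
    max_len = min(_MAX_GENE_BP, slot // 2)
    if max_len < _MIN_GENE_BP or slot < _MIN_GENE_BP * 2 + 4:
        raise ValueError(
            f"genes cannot fit: {config.genes_per_chromosome} genes in "
            f"{config.chrom_length_bp} bp leaves {slot} bp slots"
        )
    genes: list[GeneAnnotation] = []
    counter = 0
    for chrom in config.chromosomes:
        for k in range(config.genes_per_chromosome):
            counter += 1
            length = int(rng.integers(_MIN_GENE_BP, max_len + 1))
            offset = int(rng.integers(2, slot - length - 1))
            start = k * slot + offset
            genes.append(GeneAnnotation(
                gene_id=str(10_000 + counter),
                symbol=f"TR{counter:04d}",
                chrom=chrom,
                start=start,
                end=start + length - 1,
                strand="+" if rng.random() < 0.5 else "-",
            ))
    index = GeneIndex(genes)
    snps: list[SnpLocus] = []
    used: set[tuple[str, int]] = set()
    for i in range(config.n_snps):
        for _ in range(10_000):
            chrom = config.chromosomes[int(rng.integers(config.n_chromosomes))]
            pos = int(rng.integers(1, config.chrom_length_bp + 1))
            if (chrom, pos) not in used and index.is_intergenic(chrom, pos):
                used.add((chrom, pos))
                snps.append(SnpLocus(f"rs{2_000_000 + i}", chrom, pos, True))
                break
        else:  # pragma: no cover - would need a pathological config
            raise ValueError("could not place an intergenic SNP")
    return genes, snps


# ---------------------------------------------------------------------------
# Planting
# ---------------------------------------------------------------------------

def make_diseases(config: SimConfig) -> list[MeshTerm]:
    """Synthetic cancer MeSH terms plus one non-cancer decoy (filter exercise)."""
    terms = [
        MeshTerm(f"Synthetic Neoplasm Type {chr(65 + i)}", (f"C04.557.{100 + i}",))
        for i in range(config.n_diseases)
    ]
    terms.append(MeshTerm("Synthetic Cardiomyopathy", ("C14.280.238",)))
    return terms


def auto_plant(
    config: SimConfig,
    genes: Sequence[GeneAnnotation],
    snps: Sequence[SnpLocus],
    diseases: Sequence[MeshTerm],
    rng: Optional[np.random.Generator] = None,
    min_dist_bp: int = 2_000_000,
    max_dist_bp: int = 12_000_000,
) -> tuple[SimConfig, dict[str, str], dict[str, str]]:
    """Choose a target gene and disease for every SNP and plant the signal.

    The target is drawn from same-chromosome genes 2-12 Mb from the SNP,
    never the nearest gene, so neither distance nor chance proximity can
    recover it. Plants: one contact between the SNP's and the target's 1-Mb
    windows, one eQTL truth pair, and literature enrichment of the
    (target gene, disease) and (rsID, disease) pairs.
    """
    from .genome import genomic_distance

    rng = rng if rng is not None else _streams(config.seed)["plant"]
    cancer = [t.label for t in diseases if t.tree_numbers[0].startswith("C04")]
    contacts = list(config.planted_contacts)
    eqtls = list(config.planted_eqtls)
    gene_dis = list(config.planted_gene_disease)
    snp_dis = list(config.planted_snp_disease)
    targets: dict[str, str] = {}
    target_disease: dict[str, str] = {}
    for i, snp in enumerate(snps):
        same = [(genomic_distance(snp, g), g) for g in genes if g.chrom == snp.chrom]
        same.sort(key=lambda t: (t[0], t[1].gene_id))
        nearest_id = same[0][1].gene_id
        pool = [g for d, g in same
                if min_dist_bp <= d <= max_dist_bp and g.gene_id != nearest_id]
        if not pool:
            pool = [g for d, g in same if d > 700_000 and g.gene_id != nearest_id]
        if not pool:
            raise ValueError(f"no plantable target gene for {snp.rsid}")
        gene = pool[int(rng.integers(len(pool)))]
        disease = cancer[i % len(cancer)]
        snp_win = window_of(snp.chrom, snp.position)
        gene_win = windows_of_gene(gene)[0]
        contacts.append((
            (snp_win.chrom, snp_win.bin_index),
            (gene_win.chrom, gene_win.bin_index),
            config.planted_log_ratio,
        ))
        eqtls.append((snp.rsid, gene.gene_id))
        gene_dis.append((gene.gene_id, disease))
        snp_dis.append((snp.rsid, disease))
        targets[snp.rsid] = gene.gene_id
        target_disease[snp.rsid] = disease
    planted = dataclasses.replace(
        config, planted_contacts=contacts, planted_eqtls=eqtls,
        planted_gene_disease=gene_dis, planted_snp_disease=snp_dis,
    )
    return planted, targets, target_disease


# ---------------------------------------------------------------------------
# Contact map
# ---------------------------------------------------------------------------

def generate_contact_map(config: SimConfig,
                         rng: Optional[np.random.Generator] = None) -> ContactMap:
    """Distance-decaying intra-chromosomal baseline plus planted entries.

    Baseline entry for bins i <= j on one chromosome is
    ``contact_baseline - contact_decay_rate * (j - i)`` plus N(0, sd) noise;
    trans entries exist only where planted. Planted windows outside the
    genome raise.
    """
    rng = rng if rng is not None else _streams(config.seed)["contacts"]
    cmap = ContactMap(resolution=WINDOW_SIZE)
    n_bins = config.bins_per_chromosome
    for chrom in config.chromosomes:
        pairs = [(i, j) for i in range(n_bins) for j in range(i, n_bins)]
        noise = (rng.normal(0.0, config.contact_noise_sd, size=len(pairs))
                 if config.contact_noise_sd > 0 else np.zeros(len(pairs)))
        for (i, j), eps in zip(pairs, noise):
            value = config.contact_baseline - config.contact_decay_rate * (j - i)
            cmap.set(GenomicWindow(chrom, i), GenomicWindow(chrom, j),
                     float(value + eps))
    valid = set(config.chromosomes)
    for (ca, ba), (cb, bb), value in config.planted_contacts:
        if ca not in valid or cb not in valid or ba >= n_bins or bb >= n_bins:
            raise ValueError(
                f"planted contact ({ca},{ba})/({cb},{bb}) outside the genome"
            )
        cmap.set(GenomicWindow(ca, ba), GenomicWindow(cb, bb), value, force=True)
    return cmap


# ---------------------------------------------------------------------------
# Corpus
# ---------------------------------------------------------------------------

def _conditional_probs(p_joint_target: float, p_concept: float,
                       p_condition: float, pair: tuple) -> tuple[float, float]:
    """P(concept | condition) and P(concept | not condition) preserving the marginal."""
    p_hi = p_joint_target / p_condition
    if p_hi > 1.0:
        warnings.warn(f"enrichment clipped for planted pair {pair}")
        p_hi = 1.0
    p_lo = (p_concept - p_condition * p_hi) / (1.0 - p_condition)
    if p_lo < 0.0:
        warnings.warn(f"marginal not preservable for planted pair {pair}")
        p_lo = 0.0
    return p_hi, p_lo


def sample_mentions(
    config: SimConfig,
    genes: Sequence[GeneAnnotation],
    snps: Sequence[SnpLocus],
    diseases: Sequence[MeshTerm],
    rng: Optional[np.random.Generator] = None,
) -> list[MentionSample]:
    """Sample which concepts each citation mentions (the corpus ground truth).

    Concepts are independent Bernoulli(background_mention_prob) except that
    for each planted (gene, disease) or (rsID, disease) pair the joint
    probability becomes ``enrichment_factor * p^2`` (marginals preserved),
    and for each planted eQTL pair the gene is additionally mentioned with
    probability ``min(1, enrichment_factor * p)`` in citations that mention
    the rsID.
    """
    rng = rng if rng is not None else _streams(config.seed)["corpus"]
    p = config.background_mention_prob
    e = config.enrichment_factor
    n = config.n_documents
    gene_ids = [g.gene_id for g in genes]
    rsids = [s.rsid for s in snps]
    labels = [t.label for t in diseases]
    g_col = {g: i for i, g in enumerate(gene_ids)}
    r_col = {r: i for i, r in enumerate(rsids)}
    d_col = {d: i for i, d in enumerate(labels)}

    D = rng.random((n, len(labels))) < p
    R = rng.random((n, len(rsids))) < p
    G = rng.random((n, len(gene_ids))) < p

    for rsid, disease in config.planted_snp_disease:
        hi, lo = _conditional_probs(e * p * p, p, p, (rsid, disease))
        draws = rng.random(n)
        has_d = D[:, d_col[disease]]
        R[:, r_col[rsid]] = np.where(has_d, draws < hi, draws < lo)
    for gene_id, disease in config.planted_gene_disease:
        hi, lo = _conditional_probs(e * p * p, p, p, (gene_id, disease))
        draws = rng.random(n)
        has_d = D[:, d_col[disease]]
        G[:, g_col[gene_id]] = np.where(has_d, draws < hi, draws < lo)
    for rsid, gene_id in config.planted_eqtls:
        boost = rng.random(n) < min(1.0, e * p)
        G[:, g_col[gene_id]] |= R[:, r_col[rsid]] & boost

    samples = []
    for i in range(n):
        samples.append(MentionSample(
            doc_id=f"d{i:06d}",
            gene_ids=frozenset(gid for j, gid in enumerate(gene_ids) if G[i, j]),
            rsids=frozenset(r for j, r in enumerate(rsids) if R[i, j]),
            diseases=frozenset(d for j, d in enumerate(labels) if D[i, j]),
        ))
    return samples


_FILLER = (
    "cohort patients tumour expression analysis signalling pathway samples "
    "prognosis survival biopsy carcinogenesis proliferation assay allele "
    "genotype haplotype variant locus regulatory enhancer promoter"
).split()


def render_documents(
    samples: Sequence[MentionSample],
    genes: Sequence[GeneAnnotation],
    diseases: Sequence[MeshTerm],
    rng: Optional[np.random.Generator] = None,
    seed: int = 0,
) -> list[Document]:
    """Turn mention samples into abstracts with verbatim surface forms.

    Gene symbols and rsIDs are embedded in filler prose; sampled diseases
    become MeSH metadata (with their tree numbers), never free text —
    mirroring the fact that disease assignment comes from indexing.
    """
    rng = rng if rng is not None else _streams(seed)["render"]
    symbol = {g.gene_id: g.symbol for g in genes}
    by_label = {t.label: t for t in diseases}
    docs = []
    for s in samples:
        mentions = sorted(symbol[g] for g in s.gene_ids) + sorted(s.rsids)
        filler = [_FILLER[int(k)] for k in rng.integers(0, len(_FILLER), size=4)]
        if mentions:
            body = (
                f"We examined {', '.join(mentions)} in a {filler[0]} {filler[1]} "
                f"study and assessed {filler[2]} and {filler[3]}."
            )
        else:
            body = (
                f"This report describes {filler[0]} {filler[1]} findings with "
                f"no specific locus, focusing on {filler[2]} {filler[3]}."
            )
        mesh = tuple(by_label[d] for d in sorted(s.diseases))
        docs.append(Document(s.doc_id, body, mesh))
    return docs


def truth_annotations(samples: Sequence[MentionSample],
                      diseases: Sequence[MeshTerm],
                      subtree_prefix: str = "C04") -> list[AnnotatedDocument]:
    """Annotated documents built from the ground-truth samples (no text mining)."""
    cancer = {
        t.label for t in diseases
        if any(n.startswith(subtree_prefix) for n in t.tree_numbers)
    }
    return [
        AnnotatedDocument(s.doc_id, s.gene_ids, s.rsids,
                          frozenset(s.diseases & cancer))
        for s in samples
    ]


def generate_corpus(
    config: SimConfig,
    genes: Sequence[GeneAnnotation],
    snps: Sequence[SnpLocus],
    diseases: Sequence[MeshTerm],
    rng: Optional[np.random.Generator] = None,
    render_rng: Optional[np.random.Generator] = None,
) -> tuple[list[Document], list[MentionSample]]:
    """Sample mention sets and render them as documents."""
    samples = sample_mentions(config, genes, snps, diseases, rng)
    docs = render_documents(samples, genes, diseases, render_rng, seed=config.seed)
    return docs, samples


def generate_eqtl_gold(config: SimConfig,
                       rng: Optional[np.random.Generator] = None) -> list[EqtlPair]:
    """An eQTL truth pair per planted target, with sub-0.01 p-values."""
    rng = rng if rng is not None else _streams(config.seed)["gold"]
    return [
        EqtlPair(rsid, gene_id, float(10.0 ** rng.uniform(-5.0, -2.5)))
        for rsid, gene_id in config.planted_eqtls
    ]


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def simulate_study(config: SimConfig) -> SyntheticStudy:
    """Generate a complete synthetic study from a config (auto-planting if bare).

    If the config carries no explicit plantings, `auto_plant` builds the
    standard scenario: one non-nearest, same-chromosome target per SNP with
    contact, literature and eQTL signal.
    """
    streams = _streams(config.seed)
    genes, snps = generate_genome(config, streams["genome"])
    diseases = make_diseases(config)
    if not config.planted_eqtls and not config.planted_contacts:
        config, targets, target_disease = auto_plant(
            config, genes, snps, diseases, streams["plant"]
        )
    else:
        targets = dict(config.planted_eqtls)
        target_disease = dict(config.planted_snp_disease)
    cmap = generate_contact_map(config, streams["contacts"])
    docs, samples = generate_corpus(
        config, genes, snps, diseases, streams["corpus"], streams["render"]
    )
    gold = generate_eqtl_gold(config, streams["gold"])
    mesh_table = {t.label: t.tree_numbers for t in diseases}
    return SyntheticStudy(
        config=config, genes=genes, snps=snps, diseases=diseases,
        mesh_table=mesh_table, contact_map=cmap, samples=samples,
        documents=docs, gold=gold, planted_targets=targets,
        planted_diseases=target_disease,
    )


def write_study(study: SyntheticStudy, outdir) -> dict[str, Path]:
    """Write every input the readers consume, plus the planted truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {name: outdir / fname for name, fname in [
        ("genes", "genes.bed"), ("snps", "snps.tsv"),
        ("contacts", "contacts.tsv"), ("corpus", "corpus.jsonl"),
        ("mesh", "mesh.tsv"), ("dictionary", "dictionary.tsv"),
        ("gold", "gold.tsv"), ("planted", "planted.tsv"),
    ]}
    write_annotations_bed(study.genes, paths["genes"])
    write_snps_tsv(study.snps, paths["snps"])
    write_contact_map(study.contact_map, paths["contacts"])
    write_corpus_jsonl(study.documents, paths["corpus"])
    write_mesh_tsv(study.mesh_table, paths["mesh"])
    write_dictionary_tsv(
        ((g.gene_id, [g.symbol]) for g in study.genes), paths["dictionary"]
    )
    write_gold_tsv(study.gold, paths["gold"])
    with open(paths["planted"], "w") as fh:
        fh.write("rsid\tgene_id\tdisease\n")
        for rsid in sorted(study.planted_targets):
            fh.write(f"{rsid}\t{study.planted_targets[rsid]}\t"
                     f"{study.planted_diseases.get(rsid, '')}\n")
    return paths
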