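import math
from collections import Counter

import pytest

from targetrank.genome import GeneAnnotation, SnpLocus
from targetrank.litscore import (
    CooccurrenceCounts,
    assemble_associations,
    comention_counts,
    count_cooccurrences,
    filter_comentions,
    gene_disease_tscore,
    score_all_pairs,
    snp_disease_relations,
)
from targetrank.mining import AnnotatedDocument


def doc(doc_id, genes=(), rsids=(), diseases=()):
    return AnnotatedDocument(doc_id, frozenset(genes), frozenset(rsids),
                             frozenset(diseases))


def counts_of(N, n_g, n_d, n_gd):
    return CooccurrenceCounts(
        N=N, n_g=Counter({"g": n_g}), n_d=Counter({"d": n_d}),
        n_gd=Counter({("g", "d"): n_gd}),
    )


class TestCounting:
    def test_joint_and_marginal_counts(self):
        docs = [doc("1", ["A"], [], ["X"]), doc("2", ["A"], [], ["X"])]
        c = count_cooccurrences(docs)
        assert (c.N, c.n_g["A"], c.n_d["X"], c.n_gd[("A", "X")]) == (2, 2, 2, 2)

    def test_document_without_disease_counts_marginally(self):
        c = count_cooccurrences([doc("1", ["A"])])
        assert c.N == 1 and c.n_g["A"] == 1 and not c.n_gd

    def test_empty_corpus_all_zero(self):
        c = count_cooccurrences([])
        assert c.N == 0 and not c.n_g and not c.n_d and not c.n_gd


class TestTScore:
    def test_zero_at_exact_independence(self):
        # x_bar = 4/100 = 0.04, mu = (20/100)(20/100) = 0.04
        c = counts_of(100, 20, 20, 4)
        assert gene_disease_tscore(c, "g", "d").t == 0.0

    def test_worked_positive_example(self):
        s = gene_disease_tscore(counts_of(1000, 100, 50, 20), "g", "d")
        assert s.defined
        assert s.t == pytest.approx(0.015 / math.sqrt(0.0196 / 1000), rel=1e-12)
        assert s.t == pytest.approx(3.3882, abs=1e-4)

    def test_negative_when_observed_below_expected(self):
        s = gene_disease_tscore(counts_of(1000, 500, 500, 100), "g", "d")
        assert s.t == pytest.approx(-15.81, abs=0.01)

    def test_undefined_without_cooccurrence_evidence(self):
        s = gene_disease_tscore(counts_of(1000, 100, 50, 0), "g", "d")
        assert not s.defined and math.isnan(s.t)

    def test_empty_corpus_is_an_error(self):
        with pytest.raises(ValueError):
            gene_disease_tscore(CooccurrenceCounts(), "g", "d")

    def test_strictly_increasing_in_joint_count(self):
        """At fixed marginals, more co-occurrence means a larger t (exhaustive)."""
        for N, n_g, n_d in [(20, 8, 5), (50, 25, 10), (100, 10, 90)]:
            ts = [
                gene_disease_tscore(counts_of(N, n_g, n_d, k), "g", "d").t
                for k in range(1, min(n_g, n_d) + 1)
            ]
            assert all(a < b for a, b in zip(ts, ts[1:]))

    def test_antisymmetric_numerator_around_independence(self):
        """Mirroring n_gd about N*mu flips the sign of the observed-expected gap."""
        N, n_g, n_d = 1000, 100, 50
        mu_count = n_g * n_d / N  # 5
        for delta in (1, 2, 3):
            hi = gene_disease_tscore(counts_of(N, n_g, n_d, int(mu_count + delta)), "g", "d")
            lo = gene_disease_tscore(counts_of(N, n_g, n_d, int(mu_count - delta)), "g", "d")
            assert hi.t > 0 > lo.t


class TestRelationsAndAssembly:
    GENES = [GeneAnnotation(g, g, "chr1", i * 1000 + 1, i * 1000 + 100)
             for i, g in enumerate(["A", "B", "C"])]
    SNP = SnpLocus("rs652625", "chr1", 500_000, True)

    def test_relation_requires_one_cooccurring_citation(self):
        docs = [doc("1", [], ["rs652625"], ["Lung Neoplasms"]),
                doc("2", [], ["rs652625"], [])]
        assert snp_disease_relations(docs) == {("rs652625", "Lung Neoplasms")}

    def test_relations_are_set_valued(self):
        docs = [doc(str(i), [], ["rs1"], ["X"]) for i in range(3)]
        assert snp_disease_relations(docs) == {("rs1", "X")}

    def test_cartesian_assembly_two_diseases_three_genes(self):
        relations = {("rs652625", "X"), ("rs652625", "Y")}
        scores = score_all_pairs(count_cooccurrences([
            doc("1", ["A"], [], ["X"]), doc("2", ["A"], [], ["Y"]),
        ]))
        stubs = assemble_associations(self.SNP, relations, scores, self.GENES)
        assert len(stubs) == 6

    def test_unscored_gene_carries_undefined_marker(self):
        relations = {("rs652625", "X")}
        scores = score_all_pairs(count_cooccurrences([doc("1", ["A"], [], ["X"])]))
        stubs = assemble_associations(self.SNP, relations, scores, self.GENES)
        by_gene = {s.gene_id: s.lit_t for s in stubs}
        assert by_gene["A"] is not None and by_gene["B"] is None

    def test_same_gene_two_diseases_two_scores(self):
        relations = {("rs652625", "X"), ("rs652625", "Y")}
        scores = score_all_pairs(count_cooccurrences([
            doc("1", ["A"], [], ["X"]),
            doc("2", ["A"], [], ["Y"]), doc("3", ["A"], [], ["Y"]),
            doc("4", ["B"], [], []),
        ]))
        stubs = assemble_associations(self.SNP, relations, scores, [self.GENES[0]])
        ts = {s.disease: s.lit_t for s in stubs}
        assert ts["X"] != ts["Y"]

    def test_snp_without_relation_warns_and_returns_empty(self, caplog):
        with caplog.at_level("WARNING"):
            assert assemble_associations(self.SNP, set(), {}, self.GENES) == []
        assert "rs652625" in caplog.text


class TestComentions:
    def test_counting_and_filtering(self):
        docs = [doc("1", ["A"], ["rs1"]), doc("2", ["A"], ["rs1"]),
                doc("3", ["B"], ["rs1"])]
        counts = comention_counts(docs)
        assert counts == {("rs1", "A"): 2, ("rs1", "B"): 1}
        assert filter_comentions(counts, 2) == {("rs1", "A"): 2}

    def test_concepts_in_different_abstracts_not_comentioned(self):
        docs = [doc("1", ["A"], []), doc("2", [], ["rs1"])]
        assert comention_counts(docs) == {}


class TestPlantedEnrichmentSeparation:
    def test_planted_pair_beats_background_95th_percentile(self):
        """Monte-Carlo: a 10x-enriched (gene, disease) pair scores above the
        95th percentile of background pair t-scores in >=95% of replicates."""
        import numpy as np

        from targetrank.simulate import (
            SimConfig, generate_genome, make_diseases, sample_mentions,
            truth_annotations,
        )

        successes = 0
        n_reps = 50
        for seed in range(n_reps):
            config = SimConfig(
                seed=seed, n_chromosomes=1, genes_per_chromosome=60,
                n_snps=1, n_diseases=2, n_documents=2000,
                background_mention_prob=0.03, enrichment_factor=10.0,
            )
            genes, snps = generate_genome(config)
            diseases = make_diseases(config)
            planted = (genes[0].gene_id, diseases[0].label)
            config.planted_gene_disease.append(planted)
            rng = np.random.default_rng(seed + 1)
            samples = sample_mentions(config, genes, snps, diseases, rng)
            annotated = truth_annotations(samples, diseases)
            from targetrank.litscore import count_cooccurrences, score_all_pairs

            scores = score_all_pairs(count_cooccurrences(annotated))
            planted_t = scores[planted].t
            background = [s.t for k, s in scores.items() if k != planted]
            if planted_t > np.percentile(background, 95):
                successes += 1
        assert successes >= 0.95 * n_reps

    def test_no_enrichment_centres_t_near_zero(self):
        """With enrichment factor 1 the planted pair behaves like background."""
        import numpy as np

        from targetrank.simulate import (
            SimConfig, generate_genome, make_diseases, sample_mentions,
            truth_annotations,
        )

        ts = []
        for seed in range(50):
            config = SimConfig(
                seed=seed, n_chromosomes=1, genes_per_chromosome=30,
                n_snps=1, n_diseases=2, n_documents=1000,
                background_mention_prob=0.05, enrichment_factor=1.0,
            )
            genes, snps = generate_genome(config)
            diseases = make_diseases(config)
            config.planted_gene_disease.append((genes[0].gene_id, diseases[0].label))
            samples = sample_mentions(config, genes, snps, diseases,
                                      np.random.default_rng(seed + 1))
            annotated = truth_annotations(samples, diseases)
            from targetrank.litscore import count_cooccurrences, gene_disease_tscore

            s = gene_disease_tscore(count_cooccurrences(annotated),
                                    genes[0].gene_id, diseases[0].label)
            if s.defined:
                ts.append(s.t)
        assert abs(float(np.mean(ts))) < 0.5
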