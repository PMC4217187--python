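import itertools
import math

import numpy as np
import pytest

from targetrank.genome import GeneAnnotation, GenomicWindow, SnpLocus
from targetrank.associations import rank_associations
from targetrank.ranking import (
    ASCENDING,
    DESCENDING,
    fractional_rank,
    hybrid_rank,
)
from targetrank.spatial import ContactMap


def brute_force_fractional_ranks(scores, direction=ASCENDING):
    """Independent oracle: sort defined scores, assign positions 1..n,
    average positions over ties, park undefined entries after all defined
    ones as one tie block, divide by n + 1."""
    n = len(scores)
    defined = [(s, i) for i, s in enumerate(scores)
               if s is not None and not (isinstance(s, float) and math.isnan(s))]
    undefined = [i for i, s in enumerate(scores)
                 if s is None or (isinstance(s, float) and math.isnan(s))]
    key = (lambda t: t[0]) if direction == ASCENDING else (lambda t: -t[0])
    ordered = sorted(defined, key=key)
    positions = {}
    for pos, (s, i) in enumerate(ordered, start=1):
        positions.setdefault(i, []).append(pos)
    # average positions across equal scores
    ranks = [0.0] * n
    for value in {key(t) for t in ordered}:
        idxs = [i for s, i in ordered if key((s, i)) == value]
        pos = [p for p, (s, i) in enumerate(ordered, start=1)
               if key((s, i)) == value]
        mean_pos = sum(pos) / len(pos)
        for i in idxs:
            ranks[i] = mean_pos / (n + 1)
    if undefined:
        mean_pos = (len(defined) + 1 + n) / 2
        for i in undefined:
            ranks[i] = mean_pos / (n + 1)
    return ranks


class TestFractionalRank:
    def test_published_distance_example(self):
        """Distances 43k/2k/500k/8k/1292k -> ranks .5/.167/.667/.333/.833."""
        rl = fractional_rank([43_000, 2_000, 500_000, 8_000, 1_292_000], ASCENDING)
        assert [round(r, 3) for r in rl.fractional_ranks] == \
            [0.5, 0.167, 0.667, 0.333, 0.833]

    def test_single_item_is_half(self):
        assert fractional_rank([42], ASCENDING).fractional_ranks == (0.5,)

    def test_tied_scores_share_mean_position(self):
        rl = fractional_rank([5, 5, 10], ASCENDING)
        assert rl.fractional_ranks == (0.375, 0.375, 0.75)

    def test_empty_list_is_error(self):
        with pytest.raises(ValueError):
            fractional_rank([], ASCENDING)

    def test_sum_of_ranks_without_ties_is_half_n(self):
        rng = np.random.default_rng(3)
        for n in (1, 2, 5, 17, 100):
            scores = rng.permutation(n) * 7.5
            rl = fractional_rank(list(scores), ASCENDING)
            assert sum(rl.fractional_ranks) == pytest.approx(n / 2)

    @pytest.mark.parametrize("direction", [ASCENDING, DESCENDING])
    def test_matches_bruteforce_oracle_exhaustively(self, direction):
        """All score lists of length <= 6 over {0, 1, 2, undefined}."""
        alphabet = [0.0, 1.0, 2.0, None]
        for n in range(1, 7):
            for scores in itertools.product(alphabet, repeat=n):
                if all(s is None for s in scores):
                    expected = [(n + 1) / 2 / (n + 1)] * n
                else:
                    expected = brute_force_fractional_ranks(list(scores), direction)
                got = fractional_rank(list(scores), direction).fractional_ranks
                assert list(got) == pytest.approx(expected), (scores, direction)

    def test_ranks_strictly_inside_unit_interval(self):
        rl = fractional_rank([None, None, 1.0], DESCENDING)
        assert all(0 < r < 1 for r in rl.fractional_ranks)


class TestHybridRank:
    def test_unanimous_best_item_stays_best(self):
        a = fractional_rank({"x": 1, "y": 2, "z": 3}, ASCENDING)
        b = fractional_rank({"x": 10, "y": 5, "z": 1}, DESCENDING)
        h = hybrid_rank([a, b]).as_dict()
        assert min(h, key=h.get) == "x"

    def test_two_source_product_tie_example(self):
        a = fractional_rank({"A": 1, "B": 2, "C": 3}, ASCENDING)   # .25 .5 .75
        b = fractional_rank({"A": 2, "B": 1, "C": 3}, ASCENDING)   # .5 .25 .75
        h = hybrid_rank([a, b]).as_dict()
        # products .125, .125, .5625 -> positions (1+2)/2, (1+2)/2, 3 over 4
        assert h == {"A": 0.375, "B": 0.375, "C": 0.75}

    def test_two_item_direct_arithmetic(self):
        # force the rank values 0.1/0.9 vs 0.5/0.5 via custom lists
        from targetrank.ranking import RankedList
        l1 = RankedList(("p", "q"), (None, None), (0.1, 0.9), ASCENDING)
        l2 = RankedList(("p", "q"), (None, None), (0.5, 0.5), ASCENDING)
        h = hybrid_rank([l1, l2]).as_dict()
        assert h["p"] == pytest.approx(1 / 3)
        assert h["q"] == pytest.approx(2 / 3)

    def test_mismatched_universes_rejected(self):
        a = fractional_rank({"x": 1, "y": 2}, ASCENDING)
        b = fractional_rank({"x": 1, "z": 2}, ASCENDING)
        with pytest.raises(ValueError, match="universe"):
            hybrid_rank([a, b])

    def test_invariant_to_source_list_order(self):
        rng = np.random.default_rng(5)
        items = [f"g{i}" for i in range(12)]
        lists = [
            fractional_rank(dict(zip(items, rng.normal(size=12))), DESCENDING)
            for _ in range(3)
        ]
        h1 = hybrid_rank(lists).as_dict()
        h2 = hybrid_rank(list(reversed(lists))).as_dict()
        assert h1 == h2

    def test_product_equals_geometric_mean_ranking(self):
        """Ranking by product and by geometric mean agree on 1000 random draws."""
        rng = np.random.default_rng(11)
        for _ in range(1000):
            n = int(rng.integers(2, 8))
            ranks = rng.uniform(0.01, 0.99, size=(3, n))
            products = ranks.prod(axis=0)
            geomeans = products ** (1 / 3)
            by_product = fractional_rank(list(products), ASCENDING).fractional_ranks
            by_geomean = fractional_rank(list(geomeans), ASCENDING).fractional_ranks
            assert by_product == pytest.approx(by_geomean)


class TestRankAssociations:
    def _setup(self):
        snp = SnpLocus("rs1", "chr1", 500, True)
        genes = [
            GeneAnnotation("A", "A", "chr1", 2_000_001, 2_050_000),
            GeneAnnotation("B", "B", "chr1", 5_000_001, 5_050_000),
            GeneAnnotation("C", "C", "chr1", 9_000_001, 9_050_000),
        ]
        cmap = ContactMap()
        cmap.set(GenomicWindow("chr1", 0), GenomicWindow("chr1", 2), 1.0)
        cmap.set(GenomicWindow("chr1", 0), GenomicWindow("chr1", 5), 6.0)
        cmap.set(GenomicWindow("chr1", 0), GenomicWindow("chr1", 9), 3.0)
        return snp, genes, cmap

    def test_every_rank_column_normalized(self):
        snp, genes, cmap = self._setup()
        records = rank_associations(snp, "X", genes, cmap, {"A": 1.5}, "validation")
        assert len(records) == 3
        for r in records:
            assert 0 < r.rank_gen_dist < 1
            assert 0 < r.rank_spatial < 1
            assert 0 < r.rank_literature < 1
            assert 0 < r.rank_hybrid < 1
            assert r.universe_size == 3

    def test_undefined_literature_still_yields_hybrid(self):
        snp, genes, cmap = self._setup()
        records = rank_associations(snp, "X", genes, cmap, {"B": 2.0}, "validation")
        by_gene = {r.gene_id: r for r in records}
        bottom = max(r.rank_literature for r in records)
        assert by_gene["A"].rank_literature == by_gene["C"].rank_literature == bottom
        assert 0 < by_gene["A"].rank_hybrid < 1

    def test_channel_independence_across_diseases(self):
        snp, genes, cmap = self._setup()
        rx = rank_associations(snp, "X", genes, cmap, {"A": 1.0}, "validation")
        ry = rank_associations(snp, "Y", genes, cmap, {"C": 4.0}, "validation")
        gx = {r.gene_id: r for r in rx}
        gy = {r.gene_id: r for r in ry}
        for g in "ABC":
            assert gx[g].rank_spatial == gy[g].rank_spatial
            assert gx[g].rank_gen_dist == gy[g].rank_gen_dist
        assert gx["A"].rank_literature != gy["A"].rank_literature

    def test_discovery_mode_drops_distance_channel(self):
        snp, genes, cmap = self._setup()
        records = rank_associations(snp, "X", genes, cmap, {}, "discovery")
        assert all(r.rank_gen_dist is None for r in records)
        top = min(records, key=lambda r: r.rank_hybrid)
        assert top.gene_id == "B"  # strongest contact wins when literature is flat

    def test_empty_universe_is_error_naming_the_pair(self):
        snp, _, cmap = self._setup()
        with pytest.raises(ValueError, match="rs1"):
            rank_associations(snp, "X", [], cmap, {}, "validation")
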