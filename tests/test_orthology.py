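import numpy as np
import pytest

from znf.model import Locus, MappingRow, SimilarityEdge, DomainHit
from znf.orthology import (
    build_orthogroups,
    high_confidence,
    kmer_similarity,
    markov_cluster,
    pairwise_similarity,
    reciprocal_best_hits,
    relation_classes,
    synteny_orthologs,
)


def _locus(lid, species, seq, genome=None, start=0):
    genome = genome or f"{species}_1"
    h = DomainHit("ZNF", genome, start, start + 84, "+", 1, "X" * 28, 60.0, 1e-9)
    l = Locus(id=lid, species=species, genome_id=genome, strand="+", hits=[h])
    l.seq = seq
    return l


def _rand_seq(rng, n=300):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


class TestSimilarity:
    def test_identical_sequences_are_mutual_best(self):
        rng = np.random.default_rng(0)
        s1, s2 = _rand_seq(rng), _rand_seq(rng)
        xs = [_locus("x1", "H", s1), _locus("x2", "H", s2)]
        ys = [_locus("y1", "C", s1), _locus("y2", "C", s2)]
        edges = pairwise_similarity(xs, ys)
        top = {(e.a, e.b): e for e in edges}
        assert top[("x1", "y1")].best_ab and top[("x1", "y1")].best_ba

    def test_kmer_similarity_of_identical_sequences_is_one(self):
        rng = np.random.default_rng(1)
        s = _rand_seq(rng)
        assert kmer_similarity(s, s) == pytest.approx(1.0)

    def test_best_flags_equal_argmax_oracle(self):
        rng = np.random.default_rng(2)
        xs = [_locus(f"x{i}", "H", _rand_seq(rng)) for i in range(10)]
        ys = [_locus(f"y{i}", "C", _rand_seq(rng)) for i in range(10)]
        edges = pairwise_similarity(xs, ys, floor=0.0)
        scores = {(e.a, e.b): e.score for e in edges}
        for e in edges:
            row = [scores.get((e.a, y.id), -1) for y in ys]
            is_unique_max = (
                scores[(e.a, e.b)] == max(row) and row.count(max(row)) == 1
            )
            assert e.best_ab == is_unique_max


class TestRBH:
    def _edge(self, a, b, score, ab=False, ba=False):
        return SimilarityEdge(a=a, b=b, score=score, best_ab=ab, best_ba=ba)

    def test_mutual_best_is_a_pair(self):
        edges = [self._edge("a", "b", 0.9, ab=True, ba=True)]
        assert reciprocal_best_hits(edges) == [("a", "b")]

    def test_one_sided_best_is_not_a_pair(self):
        edges = [
            self._edge("a", "b", 0.9, ab=True, ba=False),
            self._edge("c", "b", 0.95, ab=True, ba=True),
        ]
        assert reciprocal_best_hits(edges) == [("c", "b")]

    def test_score_ties_yield_no_rbh(self):
        rng = np.random.default_rng(3)
        s = _rand_seq(rng)
        xs = [_locus("x1", "H", s)]
        ys = [_locus("y1", "C", s), _locus("y2", "C", s)]  # exact tie
        edges = pairwise_similarity(xs, ys)
        assert reciprocal_best_hits(edges) == []

    def test_random_scores_match_brute_force_oracle(self):
        rng = np.random.default_rng(4)
        names_x = [f"x{i}" for i in range(8)]
        names_y = [f"y{i}" for i in range(8)]
        scores = rng.uniform(0, 1, size=(8, 8))
        edges = []
        for i, a in enumerate(names_x):
            for j, b in enumerate(names_y):
                edges.append(SimilarityEdge(a=a, b=b, score=float(scores[i, j])))
        from znf.orthology import _flag_unique_best

        _flag_unique_best(edges, forward=True)
        _flag_unique_best(edges, forward=False)
        got = reciprocal_best_hits(edges)
        oracle = []
        for i, a in enumerate(names_x):
            j = int(np.argmax(scores[i]))
            if int(np.argmax(scores[:, j])) == i:
                oracle.append((a, names_y[j]))
        assert got == sorted(oracle)


class TestSynteny:
    def test_exact_coordinate_image_pairs(self):
        xs = [_locus("x1", "H", "A" * 100, start=100)]
        ys = [_locus("y1", "C", "A" * 100, start=500)]
        mapping = [MappingRow("H_1", 100, 184, "+", "C_1", 500, 584, "+")]
        assert synteny_orthologs(xs, ys, mapping) == [("x1", "y1")]

    def test_mapped_interval_over_two_loci_gives_no_unique_pair(self):
        xs = [
            _locus("x1", "H", "A" * 100, start=100),
            _locus("x2", "H", "A" * 100, start=100),
        ]
        ys = [_locus("y1", "C", "A" * 100, start=500)]
        mapping = [
            MappingRow("H_1", 100, 184, "+", "C_1", 500, 584, "+"),
        ]
        assert synteny_orthologs(xs, ys, mapping) == []

    def test_unmappable_locus_is_silently_unpaired(self):
        xs = [_locus("x1", "H", "A" * 100, start=5000)]
        ys = [_locus("y1", "C", "A" * 100, start=500)]
        mapping = [MappingRow("H_1", 100, 184, "+", "C_1", 500, 584, "+")]
        assert synteny_orthologs(xs, ys, mapping) == []

    def test_six_locus_fixture_matches_hand_derived_pairing(self):
        # hand-built: x1<->y1 and x3<->y3 map cleanly; x2's image straddles
        # two loci (ambiguous), y4 has no image
        xs = [
            _locus("x1", "H", "A" * 100, start=0),
            _locus("x2", "H", "A" * 100, start=200),
            _locus("x3", "H", "A" * 100, start=400),
        ]
        ys = [
            _locus("y1", "C", "A" * 100, start=0),
            _locus("y2", "C", "A" * 100, start=180),
            _locus("y2b", "C", "A" * 100, start=200),
            _locus("y3", "C", "A" * 100, start=400),
        ]
        mapping = [
            MappingRow("H_1", 0, 84, "+", "C_1", 0, 84, "+"),
            MappingRow("H_1", 200, 284, "+", "C_1", 180, 300, "+"),
            MappingRow("H_1", 400, 484, "+", "C_1", 400, 484, "+"),
        ]
        assert synteny_orthologs(xs, ys, mapping) == [("x1", "y1"), ("x3", "y3")]


class TestMarkovCluster:
    def _edges(self, pairs):
        return [SimilarityEdge(a=a, b=b, score=s) for a, b, s in pairs]

    def test_two_disconnected_cliques_give_two_clusters(self):
        pairs = [("a", "b", 1.0), ("b", "c", 1.0), ("a", "c", 1.0),
                 ("x", "y", 1.0), ("y", "z", 1.0), ("x", "z", 1.0)]
        clusters = markov_cluster(self._edges(pairs))
        assert sorted(map(sorted, clusters)) == [["a", "b", "c"], ["x", "y", "z"]]

    def test_single_edge_is_one_two_cluster(self):
        clusters = markov_cluster(self._edges([("a", "b", 0.8)]))
        assert clusters == [{"a", "b"}]

    def test_three_modules_with_weak_bridges_resolve(self):
        # 12 nodes, 3 groups of 4 with strong intra-module edges and weak
        # bridges between modules; MCL at inflation 2 must recover the modules
        rng = np.random.default_rng(5)
        pairs = []
        groups = [[f"{g}{i}" for i in range(4)] for g in "abc"]
        for g in groups:
            for i in range(4):
                for j in range(i + 1, 4):
                    pairs.append((g[i], g[j], 0.9 + 0.05 * rng.random()))
        pairs += [("a0", "b0", 0.05), ("b1", "c1", 0.05)]
        clusters = markov_cluster(self._edges(pairs))
        assert sorted(map(sorted, clusters)) == sorted(map(sorted, groups))

    def test_deterministic_given_input_order(self):
        pairs = [("a", "b", 0.5), ("b", "c", 0.4), ("d", "e", 0.9)]
        c1 = markov_cluster(self._edges(pairs))
        c2 = markov_cluster(self._edges(pairs))
        assert c1 == c2


class TestBuildOrthogroups:
    def _quartet(self, seed=6):
        rng = np.random.default_rng(seed)
        s = _rand_seq(rng)
        loci = [_locus(f"{sp}1", sp, s, start=0) for sp in "HCOR"]
        return loci

    def test_full_agreement_forms_one_step0_quartet(self):
        loci = self._quartet()
        pairs = [(a.id, b.id) for i, a in enumerate(loci) for b in loci[i + 1:]]
        clusters = [set(l.id for l in loci)]
        edges = [SimilarityEdge(a=a, b=b, score=1.0, best_ab=True, best_ba=True)
                 for a, b in pairs]
        groups = build_orthogroups(loci, pairs, pairs, clusters, edges=edges)
        assert len(groups) == 1
        g = groups[0]
        assert g.tier == "step0_high_confidence"
        assert all(len(v) == 1 for v in g.members.values())
        assert all(rel == "1:1" for rel in relation_classes(g).values())

    def test_cluster_conflict_vetoes_step0_and_step1(self):
        # RBH + synteny agree but MCL puts the two loci in different
        # clusters: the pair must not merge at step 0 or step 1
        loci = self._quartet()[:2]
        pair = [(loci[0].id, loci[1].id)]
        clusters = [{loci[0].id, "other1"}, {loci[1].id, "other2"}]
        others = [_locus("other1", "H", "A" * 100), _locus("other2", "C", "A" * 100)]
        edges = [SimilarityEdge(a=loci[0].id, b=loci[1].id, score=1.0,
                                best_ab=True, best_ba=True)]
        groups = build_orthogroups(loci + others, pair, pair, clusters, edges=edges)
        by_locus = {lid: g.id for g in groups for lid in g.all_loci()}
        assert by_locus[loci[0].id] != by_locus[loci[1].id]

    def test_unclustered_locus_can_join_at_step1(self):
        loci = self._quartet()[:2]
        pair = [(loci[0].id, loci[1].id)]
        edges = [SimilarityEdge(a=loci[0].id, b=loci[1].id, score=1.0,
                                best_ab=True, best_ba=True)]
        groups = build_orthogroups(loci, pair, [], [], edges=edges)
        assert len(groups) == 1 and groups[0].tier == "step1"

    def test_all_inclusive_set_partitions_the_locus_universe(self):
        rng = np.random.default_rng(7)
        loci = []
        for sp in "HCOR":
            for k in range(5):
                loci.append(_locus(f"{sp}{k}", sp, _rand_seq(rng), start=500 * k))
        cross = []
        for i, a in enumerate(loci):
            for b in loci[i + 1:]:
                if a.species != b.species:
                    cross.append(SimilarityEdge(a=a.id, b=b.id,
                                                score=float(rng.uniform(0, 1))))
        clusters = markov_cluster(cross)
        rbh = reciprocal_best_hits(cross)
        groups = build_orthogroups(loci, rbh, [], clusters, edges=cross)
        assigned = [lid for g in groups for lid in g.all_loci()]
        assert sorted(assigned) == sorted(l.id for l in loci)
        assert {g.id for g in high_confidence(groups)} <= {g.id for g in groups}
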