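"""Discrete traits: NJ (dendropy oracle), Fitch (brute-force oracle),
exhaustive MP, consensus, state summaries and NEXUS I/O."""

import itertools

import dendropy
import numpy as np
import pytest

from virtucrania.traits import (
    MISSING,
    CharacterMatrix,
    PhyloTree,
    character_distance,
    combine_pair,
    count_derived,
    exhaustive_mp,
    fitch_score,
    majority_state,
    neighbor_joining,
    read_nexus,
    strict_consensus,
    tree_from_splits,
    write_nexus,
)


def quartet(order):
    t = PhyloTree()
    t.add_edge(-1, order[0])
    t.add_edge(-1, order[1])
    t.add_edge(-1, -2)
    t.add_edge(-2, order[2])
    t.add_edge(-2, order[3])
    return t


def tree_distances(tree, taxa):
    import collections

    D = np.zeros((len(taxa), len(taxa)))
    for i, a in enumerate(taxa):
        prev = {a: None}
        q = collections.deque([a])
        while q:
            n = q.popleft()
            for m in tree.adj[n]:
                if m not in prev:
                    prev[m] = n
                    q.append(m)
        for j, b in enumerate(taxa):
            d, n = 0.0, b
            while prev[n] is not None:
                d += tree.adj[n][prev[n]]
                n = prev[n]
            D[i, j] = d
    return D


@pytest.fixture()
def additive_tree():
    t = PhyloTree()
    t.add_edge(-1, "A", 2.0)
    t.add_edge(-1, "B", 3.0)
    t.add_edge(-1, -2, 1.0)
    t.add_edge(-2, "F", 4.0)
    t.add_edge(-2, -3, 1.5)
    t.add_edge(-3, "C", 2.0)
    t.add_edge(-3, -4, 2.0)
    t.add_edge(-4, "D", 1.0)
    t.add_edge(-4, "E", 2.0)
    return t


class TestNeighborJoining:
    def test_recovers_additive_tree(self, additive_tree):
        taxa = additive_tree.leaves
        D = tree_distances(additive_tree, taxa)
        nj = neighbor_joining(D, taxa)
        assert nj.splits() == additive_tree.splits()
        np.testing.assert_allclose(tree_distances(nj, taxa), D, atol=1e-9)

    def test_matches_dendropy(self, additive_tree):
        taxa = additive_tree.leaves
        D = tree_distances(additive_tree, taxa)
        csv = "," + ",".join(taxa) + "\n"
        for i, a in enumerate(taxa):
            csv += a + "," + ",".join(str(D[i, j]) for j in range(len(taxa))) + "\n"
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            src=__import__("io").StringIO(csv)
        )
        dtree = pdm.nj_tree()
        dtree.encode_bipartitions()
        d_splits = {
            frozenset(t.label for t in e.bipartition.leafset_taxa(dtree.taxon_namespace))
            for e in dtree.bipartition_edge_map.values()
        }
        d_splits = {
            s if min(s) != min(taxa) else frozenset(set(taxa) - s)
            for s in d_splits
            if 1 < len(s) < len(taxa) - 1
        }
        ours = {
            s
            for s in neighbor_joining(D, taxa).splits()
            if 1 < len(s) < len(taxa) - 1
        }
        assert ours == d_splits

    def test_three_taxa_closed_form(self):
        D = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], dtype=float)
        taxa = ["X", "Y", "Z"]
        nj = neighbor_joining(D, taxa)
        # unique unrooted 3-taxon tree: branch lengths from the closed form
        np.testing.assert_allclose(tree_distances(nj, taxa), D, atol=1e-9)

    def test_deterministic_tie_break(self):
        D = np.ones((4, 4)) - np.eye(4)
        taxa = ["a", "b", "c", "d"]
        n1 = neighbor_joining(D, taxa).to_newick()
        n2 = neighbor_joining(D, taxa).to_newick()
        assert n1 == n2


def brute_force_parsimony(tree, matrix):
    """Independent oracle: minimise changes over all internal-node state
    assignments by exhaustive enumeration (complete matrices only)."""
    internal = [n for n in tree.adj if tree.degree(n) > 1]
    total = 0
    for ci in range(len(matrix.characters)):
        observed = sorted({row[ci] for row in matrix.states})
        assert MISSING not in observed
        leaf_state = {t: row[ci] for t, row in zip(matrix.taxa, matrix.states)}
        best = None
        for assign in itertools.product(observed, repeat=len(internal)):
            state = dict(zip(internal, assign))
            state.update(leaf_state)
            changes = sum(1 for a, b, _ in tree.edges if state[a] != state[b])
            if best is None or changes < best:
                best = changes
        total += best
    return total


class TestFitch:
    def test_textbook_quartet(self):
        m = CharacterMatrix(
            taxa=["A", "B", "C", "D"],
            characters=["c1"],
            states=[["0"], ["0"], ["1"], ["1"]],
        )
        assert fitch_score(quartet(["A", "B", "C", "D"]), m) == 1
        assert fitch_score(quartet(["A", "C", "B", "D"]), m) == 2

    def test_missing_is_free(self):
        m = CharacterMatrix(
            taxa=["A", "B", "C", "D"],
            characters=["c1"],
            states=[["0"], ["?"], ["1"], ["1"]],
        )
        assert fitch_score(quartet(["A", "B", "C", "D"]), m) == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        taxa = [f"t{i}" for i in range(6)]
        states = [[str(rng.integers(0, 2)) for _ in range(10)] for _ in taxa]
        m = CharacterMatrix(taxa=taxa, characters=[f"c{j}" for j in range(10)], states=states)
        t = PhyloTree()
        t.add_edge(-1, "t0")
        t.add_edge(-1, "t1")
        t.add_edge(-1, -2)
        t.add_edge(-2, "t2")
        t.add_edge(-2, -3)
        t.add_edge(-3, "t3")
        t.add_edge(-3, -4)
        t.add_edge(-4, "t4")
        t.add_edge(-4, "t5")
        assert fitch_score(t, m) == brute_force_parsimony(t, m)


class TestExhaustiveMP:
    def test_conflicting_characters_star_consensus(self):
        m = CharacterMatrix(
            taxa=["A", "B", "C", "D"],
            characters=["c1", "c2"],
            states=[["0", "0"], ["0", "1"], ["1", "0"], ["1", "1"]],
        )
        trees, consensus = exhaustive_mp(m)
        assert len(trees) > 1
        nontrivial = {s for s in consensus.splits() if 1 < len(s) < 3}
        assert nontrivial == set()

    def test_recovers_clean_signal(self):
        # characters perfectly compatible with ((A,B),(C,D),(E,F))
        taxa = ["A", "B", "C", "D", "E", "F"]
        chars = {
            "AB": ["1", "1", "0", "0", "0", "0"],
            "CD": ["0", "0", "1", "1", "0", "0"],
            "EF": ["0", "0", "0", "0", "1", "1"],
        }
        m = CharacterMatrix(
            taxa=taxa,
            characters=list(chars),
            states=[[chars[c][i] for c in chars] for i in range(6)],
        )
        trees, consensus = exhaustive_mp(m)
        splits = consensus.splits()
        assert frozenset({"C", "D"}) in splits or frozenset(set(taxa) - {"C", "D"}) in splits
        assert frozenset({"E", "F"}) in splits or frozenset(set(taxa) - {"E", "F"}) in splits

    def test_max_taxa_guard(self):
        taxa = [f"t{i}" for i in range(11)]
        m = CharacterMatrix(taxa=taxa, characters=["c"], states=[["0"]] * 11)
        with pytest.raises(ValueError):
            exhaustive_mp(m)


class TestConsensusAndSplits:
    def test_strict_consensus_intersection(self):
        t1 = quartet(["A", "B", "C", "D"])
        t2 = quartet(["A", "C", "B", "D"])
        cons = strict_consensus([t1, t2])
        assert {s for s in cons.splits() if 1 < len(s) < 3} == set()
        same = strict_consensus([t1, t1.copy()])
        assert same.splits() == t1.splits()

    def test_tree_from_splits_roundtrip(self, additive_tree):
        rebuilt = tree_from_splits(additive_tree.leaves, additive_tree.splits())
        assert rebuilt.splits() == additive_tree.splits()


class TestStateSummaries:
    def test_majority_state(self):
        # col 0: clear majority; col 1: 2-2 tie -> '?'; col 2: missing ignored
        rows = [
            ["0", "1", "?"],
            ["0", "1", "1"],
            ["1", "0", "1"],
            ["0", "0", "?"],
        ]
        assert majority_state(rows) == ["0", "?", "1"]

    def test_majority_state_all_missing(self):
        assert majority_state([["?"], ["?"]]) == ["?"]

    def test_combine_pair(self):
        assert combine_pair(["0", "1", "?"], ["0", "0", "1"]) == ["0", "?", "1"]

    def test_count_derived(self):
        row = ["1", "0", "?", "1"]
        dmap = {f"c{i}": "1" for i in range(4)}
        k, n = count_derived(row, dmap, [f"c{i}" for i in range(4)])
        assert (k, n) == (2, 4)

    def test_character_distance_symmetric(self):
        m = CharacterMatrix(
            taxa=["A", "B", "C"],
            characters=["c1", "c2"],
            states=[["0", "0"], ["0", "1"], ["1", "1"]],
        )
        D = character_distance(m)
        assert D[0, 1] == pytest.approx(0.5)
        assert D[0, 2] == pytest.approx(1.0)
        np.testing.assert_allclose(D, D.T)
        np.testing.assert_allclose(np.diag(D), 0)


class TestNexus:
    def test_roundtrip(self, tmp_path):
        m = CharacterMatrix(
            taxa=["Alpha", "Beta", "Gamma"],
            characters=["c1", "c2", "c3"],
            states=[["0", "1", "?"], ["1", "1", "0"], ["0", "0", "1"]],
        )
        p = tmp_path / "m.nex"
        write_nexus(m, p)
        back = read_nexus(p)
        assert back.taxa == m.taxa
        assert back.states == m.states

    def test_readable_by_dendropy(self, tmp_path):
        m = CharacterMatrix(
            taxa=["Alpha", "Beta"],
            characters=["c1", "c2"],
            states=[["0", "1"], ["1", "0"]],
        )
        p = tmp_path / "m.nex"
        write_nexus(m, p)
        d = dendropy.StandardCharacterMatrix.get(path=str(p), schema="nexus")
        assert len(d) == 2
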