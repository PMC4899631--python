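import itertools
from io import StringIO

import numpy as np
import pytest
from Bio import Phylo

from shmrep.reference import GermlineReference
from shmrep.trees import build_lineage_tree, total_tree_weight, write_newick

GERM12 = "ACGTACGTACGT"
BOUNDS12 = {"FR1": (0, 3), "CDR1": (3, 5), "FR2": (5, 7), "CDR2": (7, 9), "FR3": (9, 12)}
NEXT = {"A": "C", "C": "G", "G": "T", "T": "A"}


@pytest.fixture(scope="module")
def tiny_ref():
    return GermlineReference("tiny", GERM12, BOUNDS12, 0)


def seq_from(mset, germ=GERM12):
    s = list(germ)
    for p in mset:
        s[p] = NEXT[s[p]]
    return "".join(s)


def steiner_min_no_reversion(observed_masks, universe, max_extra=3):
    """Exhaustive minimum over reversion-free germline-rooted trees whose
    intermediate nodes are drawn from subsets of the observed mutation
    union: each node's parent is its largest subset present, so the cost of
    a node set is the sum over nodes of (|node| - |largest subset|)."""

    def popcount(x):
        return bin(x).count("1")

    def cost(nodes):
        total = 0
        for v in nodes:
            if v == 0:
                continue
            best = 0
            for u in nodes:
                if u != v and (u & v) == u and popcount(u) > popcount(best):
                    best = u
            total += popcount(v) - popcount(best)
        return total

    terms = sorted(set([0] + observed_masks))
    candidates = [m for m in range(1 << universe) if m not in set(terms)]
    best = cost(terms)
    for k in range(1, max_extra + 1):
        for extra in itertools.combinations(candidates, k):
            best = min(best, cost(terms + list(extra)))
    return best


class TestExamples:
    def test_single_sequence_single_edge(self, tiny_ref):
        tree = build_lineage_tree([seq_from({0, 5})], tiny_ref)
        assert total_tree_weight(tree) == 2
        assert len(tree.nodes) == 2  # germline + leaf
        assert not any(n.inferred for n in tree.nodes)

    def test_shared_mutation_creates_inferred_intermediate(self, tiny_ref):
        s1 = seq_from({1, 2})
        s2 = seq_from({1, 3})
        tree = build_lineage_tree([s1, s2], tiny_ref)
        assert total_tree_weight(tree) == 3
        inferred = [n for n in tree.nodes if n.inferred]
        assert len(inferred) == 1
        assert inferred[0].mutations == frozenset({(1, NEXT[GERM12[1]])})
        weights = sorted(n.edge_weight for n in tree.nodes if n.parent is not None)
        assert weights == [1, 1, 1]

    def test_nested_sets_form_chain(self, tiny_ref):
        seqs = [seq_from({1}), seq_from({1, 4}), seq_from({1, 4, 8})]
        tree = build_lineage_tree(seqs, tiny_ref)
        assert total_tree_weight(tree) == 3
        assert not any(n.inferred for n in tree.nodes)
        # chain: each observed node has exactly one child except the deepest
        depths = {n.label: len(n.mutations) for n in tree.nodes}
        assert sorted(depths.values()) == [0, 1, 2, 3]

    def test_star_of_singletons(self, tiny_ref):
        seqs = [seq_from({i}) for i in range(5)]
        tree = build_lineage_tree(seqs, tiny_ref)
        assert total_tree_weight(tree) == 5
        assert all(n.parent is tree.root for n in tree.nodes if n.parent is not None)

    def test_weight_at_least_max_leaf_distance(self, tiny_ref):
        rng = np.random.default_rng(1)
        for _ in range(20):
            msets = [
                frozenset(int(x) for x in rng.choice(12, size=rng.integers(1, 7), replace=False))
                for _ in range(rng.integers(1, 5))
            ]
            tree = build_lineage_tree([seq_from(m) for m in msets], tiny_ref)
            assert total_tree_weight(tree) >= max(len(m) for m in msets)

    def test_duplicate_changes_multiplicity_not_topology(self, tiny_ref):
        seqs = [seq_from({1, 2}), seq_from({1, 3})]
        t1 = build_lineage_tree(seqs, tiny_ref)
        t2 = build_lineage_tree(seqs + [seq_from({1, 2})], tiny_ref)
        assert total_tree_weight(t1) == total_tree_weight(t2)
        assert {(n.label, tuple(sorted(n.mutations))) for n in t1.nodes} == {
            (n.label, tuple(sorted(n.mutations))) for n in t2.nodes
        }
        node = [n for n in t2.nodes if n.mutations == frozenset({(1, NEXT[GERM12[1]]), (2, NEXT[GERM12[2]])})][0]
        assert node.multiplicity == 2

    def test_unequal_length_rejected(self, tiny_ref):
        with pytest.raises(ValueError):
            build_lineage_tree(["ACGT"], tiny_ref)


class TestOptimality:
    def test_matches_exhaustive_steiner_on_small_instances(self, tiny_ref):
        """Greedy tree weight equals the exhaustive reversion-free Steiner
        minimum over <=4-sequence instances on a length-12 germline."""
        rng = np.random.default_rng(7)
        for _ in range(120):
            n_seq = int(rng.integers(1, 5))
            universe = int(rng.integers(3, 7))
            observed = {
                frozenset(
                    int(x)
                    for x in rng.choice(universe, size=int(rng.integers(1, universe + 1)),
                                        replace=False)
                )
                for _ in range(n_seq)
            }
            observed = list(observed)
            masks = [sum(1 << p for p in m) for m in observed]
            tree = build_lineage_tree([seq_from(m) for m in observed], tiny_ref)
            for node in tree.nodes:
                if node.parent is not None:
                    assert node.parent.mutations <= node.mutations  # no reversions
            assert total_tree_weight(tree) == steiner_min_no_reversion(masks, universe), observed

    def test_perfect_phylogeny_weight_equals_union(self, tiny_ref):
        seqs = [seq_from({1}), seq_from({1, 4}), seq_from({1, 4, 8}), seq_from({1, 6})]
        tree = build_lineage_tree(seqs, tiny_ref)
        assert total_tree_weight(tree) == len({1, 4, 8, 6})


class TestTruthRecovery:
    def test_simulated_topology_recovered_when_all_nodes_observed(self, ref, hot_model):
        """A lineage without back-mutation in which every internal node is
        observed reconstructs with the simulated parent-child topology."""
        from shmrep.simulate import SimulationConfig, simulate_repertoire

        config = SimulationConfig(
            n_clones=6, clone_size_law="fixed", clone_size_param=6,
            mutations_per_lineage_step=2.0, offspring_mean=1.2, seed=21,
        )
        reads, truth = simulate_repertoire(ref, hot_model, config)
        v_len = len(ref.sequence)
        by_clone: dict[str, list[tuple[str, str]]] = {}
        for rid, seq in reads:
            by_clone.setdefault(truth.reads[rid], []).append((rid, seq[:v_len]))
        for clone_id, members in by_clone.items():
            seqs = [s for _, s in members]
            if len(set(seqs)) != len(seqs):
                continue  # identical sequences collapse; topology comparison undefined
            muts_by_read = {
                rid: frozenset(
                    (p - 1, t) for (p, _f, t, _o) in truth.mutations[rid] if p <= v_len
                )
                for rid, _ in members
            }
            # restrict to clones without back-mutation (child a superset of
            # its parent) and without homoplasy (no mutation event arising
            # independently on two edges) -- the regime where topology
            # recovery is guaranteed
            ok = all(
                muts_by_read[parent] <= muts_by_read[child]
                for parent, child in truth.lineage_edges[clone_id]
            )
            edge_events = [muts_by_read[members[0][0]]] + [
                muts_by_read[c] - muts_by_read[p]
                for p, c in truth.lineage_edges[clone_id]
            ]
            all_events = [e for ev in edge_events for e in ev]
            if not ok or len(all_events) != len(set(all_events)):
                continue
            tree = build_lineage_tree(members, ref, clone_id)
            rec_edges = {
                (p, c) for (p, c, _w) in tree.edges() if not p.startswith("inferred")
            }
            founder = members[0][0]
            true_edges = set(truth.lineage_edges[clone_id])
            # an unmutated founder merges with the germline root; a mutated
            # founder gains an explicit germline -> founder edge
            if muts_by_read[founder]:
                expected = true_edges | {("germline", founder)}
            else:
                expected = {("germline" if p == founder else p, c) for p, c in true_edges}
            assert rec_edges == expected, clone_id


class TestNewick:
    def test_single_leaf_shape(self, tiny_ref):
        tree = build_lineage_tree([("leaf", seq_from({0, 5}))], tiny_ref)
        assert write_newick(tree) == "(leaf:2)germline;"

    def test_round_trip_topology_and_weights(self, tiny_ref):
        seqs = [seq_from({1, 2}), seq_from({1, 3}), seq_from({1, 3, 5})]
        tree = build_lineage_tree(seqs, tiny_ref)
        parsed = Phylo.read(StringIO(write_newick(tree)), "newick")
        parsed_edges = {}
        for clade in parsed.find_clades():
            for child in clade.clades:
                parsed_edges[child.name] = child.branch_length
        for parent, child, weight in tree.edges():
            assert parsed_edges[child] == weight

    def test_node_labels_unique(self, tiny_ref):
        seqs = [seq_from({1, 2}), seq_from({1, 3}), seq_from({4, 5}), seq_from({4, 6})]
        tree = build_lineage_tree(seqs, tiny_ref)
        labels = [n.label for n in tree.nodes]
        assert len(labels) == len(set(labels))
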