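import itertools

import dendropy
import numpy as np
import pytest

from genefamkit.errors import ConfigurationError, EmptyOverlapError, SaturationError
from genefamkit.njtree import (
    DistanceMatrix,
    bootstrap_tree,
    build_nj,
    jc_distance,
    p_distance,
    write_newick,
)


def random_additive_case(rng, n_taxa):
    """A random binary unrooted tree as (bipartition set, path-metric matrix)."""
    labels = [f"T{i}" for i in range(n_taxa)]
    # build by sequential taxon attachment to a random edge of a growing tree
    graph = {}  # node -> {neighbor: length}

    def add_edge(a, b, w):
        graph.setdefault(a, {})[b] = w
        graph.setdefault(b, {})[a] = w

    def del_edge(a, b):
        del graph[a][b]
        del graph[b][a]

    add_edge(labels[0], labels[1], rng.uniform(0.1, 1.0))
    next_internal = 0
    for leaf in labels[2:]:
        edges = [(a, b) for a in graph for b in graph[a] if a < b]
        a, b = edges[rng.integers(0, len(edges))]
        w = graph[a][b]
        mid = f"I{next_internal}"
        next_internal += 1
        del_edge(a, b)
        split = rng.uniform(0.25, 0.75) * w
        add_edge(a, mid, split)
        add_edge(mid, b, w - split)
        add_edge(mid, leaf, rng.uniform(0.1, 1.0))

    def path_len(src, dst):
        stack = [(src, 0.0, None)]
        while stack:
            node, dist, prev = stack.pop()
            if node == dst:
                return dist
            for nxt, w in graph[node].items():
                if nxt != prev:
                    stack.append((nxt, dist + w, node))
        raise AssertionError("disconnected")

    d = np.zeros((n_taxa, n_taxa))
    for i, j in itertools.combinations(range(n_taxa), 2):
        d[i, j] = d[j, i] = path_len(labels[i], labels[j])

    biparts = set()
    all_set = frozenset(labels)
    for node in graph:
        for nxt in graph[node]:
            side = set()
            stack = [(nxt, node)]
            while stack:
                cur, prev = stack.pop()
                if cur in labels:
                    side.add(cur)
                for k in graph[cur]:
                    if k != prev:
                        stack.append((k, cur))
            side = frozenset(side)
            if 1 < len(side) < n_taxa - 1:
                biparts.add(frozenset([side, all_set - side]))
    return labels, d, biparts, graph


def least_squares_topologies(labels, d):
    """Brute-force best unrooted topology by least-squares branch fitting."""
    n = len(labels)
    best = (np.inf, None)
    for tree_labels, _, biparts, graph in all_topologies(labels):
        # path incidence matrix: rows = taxon pairs, cols = edges
        edges = sorted({tuple(sorted((a, b))) for a in graph for b in graph[a]})
        eindex = {e: k for k, e in enumerate(edges)}
        pairs = list(itertools.combinations(range(n), 2))
        A = np.zeros((len(pairs), len(edges)))
        for row, (i, j) in enumerate(pairs):
            path = find_path(graph, labels[i], labels[j])
            for a, b in zip(path, path[1:]):
                A[row, eindex[tuple(sorted((a, b)))]] = 1
        y = np.array([d[i, j] for i, j in pairs])
        x, *_ = np.linalg.lstsq(A, y, rcond=None)
        sse = ((A @ x - y) ** 2).sum()
        if sse < best[0] - 1e-12:
            best = (sse, biparts)
    return best[1]


def find_path(graph, src, dst):
    stack = [[src]]
    while stack:
        path = stack.pop()
        if path[-1] == dst:
            return path
        for nxt in graph[path[-1]]:
            if len(path) < 2 or nxt != path[-2]:
                stack.append(path + [nxt])
    raise AssertionError("disconnected")


def all_topologies(labels):
    """Every unrooted binary topology by sequential insertion."""
    if len(labels) < 4:
        raise ValueError("need >= 4 taxa")
    base = {labels[0]: {"I0": 1}, labels[1]: {"I0": 1}, labels[2]: {"I0": 1},
            "I0": {labels[0]: 1, labels[1]: 1, labels[2]: 1}}
    trees = [base]
    counter = [1]
    for leaf in labels[3:]:
        new_trees = []
        for graph in trees:
            edges = sorted({tuple(sorted((a, b))) for a in graph for b in graph[a]})
            for a, b in edges:
                g = {k: dict(v) for k, v in graph.items()}
                mid = f"I{counter[0]}"
                del g[a][b]
                del g[b][a]
                g[mid] = {a: 1, b: 1, leaf: 1}
                g[a][mid] = g[b][mid] = 1
                g[leaf] = {mid: 1}
                new_trees.append(g)
        counter[0] += 1
        trees = new_trees
    out = []
    all_set = frozenset(labels)
    for graph in trees:
        biparts = set()
        for node in graph:
            for nxt in graph[node]:
                side = set()
                stack = [(nxt, node)]
                while stack:
                    cur, prev = stack.pop()
                    if cur in all_set:
                        side.add(cur)
                    for k in graph[cur]:
                        if k != prev:
                            stack.append((k, cur))
                side = frozenset(side)
                if 1 < len(side) < len(labels) - 1:
                    biparts.add(frozenset([side, all_set - side]))
        out.append((labels, None, biparts, graph))
    return out


class TestDistances:
    def test_identical(self):
        assert jc_distance("ACGTACGT", "ACGTACGT") == 0

    def test_closed_form(self):
        seq_a = "A" * 100
        seq_b = "C" * 6 + "A" * 94
        assert jc_distance(seq_a, seq_b) == pytest.approx(0.0625, abs=1e-4)

    def test_all_gap_overlap(self):
        with pytest.raises(EmptyOverlapError):
            jc_distance("AC--", "--GT")

    def test_saturation(self):
        with pytest.raises(SaturationError):
            jc_distance("AAAA", "CCCC")

    def test_pairwise_deletion(self):
        assert p_distance("AC-T", "ACNT") == 0.0


class TestBuildNJ:
    def test_three_taxon_star(self):
        dm = DistanceMatrix(("A", "B", "C"),
                            np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float))
        tree = build_nj(dm)
        assert write_newick(tree) == "(A:1,B:2,C:3);"

    def test_four_taxon_additive(self):
        d = np.array([[0, 3, 5, 6], [3, 0, 6, 7],
                      [5, 6, 0, 7], [6, 7, 7, 0]], float)
        tree = build_nj(DistanceMatrix(("A", "B", "C", "D"), d))
        biparts = {frozenset(map(frozenset, [["A", "B"], ["C", "D"]]))}
        assert set(tree.bipartitions()) == biparts
        recovered = tree.distance_matrix()
        order = [recovered.labels.index(x) for x in ("A", "B", "C", "D")]
        assert np.allclose(recovered.d[np.ix_(order, order)], d, atol=1e-9)

    def test_zero_matrix_degenerate(self):
        dm = DistanceMatrix(("A", "B", "C", "D"), np.zeros((4, 4)))
        tree = build_nj(dm)
        assert np.allclose(tree.distance_matrix().d, 0)

    def test_too_few_taxa(self):
        with pytest.raises(ConfigurationError):
            build_nj(DistanceMatrix(("A", "B"), np.zeros((2, 2))))

    def test_nan_rejected(self):
        d = np.zeros((3, 3))
        d[0, 1] = d[1, 0] = np.nan
        with pytest.raises(ConfigurationError):
            DistanceMatrix(("A", "B", "C"), d)

    @pytest.mark.parametrize("n_taxa", [4, 5])
    def test_additive_recovery_random(self, n_taxa):
        rng = np.random.default_rng(42 + n_taxa)
        for _ in range(40):
            labels, d, biparts, _ = random_additive_case(rng, n_taxa)
            tree = build_nj(DistanceMatrix(tuple(labels), d))
            assert set(tree.bipartitions()) == biparts
            recovered = tree.distance_matrix()
            order = [recovered.labels.index(x) for x in labels]
            assert np.allclose(recovered.d[np.ix_(order, order)], d, atol=1e-9)

    def test_least_squares_oracle(self):
        rng = np.random.default_rng(99)
        for _ in range(15):
            n = int(rng.integers(4, 6))
            labels, d, _, _ = random_additive_case(rng, n)
            tree = build_nj(DistanceMatrix(tuple(labels), d))
            assert set(tree.bipartitions()) == least_squares_topologies(labels, d)


def conflict_free_alignment():
    """Every variable column supports AB|CD."""
    const = "A" * 70
    var = "G" * 30
    return {
        "A": const + "A" * 30,
        "B": const + "A" * 30,
        "C": const + var,
        "D": const + var,
    }


class TestBootstrap:
    def test_conflict_free_full_support(self):
        tree = bootstrap_tree(conflict_free_alignment(), b=100, seed=1)
        supports = [n.support for n in tree.internal_nodes()]
        assert supports == [100.0]

    def test_single_replicate_support_binary(self):
        tree = bootstrap_tree(conflict_free_alignment(), b=1, seed=1)
        assert all(n.support in (0.0, 100.0) for n in tree.internal_nodes())

    def test_deterministic_given_seed(self):
        seqs = conflict_free_alignment()
        t1 = bootstrap_tree(seqs, b=25, seed=7)
        t2 = bootstrap_tree(seqs, b=25, seed=7)
        assert write_newick(t1) == write_newick(t2)

    def test_supports_invariant_under_taxon_permutation(self):
        rng = np.random.default_rng(3)
        bases = "ACGT"
        seqs = {}
        anc = rng.integers(0, 4, 200)
        for label in "ABCDE":
            mutated = anc.copy()
            idx = rng.choice(200, size=18, replace=False)
            mutated[idx] = (mutated[idx] + rng.integers(1, 4, 18)) % 4
            seqs[label] = "".join(bases[i] for i in mutated)

        def support_map(d):
            tree = bootstrap_tree(d, b=50, seed=11)
            return {
                key: node.support for key, node in tree.bipartitions().items()
            }

        direct = support_map(seqs)
        permuted = support_map(dict(reversed(list(seqs.items()))))
        assert direct == permuted

    def test_bad_replicate_count(self):
        with pytest.raises(ConfigurationError):
            bootstrap_tree(conflict_free_alignment(), b=0)

    def test_support_bounds(self):
        tree = bootstrap_tree(conflict_free_alignment(), b=10, seed=2)
        for node in tree.internal_nodes():
            assert 0 <= node.support <= 100


class TestNewick:
    def test_three_taxon_format(self):
        dm = DistanceMatrix(("A", "B", "C"),
                            np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float))
        assert write_newick(build_nj(dm)) == "(A:1,B:2,C:3);"

    def test_support_label(self):
        tree = bootstrap_tree(conflict_free_alignment(), b=100, seed=1)
        assert ")100:" in write_newick(tree)

    def test_round_trip_preserves_topology_and_lengths(self):
        rng = np.random.default_rng(12)
        labels, d, biparts, _ = random_additive_case(rng, 5)
        tree = build_nj(DistanceMatrix(tuple(labels), d))
        text = write_newick(tree)
        parsed = dendropy.Tree.get(data=text, schema="newick")
        parsed_biparts = set()
        parsed.encode_bipartitions()
        taxa = frozenset(l.taxon.label for l in parsed.leaf_node_iter())
        for edge in parsed.preorder_edge_iter():
            if edge.head_node.is_leaf() or edge.head_node == parsed.seed_node:
                continue
            side = frozenset(
                l.taxon.label for l in edge.head_node.leaf_iter()
            )
            if 1 < len(side) < len(taxa) - 1:
                parsed_biparts.add(frozenset([side, taxa - side]))
        assert parsed_biparts == biparts
        pdm = parsed.phylogenetic_distance_matrix()
        for t1 in parsed.taxon_namespace:
            for t2 in parsed.taxon_namespace:
                if t1.label < t2.label:
                    i, j = labels.index(t1.label), labels.index(t2.label)
                    assert pdm.distance(t1, t2) == pytest.approx(d[i, j], abs=1e-9)
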