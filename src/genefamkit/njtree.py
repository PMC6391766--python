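"""Neighbor-Joining tree construction with bootstrap branch support.

Distance input is either a precomputed matrix or a multiple alignment, from
which Jukes–Cantor (default) or raw p-distances are computed with pairwise
deletion of gapped/ambiguous columns.  Trees are unrooted; the root of the
internal representation is simply the final degree-3 join.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, EmptyOverlapError, SaturationError

_VALID = frozenset("ACGT")


def jc_distance(seq_a: str, seq_b: str) -> float:
    """Jukes–Cantor distance with pairwise deletion of non-ACGT columns."""
    p = p_distance(seq_a, seq_b)
    if p >= 0.75:
        raise SaturationError(f"p-distance {p} >= 3/4: JC distance undefined")
    if p == 0:
        return 0.0
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def p_distance(seq_a: str, seq_b: str) -> float:
    """Mismatch proportion over columns where both sequences have A/C/G/T."""
    if len(seq_a) != len(seq_b):
        raise ConfigurationError("aligned sequences differ in length")
    comparable = 0
    mismatches = 0
    for a, b in zip(seq_a.upper(), seq_b.upper()):
        if a in _VALID and b in _VALID:
            comparable += 1
            if a != b:
                mismatches += 1
    if comparable == 0:
        raise EmptyOverlapError("no comparable ungapped site between sequences")
    return mismatches / comparable


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.d, dtype=float)
        object.__setattr__(self, "d", d)
        n = len(self.labels)
        if d.shape != (n, n):
            raise ConfigurationError("matrix shape does not match label count")
        if np.isnan(d).any():
            raise ConfigurationError("distance matrix contains NaN entries")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ConfigurationError("distance matrix is not symmetric")
        if np.any(np.diag(d) != 0):
            raise ConfigurationError("distance matrix diagonal must be zero")
        if np.any(d < 0):
            raise ConfigurationError("distances must be non-negative")


class Node:
    """Tree node; leaves carry ``name``, internal edges may carry ``support``."""

    __slots__ = ("name", "children", "support")

    def __init__(self, name=None, children=None, support=None):
        self.name = name
        self.children: list[tuple["Node", float]] = children or []
        self.support = support

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_names(self) -> frozenset[str]:
        if self.is_leaf:
            return frozenset([self.name])
        out: set[str] = set()
        for child, _ in self.children:
            out |= child.leaf_names()
        return frozenset(out)


@dataclass
class Tree:
    """Unrooted phylogeny, stored rooted at the final degree-3 join."""

    root: Node
    labels: tuple[str, ...]

    def leaf_names(self) -> frozenset[str]:
        return self.root.leaf_names()

    def internal_nodes(self) -> list[Node]:
        """Non-root internal nodes; each defines one internal edge."""
        out: list[Node] = []

        def walk(node: Node):
            for child, _ in node.children:
                if not child.is_leaf:
                    out.append(child)
                walk(child)

        walk(self.root)
        return out

    def bipartitions(self) -> dict[frozenset[frozenset[str]], Node]:
        """Map internal-edge bipartition keys to the node below the edge."""
        all_leaves = self.leaf_names()
        out: dict[frozenset[frozenset[str]], Node] = {}
        for node in self.internal_nodes():
            side = node.leaf_names()
            key = frozenset([side, all_leaves - side])
            out[key] = node
        return out

    def distance_matrix(self) -> DistanceMatrix:
        """Path-length metric between all leaves (for additivity checks)."""
        labels = sorted(self.leaf_names())
        index = {name: i for i, name in enumerate(labels)}
        n = len(labels)
        d = np.zeros((n, n))

        def pairs(node: Node) -> dict[str, float]:
            if node.is_leaf:
                return {node.name: 0.0}
            sub: list[dict[str, float]] = []
            for child, length in node.children:
                below = pairs(child)
                sub.append({k: v + length for k, v in below.items()})
            for i in range(len(sub)):
                for j in range(i + 1, len(sub)):
                    for la, da in sub[i].items():
                        for lb, db in sub[j].items():
                            d[index[la], index[lb]] = d[index[lb], index[la]] = da + db
            merged: dict[str, float] = {}
            for s in sub:
                merged.update(s)
            return merged

        pairs(self.root)
        return DistanceMatrix(tuple(labels), d)


def build_nj(dm: DistanceMatrix) -> Tree:
    """Saitou–Nei agglomeration minimising the Q-criterion.

    Ties in Q are broken by the lowest (i, j) index pair in the current node
    order (merged nodes are appended at the end), which makes the result
    deterministic across platforms.  Negative branch lengths are clamped to
    zero with the deficit moved to the sister branch.
    """
    n = len(dm.labels)
    if n < 3:
        raise ConfigurationError("neighbor joining requires at least 3 taxa")
    nodes: list[Node] = [Node(name=label) for label in dm.labels]
    d = dm.d.astype(float).copy()

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        best = None
        best_q = math.inf
        for i in range(m):
            for j in range(i + 1, m):
                if q[i, j] < best_q:
                    best_q = q[i, j]
                    best = (i, j)
        i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        new = Node(children=[(nodes[i], li), (nodes[j], lj)])
        dnew = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [x for x in range(m) if x not in (i, j)]
        d2 = np.zeros((m - 1, m - 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = dnew[keep]
        d = d2
        nodes = [nodes[x] for x in keep] + [new]

    dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
    la = max(0.0, 0.5 * (dab + dac - dbc))
    lb = max(0.0, 0.5 * (dab + dbc - dac))
    lc = max(0.0, 0.5 * (dac + dbc - dab))
    root = Node(children=[(nodes[0], la), (nodes[1], lb), (nodes[2], lc)])
    return Tree(root=root, labels=dm.labels)


def alignment_distance_matrix(
    sequences: dict[str, str], model: str = "jc"
) -> DistanceMatrix:
    """Pairwise JC or p-distance matrix from a multiple alignment."""
    if model not in ("jc", "p"):
        raise ConfigurationError(f"unknown distance model {model!r}")
    dist = jc_distance if model == "jc" else p_distance
    labels = tuple(sequences)
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = dist(sequences[labels[i]], sequences[labels[j]])
    return DistanceMatrix(labels, d)


def nj_from_alignment(sequences: dict[str, str], model: str = "jc") -> Tree:
    return build_nj(alignment_distance_matrix(sequences, model=model))


def bootstrap_tree(
    sequences: dict[str, str],
    b: int = 1000,
    seed: int = 1378,
    model: str = "jc",
) -> Tree:
    """NJ point-estimate tree with bootstrap supports on internal edges.

    Alignment columns are resampled with replacement ``b`` times; support of
    each internal edge of the point tree is the percentage of replicate trees
    containing the same bipartition.  Replicates whose distance matrix cannot
    be computed (saturation / empty overlap) contribute no bipartitions but
    stay in the denominator.  Deterministic for a given seed.
    """
    if b < 1:
        raise ConfigurationError("bootstrap replicate count must be >= 1")
    length = len(next(iter(sequences.values())))
    if length < 1:
        raise ConfigurationError("alignment must have at least one column")
    tree = nj_from_alignment(sequences, model=model)
    point_biparts = tree.bipartitions()
    counts = {key: 0 for key in point_biparts}
    rng = np.random.default_rng(seed)
    labels = list(sequences)
    seq_arrays = {k: np.frombuffer(v.encode(), dtype="S1") for k, v in sequences.items()}
    for _ in range(b):
        idx = rng.integers(0, length, size=length)
        resampled = {
            k: seq_arrays[k][idx].tobytes().decode() for k in labels
        }
        try:
            rep = nj_from_alignment(resampled, model=model)
        except (SaturationError, EmptyOverlapError):
            continue
        rep_keys = rep.bipartitions().keys()
        for key in counts:
            if key in rep_keys:
                counts[key] += 1
    for key, node in point_biparts.items():
        node.support = 100.0 * counts[key] / b
    return tree


def _fmt_len(x: float) -> str:
    return f"{x:.10g}"


def _newick_node(node: Node, length: float | None) -> str:
    if node.is_leaf:
        body = node.name
    else:
        inner = ",".join(_newick_node(c, l) for c, l in node.children)
        label = "" if node.support is None else str(int(round(node.support)))
        body = f"({inner}){label}"
    if length is None:
        return body
    return f"{body}:{_fmt_len(length)}"


def write_newick(tree: Tree) -> str:
    """Serialise to Newick with branch lengths and integer support labels."""
    inner = ",".join(_newick_node(c, l) for c, l in tree.root.children)
    return f"({inner});"
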