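"""Leaf-labeled unrooted bifurcating tree topologies and their ordinal construction.

A tree topology on ``N`` taxa is grown autoregressively: starting from the unique
3-leaf star, each step attaches the next leaf (in a fixed taxa order) to one of the
``2n - 3`` edges of the current rank-``n`` tree.  This yields a bijection between
topologies and decision sequences ``(d_3, ..., d_{N-1})`` with ``d_n < 2n - 3``,
hence ``prod_n (2n-3) = (2N-5)!!`` distinct trees.

Node keys
---------
Leaves carry their global taxon index ``0..N-1``; the interior node created at
step ``k`` carries key ``N + (k - 3)`` (creation order).  Edges are stored as
``(min, max)`` key pairs and the canonical edge order is the lexicographic sort
of those pairs.  This keying makes the adjacency updates of :func:`attach_leaf`
touch O(1) entries besides the appended row/column.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import dendropy

__all__ = [
    "TaxaOrder",
    "OrdinalTreeState",
    "Topology",
    "DecisionSequence",
    "init_state",
    "attach_leaf",
    "replay",
    "decompose",
    "enumerate_topologies",
    "read_newick",
    "write_newick",
    "rf_distance",
]


class TaxaOrder:
    """A fixed ordering of taxon labels; defaults to lexicographic."""

    def __init__(self, names: Sequence[str], sort: bool = True):
        names = list(names)
        if len(set(names)) != len(names):
            raise ValueError("duplicate taxon labels")
        self.names: tuple[str, ...] = tuple(sorted(names) if sort else names)
        self.index_of: dict[str, int] = {x: i for i, x in enumerate(self.names)}

    def __len__(self) -> int:
        return len(self.names)

    def __eq__(self, other) -> bool:
        return isinstance(other, TaxaOrder) and self.names == other.names

    def __hash__(self) -> int:
        return hash(self.names)

    def __repr__(self) -> str:
        return f"TaxaOrder({list(self.names)!r})"

    @classmethod
    def generic(cls, n: int) -> "TaxaOrder":
        """``t00 .. t{n-1}`` — zero-padded so lexicographic = numeric order."""
        width = len(str(max(n - 1, 1)))
        return cls([f"t{i:0{width}d}" for i in range(n)], sort=False)


@dataclass
class OrdinalTreeState:
    """A rank-``n`` tree mid-construction, with its adjacency bookkeeping.

    ``A`` is the (n-2)x(n-2) interior adjacency, ``C`` the (n-2)xn
    leaf-interior cross adjacency; every interior node has total degree 3.
    """

    taxa: TaxaOrder
    n: int
    A: np.ndarray
    C: np.ndarray
    edges: list[tuple[int, int]]
    interior_creation: dict[int, int] = field(default_factory=dict)

    @property
    def N(self) -> int:
        return len(self.taxa)

    def is_complete(self) -> bool:
        return self.n == self.N

    def node_row(self, key: int) -> int:
        """Row of a node key in the stacked embedding matrix (leaves first)."""
        return key if key < self.N else self.n + (key - self.N)

    def edge_rows(self) -> np.ndarray:
        """(2n-3, 2) array of embedding-row indices of each edge's endpoints."""
        return np.array(
            [[self.node_row(u), self.node_row(v)] for (u, v) in self.edges],
            dtype=np.intp,
        )

    def neighbors(self) -> dict[int, list[int]]:
        adj: dict[int, list[int]] = {}
        for u, v in self.edges:
            adj.setdefault(u, []).append(v)
            adj.setdefault(v, []).append(u)
        return adj

    def to_topology(self) -> "Topology":
        if not self.is_complete():
            raise ValueError("state is not at full rank")
        return Topology(self.taxa, {k: tuple(v) for k, v in self.neighbors().items()})

    def check(self) -> None:
        """Validate the structural invariants; raises on violation."""
        n = self.n
        assert self.A.shape == (n - 2, n - 2) and self.C.shape == (n - 2, n)
        assert np.array_equal(self.A, self.A.T) and not self.A.diagonal().any()
        assert len(self.edges) == 2 * n - 3
        deg = self.A.sum(axis=1) + self.C.sum(axis=1)
        assert (deg == 3).all(), "interior degree must be 3"
        adj = self.neighbors()
        assert len(adj) == 2 * n - 2
        assert all(len(adj[i]) == 1 for i in range(n)), "leaves must have degree 1"


class DecisionSequence:
    """Edge choices ``(d_3, ..., d_{N-1})`` encoding a topology."""

    def __init__(self, decisions: Sequence[int]):
        self.decisions = tuple(int(d) for d in decisions)
        for k, d in enumerate(self.decisions):
            n = k + 3
            if not 0 <= d < 2 * n - 3:
                raise ValueError(f"decision {d} out of range at rank {n}")

    def __len__(self) -> int:
        return len(self.decisions)

    def __iter__(self):
        return iter(self.decisions)

    def __getitem__(self, i):
        return self.decisions[i]

    def __eq__(self, other) -> bool:
        return isinstance(other, DecisionSequence) and self.decisions == other.decisions

    def __hash__(self) -> int:
        return hash(self.decisions)

    def __repr__(self) -> str:
        return f"DecisionSequence{self.decisions!r}"


class Topology:
    """An immutable unrooted bifurcating tree on a fixed taxa set.

    Equality and hashing are by the set of non-trivial splits (leaf-index
    bipartitions), so they are independent of interior-node keying.
    """

    def __init__(
        self,
        taxa: TaxaOrder,
        neighbors: Mapping[int, tuple[int, ...]],
        lengths: Mapping[tuple[int, int], float] | None = None,
    ):
        self.taxa = taxa
        self.neighbors = {k: tuple(v) for k, v in neighbors.items()}
        self.lengths = dict(lengths) if lengths else None
        N = len(taxa)
        for i in range(N):
            if len(self.neighbors.get(i, ())) != 1:
                raise ValueError("leaves must have degree 1")
        for k, nb in self.neighbors.items():
            if k >= N and len(nb) != 3:
                raise ValueError("tree is not bifurcating (internal degree != 3)")
        self._splits: frozenset[frozenset[int]] | None = None

    @property
    def N(self) -> int:
        return len(self.taxa)

    @property
    def edges(self) -> list[tuple[int, int]]:
        return sorted(
            {(min(u, v), max(u, v)) for u, nb in self.neighbors.items() for v in nb}
        )

    def splits(self) -> frozenset[frozenset[int]]:
        """Non-trivial splits, each as the leaf-index side not containing 0."""
        if self._splits is None:
            out = []
            for u, v in self.edges:
                if u < self.N:  # pendant edge -> trivial split
                    continue
                side = self._leafside(u, v)
                if 0 in side:
                    side = set(range(self.N)) - side
                out.append(frozenset(side))
            self._splits = frozenset(out)
        return self._splits

    def _leafside(self, u: int, v: int) -> set[int]:
        """Leaves reachable from u when the edge (u, v) is cut."""
        seen, stack, leaves = {v, u}, [u], set()
        while stack:
            w = stack.pop()
            if w < self.N:
                leaves.add(w)
            for x in self.neighbors[w]:
                if x not in seen:
                    seen.add(x)
                    stack.append(x)
        return leaves

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Topology)
            and self.taxa == other.taxa
            and self.splits() == other.splits()
        )

    def __hash__(self) -> int:
        return hash((self.taxa, self.splits()))

    def __repr__(self) -> str:
        return f"<Topology N={self.N} splits={len(self.splits())}>"


def init_state(taxa_order: TaxaOrder) -> OrdinalTreeState:
    """The unique rank-3 tree: one interior node joined to the first 3 leaves."""
    N = len(taxa_order)
    if N < 3:
        raise ValueError("need at least 3 taxa")
    A = np.zeros((1, 1), dtype=np.int8)
    C = np.array([[1, 1, 1]], dtype=np.int8)
    edges = [(0, N), (1, N), (2, N)]
    return OrdinalTreeState(taxa_order, 3, A, C, edges, {0: 3})


def attach_leaf(state: OrdinalTreeState, edge_index: int) -> OrdinalTreeState:
    """Subdivide the chosen edge with a new interior node and hang the next leaf on it.

    Returns a new rank-(n+1) state; the input is not modified.  The adjacency
    update clears at most one entry of ``A``/``C`` and fills the appended
    row/column, so it is O(1) beyond the reallocation.
    """
    n, N = state.n, state.N
    if n >= N:
        raise ValueError("state is already at full rank")
    if not 0 <= edge_index < 2 * n - 3:
        raise IndexError(f"edge index {edge_index} out of range [0, {2 * n - 3})")

    a, b = state.edges[edge_index]
    w = N + (n - 2)  # key of the new interior node
    leaf = n  # key of the new leaf

    A = np.zeros((n - 1, n - 1), dtype=np.int8)
    A[: n - 2, : n - 2] = state.A
    C = np.zeros((n - 1, n + 1), dtype=np.int8)
    C[: n - 2, :n] = state.C
    new_row = n - 2

    for x in (a, b):
        if x < N:  # leaf endpoint: re-home its pendant edge onto w
            other = b if x == a else a
            C[other - N, x] = 0
            C[new_row, x] = 1
        else:
            if a >= N and b >= N:
                A[a - N, b - N] = A[b - N, a - N] = 0
            A[x - N, new_row] = A[new_row, x - N] = 1
    C[new_row, leaf] = 1

    edges = [e for e in state.edges if e != (a, b)]
    edges += [(min(a, w), max(a, w)), (min(b, w), max(b, w)), (leaf, w)]
    edges.sort()
    creation = dict(state.interior_creation)
    creation[new_row] = n + 1
    return OrdinalTreeState(state.taxa, n + 1, A, C, edges, creation)


def replay(decisions: DecisionSequence | Sequence[int], taxa_order: TaxaOrder) -> Topology:
    """Rebuild the topology encoded by a decision sequence."""
    state = init_state(taxa_order)
    for d in decisions:
        state = attach_leaf(state, d)
    if not state.is_complete():
        raise ValueError("decision sequence shorter than N - 3")
    return state.to_topology()


def decompose(topology: Topology, taxa_order: TaxaOrder | None = None) -> DecisionSequence:
    """Invert the leaf-addition construction.

    Peels the highest-indexed leaf at each step (deleting its interior
    neighbor and fusing the two remaining edges), then replays forward to
    read off each fused edge's canonical index in the reduced state.
    """
    taxa_order = taxa_order or topology.taxa
    if taxa_order != topology.taxa:
        raise ValueError("taxa order does not match the topology's leaf set")
    N = topology.N
    nbrs = {k: list(v) for k, v in topology.neighbors.items()}

    # Peel: record, for each rank n = N-1 .. 3, the fused edge (a, b) by the
    # ORIGINAL node ids, and the interior node removed along with leaf n.
    fused: list[tuple[int, int, int]] = []  # (a, b, removed_interior)
    for leaf in range(N - 1, 2, -1):
        (w,) = nbrs[leaf]
        a, b = (x for x in nbrs[w] if x != leaf)
        for x, other in ((a, b), (b, a)):
            nbrs[x] = [other if y == w else y for y in nbrs[x]]
        del nbrs[leaf], nbrs[w]
        fused.append((a, b, w))
    fused.reverse()

    # Replay: map original interior ids to state keys as they get created.
    state = init_state(taxa_order)
    (root,) = (k for k in nbrs if k >= N)  # the single surviving interior node
    orig2key = {root: N}
    for i in range(N):
        orig2key[i] = i
    decisions = []
    for n in range(3, N):
        a, b, w = fused[n - 3]
        ka, kb = orig2key[a], orig2key[b]
        target = (min(ka, kb), max(ka, kb))
        decisions.append(state.edges.index(target))
        state = attach_leaf(state, decisions[-1])
        orig2key[w] = N + (n - 2)
    return DecisionSequence(decisions)


def enumerate_topologies(N: int, taxa_order: TaxaOrder | None = None) -> list[Topology]:
    """All (2N-5)!! leaf-labeled topologies on N taxa, via decision sequences."""
    if N > 8:
        raise ValueError("refusing to enumerate beyond N = 8")
    taxa_order = taxa_order or TaxaOrder.generic(N)
    out: list[Topology] = []

    def grow(state: OrdinalTreeState):
        if state.is_complete():
            out.append(state.to_topology())
            return
        for d in range(2 * state.n - 3):
            grow(attach_leaf(state, d))

    grow(init_state(taxa_order))
    return out


def rf_distance(t1: Topology, t2: Topology) -> int:
    """Robinson-Foulds distance: |symmetric difference of non-trivial splits|."""
    if t1.taxa != t2.taxa:
        raise ValueError("trees are over different leaf sets")
    return len(t1.splits() ^ t2.splits())


# ---------------------------------------------------------------------------
# Newick I/O (dendropy-backed parsing; unrooted semantics)
# ---------------------------------------------------------------------------

def _from_dendropy(tree: dendropy.Tree, taxa_order: TaxaOrder | None) -> Topology:
    tree.encode_bipartitions(suppress_unifurcations=True, collapse_unrooted_basal_bifurcation=True)
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    taxa = taxa_order or TaxaOrder(labels)
    if set(labels) != set(taxa.names) or len(labels) != len(taxa.names):
        raise ValueError("leaf labels do not match the taxa order")

    next_key = len(taxa)
    keys: dict[int, int] = {}
    nbrs: dict[int, list[int]] = {}
    lengths: dict[tuple[int, int], float] = {}
    any_length = False

    def key_of(node) -> int:
        nonlocal next_key
        nid = id(node)
        if nid not in keys:
            if node.is_leaf():
                keys[nid] = taxa.index_of[node.taxon.label]
            else:
                keys[nid] = next_key
                next_key += 1
        return keys[nid]

    root = tree.seed_node
    if len(root.child_nodes()) == 2:  # rooted binary input: suppress the root
        tree.deroot()
        root = tree.seed_node
    for node in tree.preorder_node_iter():
        for child in node.child_nodes():
            u, v = key_of(node), key_of(child)
            nbrs.setdefault(u, []).append(v)
            nbrs.setdefault(v, []).append(u)
            if child.edge.length is not None:
                any_length = True
                lengths[(min(u, v), max(u, v))] = float(child.edge.length)
    return Topology(taxa, {k: tuple(v) for k, v in nbrs.items()},
                    lengths if any_length else None)


def read_newick(source: str, taxa_order: TaxaOrder | None = None) -> Topology:
    """Parse one Newick string (or a path to a file holding one tree)."""
    text = source
    if "(" not in source:
        with open(source) as fh:
            text = fh.read()
    tree = dendropy.Tree.get(data=text, schema="newick",
                             suppress_internal_node_taxa=True)
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate leaf labels in Newick input")
    return _from_dendropy(tree, taxa_order)


def write_newick(topology: Topology, path: str | None = None) -> str:
    """Serialize with a trifurcation at an interior node; lengths if present."""
    N = topology.N
    root = topology.neighbors[0][0]  # interior node next to the first leaf

    def fmt(u: int, parent: int) -> str:
        lab = topology.taxa.names[u] if u < N else ""
        if u >= N:
            kids = ",".join(fmt(v, u) for v in topology.neighbors[u] if v != parent)
            lab = f"({kids})"
        if topology.lengths is not None and parent >= 0:
            q = topology.lengths[(min(u, parent), max(u, parent))]
            lab += f":{q:.10g}"
        return lab

    text = fmt(root, -1) + ";"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text


def read_tree_set(path: str, taxa_order: TaxaOrder | None = None
                  ) -> tuple[list[Topology], np.ndarray]:
    """Read a list of Newick trees, one per line, optional tab-separated weight.

    Returns (topologies, weights); weights are normalized to sum to 1 and
    default to uniform when no weight column is present.
    """
    trees: list[Topology] = []
    weights: list[float] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if "\t" in line:
                nwk, w = line.split("\t")
                weights.append(float(w))
            else:
                nwk = line
                weights.append(1.0)
            trees.append(read_newick(nwk, taxa_order))
    w = np.asarray(weights, dtype=float)
    return trees, w / w.sum()


def write_tree_set(path: str, trees: Iterable[Topology],
                   weights: Sequence[float] | None = None) -> None:
    buf = io.StringIO()
    for i, t in enumerate(trees):
        buf.write(write_newick(t))
        if weights is not None:
            buf.write(f"\t{weights[i]:.10g}")
        buf.write("\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())
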