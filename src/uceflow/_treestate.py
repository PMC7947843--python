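"""Lightweight unrooted binary tree over integer leaf ids.

The likelihood engine and the quartet search both need fast topology
surgery (NNI), split extraction and conversion to/from dendropy.  dendropy
trees stay the public interchange format; :class:`TreeState` is the
internal array-of-adjacency representation those algorithms run on.
Leaves are ``0..n-1`` (indexing a caller-supplied taxon list), internal
nodes are ``>= n``.
"""

from __future__ import annotations

import dendropy
import numpy as np

__all__ = ["TreeState"]


class TreeState:
    """Unrooted tree with branch lengths, mutable via NNI.

    Parameters
    ----------
    n_leaves:
        Number of leaves; leaf ids are ``0..n_leaves-1``.
    adj:
        Symmetric adjacency ``{node: {neighbor: branch_length}}``.
    """

    __slots__ = ("n", "adj")

    def __init__(self, n_leaves: int, adj: dict[int, dict[int, float]]):
        self.n = n_leaves
        self.adj = adj

    # ------------------------------------------------------------------ basic
    def copy(self) -> "TreeState":
        return TreeState(self.n, {u: dict(d) for u, d in self.adj.items()})

    def nodes(self):
        return list(self.adj)

    def is_leaf(self, u: int) -> bool:
        return u < self.n

    def edges(self):
        """All undirected edges as (u, v) with u < v."""
        return [(u, v) for u, d in self.adj.items() for v in d if u < v]

    def internal_edges(self):
        return [(u, v) for (u, v) in self.edges()
                if u >= self.n and v >= self.n]

    def length(self, u: int, v: int) -> float:
        return self.adj[u][v]

    def set_length(self, u: int, v: int, t: float) -> None:
        self.adj[u][v] = t
        self.adj[v][u] = t

    def total_length(self) -> float:
        return sum(t for _, d in self.adj.items() for t in d.values()) / 2.0

    # -------------------------------------------------------------- traversal
    def rooted_orders(self, root: int | None = None):
        """(postorder, parent) arrays for an arbitrary rooting.

        ``parent[root] == -1``.  Used to schedule message passing.
        """
        if root is None:
            root = max(self.adj)  # an internal node for n >= 3
        parent = {root: -1}
        order = [root]
        stack = [root]
        while stack:
            u = stack.pop()
            for v in self.adj[u]:
                if v != parent[u]:
                    parent[v] = u
                    order.append(v)
                    stack.append(v)
        # order is a preorder; postorder is its reverse
        return order[::-1], parent

    def leafset_behind(self, u: int, v: int) -> frozenset:
        """Leaves in the component containing ``u`` when edge (u,v) is cut."""
        seen = {v, u}
        stack = [u]
        out = []
        while stack:
            w = stack.pop()
            if self.is_leaf(w):
                out.append(w)
            for x in self.adj[w]:
                if x not in seen:
                    seen.add(x)
                    stack.append(x)
        return frozenset(out)

    def all_leafsets(self) -> dict[tuple[int, int], frozenset]:
        """Leafset behind every directed edge, computed in two sweeps."""
        post, parent = self.rooted_orders()
        ls: dict[tuple[int, int], frozenset] = {}
        for u in post:
            p = parent[u]
            if p == -1:
                continue
            if self.is_leaf(u):
                ls[(u, p)] = frozenset([u])
            else:
                kids = [v for v in self.adj[u] if v != p]
                ls[(u, p)] = frozenset().union(*(ls[(v, u)] for v in kids))
        all_leaves = frozenset(range(self.n))
        for (u, p), s in list(ls.items()):
            ls[(p, u)] = all_leaves - s
        return ls

    def splits(self) -> set[frozenset]:
        """Nontrivial splits, canonicalized to the side containing leaf 0."""
        out = set()
        ls = self.all_leafsets()
        for u, v in self.internal_edges():
            side = ls[(u, v)]
            if 0 not in side:
                side = frozenset(range(self.n)) - side
            out.add(side)
        return out

    # ------------------------------------------------------------------- NNI
    def nni_moves(self, u: int, v: int):
        """The two NNI rearrangements around internal edge (u, v).

        Returns two (x, y) pairs: exchange subtree x (attached at u) with
        subtree y (attached at v).
        """
        a, b = [w for w in self.adj[u] if w != v]
        c, d = [w for w in self.adj[v] if w != u]
        return [(b, c), (b, d)]

    def apply_nni(self, u: int, v: int, x: int, y: int) -> None:
        """Swap neighbor ``x`` of ``u`` with neighbor ``y`` of ``v``."""
        tx = self.adj[u].pop(x)
        ty = self.adj[v].pop(y)
        del self.adj[x][u]
        del self.adj[y][v]
        self.adj[u][y] = ty
        self.adj[y][u] = ty
        self.adj[v][x] = tx
        self.adj[x][v] = tx

    # ------------------------------------------------------------ conversion
    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree,
                      label_to_index: dict[str, int],
                      default_length: float = 0.05) -> "TreeState":
        """Convert, derooting a degree-2 seed node if present."""
        t = tree.clone(depth=1)
        if t.seed_node.num_child_nodes() == 2:
            t.deroot()
        n = len(label_to_index)
        adj: dict[int, dict[int, float]] = {}
        ids: dict[int, int] = {}
        next_internal = n

        def node_id(nd):
            nonlocal next_internal
            key = id(nd)
            if key not in ids:
                if nd.is_leaf():
                    label = nd.taxon.label if nd.taxon is not None else nd.label
                    ids[key] = label_to_index[label]
                else:
                    ids[key] = next_internal
                    next_internal += 1
            return ids[key]

        for nd in t.preorder_node_iter():
            u = node_id(nd)
            adj.setdefault(u, {})
            for ch in nd.child_nodes():
                w = node_id(ch)
                adj.setdefault(w, {})
                bl = ch.edge.length
                bl = default_length if bl is None else max(float(bl), 0.0)
                adj[u][w] = bl
                adj[w][u] = bl
        return cls(n, adj)

    def to_dendropy(self, labels: list[str],
                    taxon_namespace: dendropy.TaxonNamespace | None = None,
                    support: dict[frozenset, float] | None = None,
                    ) -> dendropy.Tree:
        """Emit an (unrooted) dendropy tree; optional per-split support labels."""
        if taxon_namespace is None:
            taxon_namespace = dendropy.TaxonNamespace(labels)
        tree = dendropy.Tree(taxon_namespace=taxon_namespace)
        tree.is_rooted = False
        ls = self.all_leafsets() if support is not None else {}
        root = max(self.adj)
        nodes = {root: tree.seed_node}
        stack = [(root, -1)]
        while stack:
            u, p = stack.pop()
            for v in self.adj[u]:
                if v == p:
                    continue
                ch = dendropy.Node()
                ch.edge.length = self.adj[u][v]
                if self.is_leaf(v):
                    ch.taxon = taxon_namespace.get_taxon(labels[v])
                    if ch.taxon is None:  # pragma: no cover - defensive
                        raise KeyError(f"taxon {labels[v]!r} not in namespace")
                elif support is not None:
                    side = ls[(v, u)]
                    if 0 not in side:
                        side = frozenset(range(self.n)) - side
                    if side in support:
                        ch.label = f"{support[side]:g}"
                nodes[u].add_child(ch)
                nodes[v] = ch
                stack.append((v, u))
        return tree

    # ------------------------------------------------------------ generators
    @classmethod
    def random_topology(cls, n: int, rng: np.random.Generator,
                        branch_length: float = 0.1) -> "TreeState":
        """Uniform random unrooted binary topology by sequential addition."""
        if n < 3:
            raise ValueError("need at least 3 leaves")
        adj: dict[int, dict[int, float]] = {}
        bl = branch_length

        def connect(a, b):
            adj.setdefault(a, {})[b] = bl
            adj.setdefault(b, {})[a] = bl

        center = n  # first internal node
        for leaf in (0, 1, 2):
            connect(leaf, center)
        next_internal = n + 1
        edges = [(0, center), (1, center), (2, center)]
        for leaf in range(3, n):
            u, v = edges[rng.integers(len(edges))]
            w = next_internal
            next_internal += 1
            del adj[u][v]
            del adj[v][u]
            connect(u, w)
            connect(v, w)
            connect(leaf, w)
            edges.remove((u, v))
            edges.extend([(u, w), (v, w), (leaf, w)])
        return cls(n, adj)

    @classmethod
    def enumerate_topologies(cls, n: int, branch_length: float = 0.1):
        """Yield every unrooted binary topology on ``n`` leaves.

        (2n-5)!! trees; intended for n <= 8 where that is 10,395.
        """
        if n < 3:
            raise ValueError("need at least 3 leaves")
        center = n
        adj: dict[int, dict[int, float]] = {center: {}}
        for leaf in (0, 1, 2):
            adj[center][leaf] = branch_length
            adj[leaf] = {center: branch_length}
        base = cls(n, adj)

        def grow(state: "TreeState", leaf: int, next_internal: int):
            if leaf == n:
                out = state.copy()
                out.n = n
                yield out
                return
            for (u, v) in list(state.edges()):
                s = state.copy()
                w = next_internal
                del s.adj[u][v]
                del s.adj[v][u]
                for a, b in ((u, w), (v, w), (leaf, w)):
                    s.adj.setdefault(a, {})[b] = branch_length
                    s.adj.setdefault(b, {})[a] = branch_length
                yield from grow(s, leaf + 1, next_internal + 1)

        if n == 3:
            yield base.copy()
            return
        # relabel base's internal node to n (it already is) and grow
        yield from grow(base, 3, n + 1)


def nj_topology(D: np.ndarray) -> TreeState:
    """Neighbor-joining TreeState from a distance matrix (via dendropy)."""
    import io

    n = D.shape[0]
    if n == 3:
        return TreeState.random_topology(3, np.random.default_rng(0))
    labels = [f"T{i}" for i in range(n)]
    buf = io.StringIO()
    buf.write("," + ",".join(labels) + "\n")
    for i, lab in enumerate(labels):
        buf.write(lab + "," + ",".join(f"{x:.10f}" for x in D[i]) + "\n")
    buf.seek(0)
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
        buf, delimiter=",", is_first_row_column_names=True,
        is_first_column_row_names=True)
    njt = pdm.nj_tree()
    ts = TreeState.from_dendropy(njt, {lab: i for i, lab in enumerate(labels)})
    for (u, v) in ts.edges():
        ts.set_length(u, v, max(ts.adj[u][v], 1e-4))
    return ts


def splits_compatible(a: frozenset, b: frozenset, universe: frozenset) -> bool:
    """Split compatibility on a shared taxon set (classic 4-intersection test)."""
    if not a & b:
        return True
    if a <= b or b <= a:
        return True
    return a | b == universe
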