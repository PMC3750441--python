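"""Tree building and comparison: neighbor-joining, exhaustive maximum parsimony
(Fitch small parsimony over all unrooted topologies), bootstrap supports and the
tree-similarity metrics used by the marker screen.

Trees are unrooted objects represented by their internal splits; outgroup
rooting is display-only. Exhaustive MP is feasible because intragenus panels
are small (4-9 strains, (2n-5)!! topologies); the per-topology Fitch count is
vectorized over unique column patterns, which also makes bootstrap resampling
cheap (pattern counts are computed once per topology, replicates only reweight
them).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from ._util import GAP, MISSING
from .align_dist import Alignment, DistanceMatrix

Nested = int | tuple  # rooted-at-leaf-0 binary topology over leaf indices 1..n-1

_BASE_MASK = {"A": 1, "C": 2, "G": 4, "T": 8}
_FULL = 15  # gap / N / anything ambiguous: compatible with all states at no cost


# ---------------------------------------------------------------------------
# tree object
# ---------------------------------------------------------------------------

class Node:
    __slots__ = ("name", "length", "children")

    def __init__(self, name: str | None = None, length: float = 0.0,
                 children: list["Node"] | None = None):
        self.name = name
        self.length = length
        self.children = children or []

    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class Tree:
    """Unrooted tree stored in an arbitrary rooted layout.

    All comparisons operate on the canonical split set, so the layout (and any
    display rooting) never affects topology semantics.
    """

    root: Node
    supports: dict[frozenset, float] = field(default_factory=dict)
    heuristic: bool = False

    # -- basic accessors ----------------------------------------------------
    def leaves(self) -> list[str]:
        out: list[str] = []

        def rec(n: Node) -> None:
            if n.is_leaf():
                out.append(n.name)
            for c in n.children:
                rec(c)

        rec(self.root)
        return sorted(out)

    def _leafset(self, n: Node) -> frozenset:
        if n.is_leaf():
            return frozenset([n.name])
        return frozenset().union(*(self._leafset(c) for c in n.children))

    def splits(self) -> frozenset:
        """Canonical internal splits: each as the side NOT containing min(leaf)."""
        all_leaves = frozenset(self.leaves())
        anchor = min(all_leaves)
        out = set()

        def rec(n: Node) -> frozenset:
            if n.is_leaf():
                return frozenset([n.name])
            below = frozenset().union(*(rec(c) for c in n.children))
            side = all_leaves - below if anchor in below else below
            if 2 <= len(side) <= len(all_leaves) - 2:
                out.add(side)
            return below

        rec(self.root)
        return frozenset(out)

    def branch_lengths(self) -> dict:
        """Map canonical split (internal edges) or leaf name (terminal) -> length."""
        all_leaves = frozenset(self.leaves())
        anchor = min(all_leaves)
        out: dict = {}

        def rec(n: Node) -> frozenset:
            if n.is_leaf():
                out[n.name] = n.length
                return frozenset([n.name])
            below = frozenset().union(*(rec(c) for c in n.children))
            side = all_leaves - below if anchor in below else below
            if 2 <= len(side) <= len(all_leaves) - 2:
                out[side] = out.get(side, 0.0) + n.length
            return below

        rec(self.root)
        return out

    # -- newick -------------------------------------------------------------
    def to_newick(self, outgroup: str | None = None) -> str:
        tree = self if outgroup is None else root_with_outgroup(self, outgroup)
        all_leaves = frozenset(tree.leaves())
        anchor = min(all_leaves)

        def rec(n: Node) -> str:
            if n.is_leaf():
                return f"{n.name}:{n.length:.6f}"
            inner = ",".join(rec(c) for c in n.children)
            below = tree._leafset(n)
            side = all_leaves - below if anchor in below else below
            sup = tree.supports.get(side)
            label = f"{sup:.0f}" if sup is not None else ""
            return f"({inner}){label}:{n.length:.6f}"

        inner = ",".join(rec(c) for c in tree.root.children)
        return f"({inner});"

    @classmethod
    def from_newick(cls, newick: str) -> "Tree":
        import dendropy

        dt = dendropy.Tree.get(data=newick, schema="newick")

        def rec(dn) -> Node:
            if dn.is_leaf():
                return Node(dn.taxon.label.replace(" ", "_"),
                            dn.edge.length or 0.0)
            n = Node(None, dn.edge.length or 0.0,
                     [rec(c) for c in dn.child_nodes()])
            return n

        root = Node(None, 0.0, [rec(c) for c in dt.seed_node.child_nodes()])
        tree = cls(root)
        # recover internal-node labels as supports where numeric
        supports: dict[frozenset, float] = {}
        all_leaves = frozenset(tree.leaves())
        anchor = min(all_leaves)
        for dn in dt.preorder_node_iter():
            if dn.is_leaf() or dn is dt.seed_node or dn.label is None:
                continue
            try:
                val = float(dn.label)
            except ValueError:
                continue
            below = frozenset(l.taxon.label.replace(" ", "_")
                              for l in dn.leaf_iter())
            side = all_leaves - below if anchor in below else below
            if 2 <= len(side) <= len(all_leaves) - 2:
                supports[side] = val
        tree.supports = supports
        return tree


def root_with_outgroup(tree: Tree, outgroup: str) -> Tree:
    """Display-only rerooting on the outgroup leaf's edge."""
    if outgroup not in tree.leaves():
        raise ValueError(f"outgroup {outgroup!r} not among leaves")
    # build undirected adjacency, then orient away from the outgroup edge
    nodes: list[Node] = []
    edges: dict[int, list[tuple[int, float]]] = {}
    names: dict[int, str | None] = {}

    def collect(n: Node) -> int:
        i = len(nodes)
        nodes.append(n)
        names[i] = n.name if n.is_leaf() else None
        edges.setdefault(i, [])
        for c in n.children:
            j = collect(c)
            edges[i].append((j, c.length))
            edges[j].append((i, c.length))
        return i

    collect(tree.root)
    og = next(i for i, nm in names.items() if nm == outgroup)
    (par, blen), = edges[og]

    def orient(i: int, prev: int, length: float) -> Node:
        kids = [orient(j, i, l) for j, l in edges[i] if j != prev]
        if not kids:
            return Node(names[i], length)
        if len(kids) == 1:  # collapse degree-2 pass-through (old rooting point)
            kids[0].length += length
            return kids[0]
        return Node(None, length, kids)

    new_root = Node(None, 0.0, [Node(outgroup, blen / 2.0),
                                orient(par, og, blen / 2.0)])
    return Tree(new_root, dict(tree.supports), tree.heuristic)


# ---------------------------------------------------------------------------
# neighbor-joining
# ---------------------------------------------------------------------------

def nj_tree(dm: DistanceMatrix, allow_two: bool = False) -> Tree:
    """Saitou-Nei neighbor joining with deterministic label-order tie-break.

    Negative branch lengths are clamped to zero with the deficit shifted to the
    sister edge (the pairwise path length through the new node is preserved).
    """
    labels = list(dm.labels)
    n = len(labels)
    if n < 3:
        if n == 2 and allow_two:
            half = dm.d[0, 1] / 2.0
            return Tree(Node(None, 0.0, [Node(labels[0], half), Node(labels[1], half)]))
        raise ValueError("nj_tree needs >=3 labels (pass allow_two=True for the degenerate pair)")

    nodes: list[Node] = [Node(l) for l in labels]
    keys: list[str] = list(labels)  # min leaf under each active node, for ties
    D = dm.d.astype(float).copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        r = {i: sum(D[i, j] for j in active if j != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * D[i, j] - r[i] - r[j]
                key = (q, *sorted((keys[i], keys[j])))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        ni, nj_ = nodes[i], nodes[j]
        ni.length, nj_.length = li, lj
        new = Node(None, 0.0, [ni, nj_])
        # distances to the new node
        newD = np.zeros(D.shape[0] + 1)
        for k in active:
            if k in (i, j):
                continue
            newD[k] = 0.5 * (D[i, k] + D[j, k] - D[i, j])
        D = np.vstack([np.hstack([D, newD[:-1, None]]), newD[None, :]])
        u = D.shape[0] - 1
        nodes.append(new)
        keys.append(min(keys[i], keys[j]))
        active = [k for k in active if k not in (i, j)] + [u]

    a, b, c = sorted(active, key=lambda k: keys[k])
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    for node, l in ((nodes[a], la), (nodes[b], lb), (nodes[c], lc)):
        node.length = max(l, 0.0)
    return Tree(Node(None, 0.0, [nodes[a], nodes[b], nodes[c]]))


def patristic_matrix(tree: Tree) -> DistanceMatrix:
    """Leaf-to-leaf path lengths (used for the NJ additivity fixed-point check)."""
    leaves = tree.leaves()
    idx = {l: i for i, l in enumerate(leaves)}
    n = len(leaves)
    d = np.zeros((n, n))

    def rec(node: Node) -> dict[str, float]:
        if node.is_leaf():
            return {node.name: 0.0}
        below: dict[str, float] = {}
        groups = []
        for c in rec_children(node):
            groups.append(c)
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                for la, da in groups[gi].items():
                    for lb, db in groups[gj].items():
                        d[idx[la], idx[lb]] = d[idx[lb], idx[la]] = da + db
        for g in groups:
            below.update(g)
        return below

    def rec_children(node: Node):
        for c in node.children:
            sub = rec(c)
            yield {l: dl + c.length for l, dl in sub.items()}

    rec(tree.root)
    return DistanceMatrix(leaves, d)


# ---------------------------------------------------------------------------
# parsimony
# ---------------------------------------------------------------------------

def _leaf_masks(aln: Alignment) -> np.ndarray:
    """(n_rows, L) uint8 state bitmasks; gap/N = all states (missing)."""
    arr = aln.matrix()
    masks = np.full(arr.shape, _FULL, dtype=np.uint8)
    for base, m in _BASE_MASK.items():
        masks[arr == base] = m
    return masks


def _unique_patterns(masks: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Collapse identical columns. Returns (patterns (n, P), weights, col->pattern)."""
    cols = masks.T.copy()
    pats, inverse, counts = np.unique(cols, axis=0, return_inverse=True, return_counts=True)
    return pats.T, counts.astype(float), inverse


def _fitch_pattern_counts(top: Nested, masks: np.ndarray) -> np.ndarray:
    """Fitch change counts per pattern for one rooted-at-leaf-0 topology."""

    def rec(node: Nested) -> tuple[np.ndarray, np.ndarray]:
        if isinstance(node, int):
            return masks[node], np.zeros(masks.shape[1], dtype=np.int64)
        (m1, c1), (m2, c2) = rec(node[0]), rec(node[1])
        inter = m1 & m2
        empty = inter == 0
        return np.where(empty, m1 | m2, inter), c1 + c2 + empty

    m, c = rec(top)
    return c + ((m & masks[0]) == 0)


def enumerate_topologies(n: int) -> list[Nested]:
    """All (2n-5)!! unrooted binary topologies over leaves 0..n-1,
    each encoded as a binary subtree over 1..n-1 hanging off leaf 0's edge."""
    if n < 3:
        raise ValueError("need >=3 leaves")

    def insert(t: Nested, k: int):
        yield (t, k)
        if isinstance(t, tuple):
            l, r = t
            for nl in insert(l, k):
                yield (nl, r)
            for nr in insert(r, k):
                yield (l, nr)

    tops: list[Nested] = [(1, 2)] if n >= 3 else []
    for k in range(3, n):
        tops = [nt for t in tops for nt in insert(t, k)]
    return tops


def _nested_leafsets(top: Nested, labels: Sequence[str]) -> list[frozenset]:
    """Internal splits (canonical sides) of a rooted-at-leaf-0 nested topology."""
    all_leaves = frozenset(labels)
    anchor = min(all_leaves)
    n = len(labels)
    out: list[frozenset] = []

    def rec(node: Nested) -> frozenset:
        if isinstance(node, int):
            return frozenset([labels[node]])
        below = rec(node[0]) | rec(node[1])
        if 2 <= len(below) <= n - 2:
            out.append(all_leaves - below if anchor in below else below)
        return below

    rec(top)
    return out


def nested_to_tree(top: Nested, labels: Sequence[str]) -> Tree:
    def rec(node: Nested) -> Node:
        if isinstance(node, int):
            return Node(labels[node], 1.0)
        return Node(None, 1.0, [rec(node[0]), rec(node[1])])

    root = Node(None, 0.0, [Node(labels[0], 1.0), rec(top)])
    return Tree(root)


def fitch_score(tree: Tree, aln: Alignment) -> int:
    """Total Fitch small-parsimony changes of the alignment on one tree.

    '-' and N are missing (union-compatible with anything at no cost). The
    score is invariant to the rooted layout.
    """
    leaves = tree.leaves()
    if not set(leaves) <= set(aln.order):
        raise ValueError("tree leaves not all present in alignment")
    sub = aln.subset(leaves) if set(leaves) != set(aln.order) else aln
    masks_rows = _leaf_masks(sub)
    pats, w, _ = _unique_patterns(masks_rows)
    row_of = {s: i for i, s in enumerate(sub.order)}

    def rec(node: Node) -> tuple[np.ndarray, np.ndarray]:
        if node.is_leaf():
            return pats[row_of[node.name]], np.zeros(pats.shape[1], dtype=np.int64)
        m, c = rec(node.children[0])
        for child in node.children[1:]:
            m2, c2 = rec(child)
            inter = m & m2
            empty = inter == 0
            m = np.where(empty, m | m2, inter)
            c = c + c2 + empty
        return m, c

    _, counts = rec(tree.root)
    return int(np.dot(counts, w))


@dataclass
class ParsimonyResult:
    best_score: int
    optimal_topologies: list[Tree]
    n_enumerated: int
    exhaustive: bool = True


class ExhaustiveMP:
    """Shared machinery for exhaustive MP search and MP bootstrap.

    Scores every unrooted topology against every unique column pattern once;
    searches and bootstrap replicates are then weighted argmins over that
    matrix.
    """

    def __init__(self, aln: Alignment):
        self.aln = aln
        self.labels = list(aln.order)
        n = len(self.labels)
        if n < 4:
            raise ValueError("exhaustive MP needs >=4 leaves")
        if n > 9:
            raise ValueError("exhaustive MP limited to 9 leaves; use mp_search heuristic path")
        masks = _leaf_masks(aln)
        self.patterns, self.weights, self.col_to_pattern = _unique_patterns(masks)
        self.topologies = enumerate_topologies(n)
        self.counts = np.stack(
            [_fitch_pattern_counts(t, self.patterns) for t in self.topologies]
        )  # (T, P)
        self._splits_cache: list[list[frozenset]] | None = None

    @property
    def topology_splits(self) -> list[list[frozenset]]:
        if self._splits_cache is None:
            self._splits_cache = [_nested_leafsets(t, self.labels) for t in self.topologies]
        return self._splits_cache

    def scores(self, weights: np.ndarray | None = None) -> np.ndarray:
        w = self.weights if weights is None else weights
        return self.counts @ w

    def best(self, weights: np.ndarray | None = None) -> tuple[float, list[int]]:
        s = self.scores(weights)
        mn = s.min()
        return float(mn), [int(i) for i in np.flatnonzero(s == mn)]

    def bootstrap_weights(self, rng: np.random.Generator) -> np.ndarray:
        L = len(self.col_to_pattern)
        cols = rng.integers(0, L, size=L)
        return np.bincount(self.col_to_pattern[cols],
                           minlength=self.patterns.shape[1]).astype(float)


def mp_search(aln: Alignment, max_exhaustive: int = 9) -> ParsimonyResult:
    """Maximum parsimony: exhaustive enumeration for 4-9 leaves, NNI hill climb
    from the NJ tree beyond (flagged heuristic)."""
    n = len(aln.order)
    if n < 4:
        raise ValueError("mp_search needs >=4 leaves")
    if n <= max_exhaustive:
        mp = ExhaustiveMP(aln)
        score, idxs = mp.best()
        trees = [nested_to_tree(mp.topologies[i], mp.labels) for i in idxs]
        return ParsimonyResult(int(round(score)), trees, len(mp.topologies), exhaustive=True)
    return _mp_nni(aln)


def _nni_neighbors(top: Nested) -> list[Nested]:
    out: list[Nested] = []

    def variants(node: Nested) -> list[Nested]:
        if isinstance(node, int):
            return []
        l, r = node
        here: list[Nested] = []
        if isinstance(l, tuple):
            a, b = l
            here += [((a, r), b), ((b, r), a)]
        if isinstance(r, tuple):
            a, b = r
            here += [(b, (a, l)), (a, (b, l))]
        here += [(vl, r) for vl in variants(l)]
        here += [(l, vr) for vr in variants(r)]
        return here

    out.extend(variants(top))
    return out


def _mp_nni(aln: Alignment) -> ParsimonyResult:
    from .align_dist import p_distance

    labels = list(aln.order)
    nj = nj_tree(p_distance(aln))
    top = _tree_to_nested(nj, labels)
    masks = _leaf_masks(aln)
    pats, w, _ = _unique_patterns(masks)

    def score(t: Nested) -> float:
        return float(np.dot(_fitch_pattern_counts(t, pats), w))

    cur, cur_s = top, score(top)
    n_eval = 1
    improved = True
    while improved:
        improved = False
        for nb in _nni_neighbors(cur):
            n_eval += 1
            s = score(nb)
            if s < cur_s:
                cur, cur_s = nb, s
                improved = True
                break
    return ParsimonyResult(int(round(cur_s)), [nested_to_tree(cur, labels)],
                           n_eval, exhaustive=False)


def _tree_to_nested(tree: Tree, labels: Sequence[str]) -> Nested:
    """Re-encode an unrooted binary tree as a nested tuple hung off labels[0]."""
    idx = {l: i for i, l in enumerate(labels)}
    nodes: list[Node] = []
    edges: dict[int, list[int]] = {}
    names: dict[int, str | None] = {}

    def collect(n: Node) -> int:
        i = len(nodes)
        nodes.append(n)
        names[i] = n.name if n.is_leaf() else None
        edges.setdefault(i, [])
        for c in n.children:
            j = collect(c)
            edges[i].append(j)
            edges[j].append(i)
        return i

    collect(tree.root)
    # drop degree-2 pass-through nodes (rooted layout artifacts)
    for i, nbrs in list(edges.items()):
        if names[i] is None and len(nbrs) == 2:
            a, b = nbrs
            edges[a] = [x if x != i else b for x in edges[a]]
            edges[b] = [x if x != i else a for x in edges[b]]
            edges[i] = []
    start = next(i for i, nm in names.items() if nm == labels[0])

    def build(i: int, prev: int) -> Nested:
        kids = [j for j in edges[i] if j != prev]
        if not kids:
            return idx[names[i]]
        if len(kids) != 2:
            raise ValueError("tree is not binary (after unrooting)")
        return (build(kids[0], i), build(kids[1], i))

    (anchor_nbr,) = edges[start]
    return build(anchor_nbr, start)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def bootstrap_support(
    aln: Alignment,
    builder: Callable[[Alignment], Tree],
    B: int = 100,
    seed: int = 0,
) -> Tree:
    """Column-resampling bootstrap: supports = % of replicate trees containing
    each split of the tree built on the original alignment."""
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    base = builder(aln)
    target = base.splits()
    hits = {s: 0 for s in target}
    L = aln.length
    for _ in range(B):
        cols = rng.integers(0, L, size=L)
        rows = ["".join(r[c] for c in cols) for r in aln.rows]
        rep = Alignment(aln.region_id, list(aln.order), rows, aln.frame)
        rep_splits = builder(rep).splits()
        for s in target:
            if s in rep_splits:
                hits[s] += 1
    base.supports = {s: 100.0 * h / B for s, h in hits.items()}
    return base


def mp_bootstrap(aln: Alignment, B: int = 100, seed: int = 0,
                 mp: ExhaustiveMP | None = None) -> tuple[Tree, dict]:
    """Exhaustive-MP bootstrap via pattern reweighting. Returns the MP tree on
    the original data (first optimum in enumeration order) with supports for
    its internal splits."""
    if B < 1:
        raise ValueError("B must be >= 1")
    mp = mp or ExhaustiveMP(aln)
    rng = np.random.default_rng(seed)
    _, idxs = mp.best()
    best_idx = idxs[0]
    target = mp.topology_splits[best_idx]
    hits = {s: 0 for s in target}
    for _ in range(B):
        w = mp.bootstrap_weights(rng)
        s = mp.scores(w)
        rep_idx = int(np.argmin(s))
        rep_splits = set(mp.topology_splits[rep_idx])
        for sp in target:
            if sp in rep_splits:
                hits[sp] += 1
    tree = nested_to_tree(mp.topologies[best_idx], mp.labels)
    tree.supports = {s: 100.0 * h / B for s, h in hits.items()}
    return tree, tree.supports


# ---------------------------------------------------------------------------
# tree / matrix comparison
# ---------------------------------------------------------------------------

def rf_distance(t1: Tree, t2: Tree) -> int:
    """Robinson-Foulds: size of the symmetric difference of internal split sets."""
    l1, l2 = set(t1.leaves()), set(t2.leaves())
    if l1 != l2:
        raise ValueError(f"leaf sets differ: {sorted(l1 ^ l2)}")
    return len(t1.splits() ^ t2.splits())


def matrix_euclidean(m1: DistanceMatrix, m2: DistanceMatrix,
                     normalized: bool = False) -> float:
    """sqrt of the sum over unordered label pairs of squared entry differences;
    optionally divided by the pair count before the sqrt."""
    if set(m1.labels) != set(m2.labels):
        raise ValueError(f"label sets differ: {sorted(set(m1.labels) ^ set(m2.labels))}")
    order = sorted(m1.labels)
    a = m1.subset(order).d
    b = m2.subset(order).d
    iu = np.triu_indices(len(order), 1)
    ss = float(((a - b) ** 2)[iu].sum())
    if normalized:
        ss /= len(iu[0])
    return float(np.sqrt(ss))
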