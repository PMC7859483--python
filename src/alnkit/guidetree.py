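"""Guide-tree construction: UPGMA and neighbor joining, plus Newick I/O.

Both clustering algorithms consume a :class:`~alnkit.distance.DistanceMatrix`
and produce a rooted, strictly bifurcating :class:`GuideTree` with
non-negative branch lengths, suitable for driving progressive alignment.

UPGMA is true size-weighted average linkage and yields ultrametric trees.
Neighbor joining (Saitou–Nei) is exact on additive matrices; its unrooted
result is midpoint-rooted for guide-tree use, and any negative branch
length is clamped to zero with the deficit moved onto the sibling edge so
that leaf-to-leaf path lengths are preserved.

Ties in the merge criterion are broken by the lexicographically smallest
(row, column) index pair in current matrix order, making both algorithms
deterministic.
"""

from __future__ import annotations

import io
import itertools
from dataclasses import dataclass, field

import numpy as np
from skbio import TreeNode as _SkbioTree

from .distance import DistanceMatrix

__all__ = [
    "TreeNode",
    "GuideTree",
    "upgma",
    "neighbor_joining",
    "to_newick",
    "from_newick",
    "robinson_foulds",
]


@dataclass
class TreeNode:
    """Node of a rooted guide tree: leaf (with a name) or binary internal."""

    name: str | None = None
    length: float = 0.0  # branch length of the edge above this node
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self):
        for child in self.children:
            yield from child.postorder()
        yield self

    def leaves(self) -> list["TreeNode"]:
        return [n for n in self.postorder() if n.is_leaf]


class GuideTree:
    """Rooted binary tree over sequence ids, with branch lengths ≥ 0."""

    def __init__(self, root: TreeNode):
        self.root = root
        for node in root.postorder():
            if not node.is_leaf and len(node.children) != 2:
                raise ValueError("guide tree must be strictly bifurcating")
            if node.is_leaf and not node.name:
                raise ValueError("every leaf must be labelled")
            if node.length < 0:
                raise ValueError("branch lengths must be non-negative")
        names = self.leaf_names()
        if len(set(names)) != len(names):
            raise ValueError("duplicate leaf labels")

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.root.leaves()]

    def leaf_depths(self) -> dict[str, float]:
        """Leaf-to-root path lengths (sums of branch lengths)."""
        depths: dict[str, float] = {}

        def walk(node: TreeNode, acc: float) -> None:
            acc += node.length
            if node.is_leaf:
                depths[node.name] = acc
            for c in node.children:
                walk(c, acc)

        walk(self.root, -self.root.length)  # root's own length not counted
        return depths

    def path_distances(self) -> dict[frozenset[str], float]:
        """All leaf-to-leaf path lengths, keyed by unordered label pair."""
        dists: dict[frozenset[str], float] = {}

        def walk(node: TreeNode) -> dict[str, float]:
            if node.is_leaf:
                return {node.name: 0.0}
            sides = []
            for c in walk_children(node):
                sides.append({k: v + c.length for k, v in walk(c).items()})
            for left, right in itertools.combinations(sides, 2):
                for a, da in left.items():
                    for b, db in right.items():
                        dists[frozenset((a, b))] = da + db
            merged: dict[str, float] = {}
            for s in sides:
                merged.update(s)
            return merged

        def walk_children(node: TreeNode):
            return node.children

        walk(self.root)
        return dists

    def height(self) -> float:
        return max(self.leaf_depths().values())

    def __str__(self) -> str:
        return to_newick(self)


# ---------------------------------------------------------------------------
# UPGMA


def upgma(d: DistanceMatrix) -> GuideTree:
    """Size-weighted average-linkage clustering into an ultrametric tree.

    The closest pair of clusters merges at height d/2; the merged cluster's
    distance to any other is the member-count-weighted mean of its parts'
    distances.  All leaf-to-root path sums of the result are equal.
    """
    if len(d) < 2:
        raise ValueError("need at least 2 labels")
    nodes = [TreeNode(name=lab) for lab in d.labels]
    heights = [0.0] * len(nodes)
    sizes = [1] * len(nodes)
    mat = d.values.copy()

    while len(nodes) > 1:
        n = len(nodes)
        bi, bj, best = 0, 1, np.inf
        for i in range(n):
            for j in range(i + 1, n):
                if mat[i, j] < best:  # strict < keeps first (lexicographic) pair
                    bi, bj, best = i, j, mat[i, j]
        h = best / 2.0
        left, right = nodes[bi], nodes[bj]
        left.length = h - heights[bi]
        right.length = h - heights[bj]
        parent = TreeNode(children=[left, right])

        # Size-weighted distances from the merged cluster to the rest.
        wi, wj = sizes[bi], sizes[bj]
        new_row = (wi * mat[bi] + wj * mat[bj]) / (wi + wj)
        keep = [k for k in range(n) if k not in (bi, bj)]
        new_mat = np.zeros((len(keep) + 1, len(keep) + 1))
        new_mat[:-1, :-1] = mat[np.ix_(keep, keep)]
        new_mat[-1, :-1] = new_mat[:-1, -1] = new_row[keep]
        mat = new_mat
        nodes = [nodes[k] for k in keep] + [parent]
        heights = [heights[k] for k in keep] + [h]
        sizes = [sizes[k] for k in keep] + [wi + wj]
    return GuideTree(nodes[0])


# ---------------------------------------------------------------------------
# Neighbor joining


def neighbor_joining(d: DistanceMatrix) -> GuideTree:
    """Saitou–Nei neighbor joining, midpoint-rooted.

    Repeatedly joins the pair minimizing
    Q(i,j) = (n−2)·d(i,j) − Σₖd(i,k) − Σₖd(j,k), with the standard limb
    lengths.  Exact on additive matrices.  A two-label matrix returns the
    trivial cherry splitting the distance equally.
    """
    if len(d) < 2:
        raise ValueError("need at least 2 labels")
    if len(d) == 2:
        half = d.values[0, 1] / 2.0
        return GuideTree(
            TreeNode(children=[
                TreeNode(name=d.labels[0], length=half),
                TreeNode(name=d.labels[1], length=half),
            ])
        )

    # Grow an unrooted tree as an adjacency map over node objects.
    adj: dict[int, list[tuple[int, float]]] = {}
    node_name: dict[int, str] = {}
    next_id = 0

    def new_node(name: str | None = None) -> int:
        nonlocal next_id
        nid = next_id
        next_id += 1
        adj[nid] = []
        if name is not None:
            node_name[nid] = name
        return nid

    def connect(u: int, v: int, length: float) -> None:
        length = max(0.0, length)
        adj[u].append((v, length))
        adj[v].append((u, length))

    active = [new_node(lab) for lab in d.labels]
    mat = d.values.copy()

    while len(active) > 3:
        n = len(active)
        row_sums = mat.sum(axis=1)
        bi, bj, best = 0, 1, np.inf
        for i in range(n):
            for j in range(i + 1, n):
                q = (n - 2) * mat[i, j] - row_sums[i] - row_sums[j]
                if q < best - 1e-12:
                    bi, bj, best = i, j, q
        dij = mat[bi, bj]
        limb_i = 0.5 * dij + (row_sums[bi] - row_sums[bj]) / (2 * (n - 2))
        limb_j = dij - limb_i
        # Clamp a negative limb to zero, moving the deficit to the sibling
        # so the leaf-to-leaf path through the new node keeps length d(i,j).
        if limb_i < 0:
            limb_i, limb_j = 0.0, dij
        elif limb_j < 0:
            limb_i, limb_j = dij, 0.0
        parent = new_node()
        connect(active[bi], parent, limb_i)
        connect(active[bj], parent, limb_j)

        keep = [k for k in range(n) if k not in (bi, bj)]
        new_row = np.maximum(
            0.0, 0.5 * (mat[bi] + mat[bj] - dij)
        )
        new_mat = np.zeros((len(keep) + 1, len(keep) + 1))
        new_mat[:-1, :-1] = mat[np.ix_(keep, keep)]
        new_mat[-1, :-1] = new_mat[:-1, -1] = new_row[keep]
        mat = new_mat
        active = [active[k] for k in keep] + [parent]

    # Final three-way join: a central node with limb lengths from the
    # three-point formulas, clamped at zero.
    x, y, z = active
    dxy, dxz, dyz = mat[0, 1], mat[0, 2], mat[1, 2]
    center = new_node()
    connect(x, center, max(0.0, (dxy + dxz - dyz) / 2))
    connect(y, center, max(0.0, (dxy + dyz - dxz) / 2))
    connect(z, center, max(0.0, (dxz + dyz - dxy) / 2))

    return _midpoint_root(adj, node_name)


def _midpoint_root(
    adj: dict[int, list[tuple[int, float]]], node_name: dict[int, str]
) -> GuideTree:
    """Root an unrooted tree at the midpoint of its longest leaf-leaf path."""
    leaves = sorted(node_name, key=lambda nid: node_name[nid])

    def paths_from(src: int) -> tuple[dict[int, float], dict[int, int]]:
        dist = {src: 0.0}
        prev: dict[int, int] = {}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + w
                    prev[v] = u
                    stack.append(v)
        return dist, prev

    # Longest leaf-to-leaf path; ties broken by leaf-name order for
    # determinism.
    best = (-1.0, None, None, None)
    for u in leaves:
        dist, prev = paths_from(u)
        for v in leaves:
            if v == u:
                continue
            if dist[v] > best[0] + 1e-12:
                best = (dist[v], u, v, prev)
    diameter, u, v, prev = best
    # Reconstruct the u→v path.
    path = [v]
    while path[-1] != u:
        path.append(prev[path[-1]])
    path.reverse()

    def edge_len(a: int, b: int) -> float:
        return next(w for nbr, w in adj[a] if nbr == b)

    # Locate the edge containing the midpoint and split it there.
    target = diameter / 2.0
    acc = 0.0
    for a, b in zip(path, path[1:]):
        w = edge_len(a, b)
        if acc + w >= target - 1e-12:
            offset = min(max(target - acc, 0.0), w)
            return _build_rooted(adj, node_name, a, b, offset, w)
        acc += w
    # Degenerate all-zero-length tree: root on the first edge.
    a, b = path[0], path[1]
    return _build_rooted(adj, node_name, a, b, 0.0, edge_len(a, b))


def _build_rooted(
    adj: dict[int, list[tuple[int, float]]],
    node_name: dict[int, str],
    a: int,
    b: int,
    offset: float,
    edge_length: float,
) -> GuideTree:
    """Create a rooted binary tree with the root splitting edge (a, b)."""

    def subtree(node: int, parent: int, length: float) -> TreeNode:
        kids = [
            subtree(v, node, w) for v, w in adj[node] if v != parent
        ]
        return TreeNode(
            name=node_name.get(node), length=length, children=kids
        )

    left = subtree(a, b, offset)
    right = subtree(b, a, edge_length - offset)
    return GuideTree(TreeNode(children=[left, right]))


# ---------------------------------------------------------------------------
# Newick I/O


def to_newick(t: GuideTree) -> str:
    """Serialize with branch lengths formatted to six decimals."""

    def render(node: TreeNode) -> str:
        if node.is_leaf:
            body = node.name
        else:
            body = "(" + ",".join(render(c) for c in node.children) + ")"
        return f"{body}:{node.length:.6f}"

    root = t.root
    inner = "(" + ",".join(render(c) for c in root.children) + ")"
    return inner + ";"


def from_newick(text: str, expected_labels: list[str] | None = None) -> GuideTree:
    """Parse a bifurcating Newick string with mandatory branch lengths.

    Raises on multifurcations, missing branch lengths, or (when
    ``expected_labels`` is given) a leaf-label set that differs from the
    expectation.
    """
    sk = _SkbioTree.read(io.StringIO(text.strip()), format="newick")

    def convert(node) -> TreeNode:
        kids = list(node.children)
        if kids and len(kids) != 2:
            raise ValueError(
                f"multifurcation ({len(kids)} children) is not supported"
            )
        if node.parent is not None and node.length is None:
            raise ValueError("branch lengths required")
        length = float(node.length) if node.length is not None else 0.0
        if length < 0:
            raise ValueError("branch lengths must be non-negative")
        name = str(node.name) if node.is_tip() else None
        return TreeNode(name=name, length=length,
                        children=[convert(c) for c in kids])

    root = convert(sk)
    root.length = 0.0
    tree = GuideTree(root)
    if expected_labels is not None:
        have, want = set(tree.leaf_names()), set(expected_labels)
        if have != want:
            missing = sorted(want - have)
            extra = sorted(have - want)
            raise ValueError(
                f"leaf labels differ from expectation: missing {missing}, "
                f"unexpected {extra}"
            )
    return tree


def robinson_foulds(a: GuideTree, b: GuideTree) -> int:
    """Unrooted Robinson–Foulds distance (symmetric bipartition difference).

    Counts non-trivial splits present in exactly one of the two trees; both
    trees must share one leaf-label set.
    """
    if set(a.leaf_names()) != set(b.leaf_names()):
        raise ValueError("trees must share the same leaf set")
    taxa = frozenset(a.leaf_names())

    def splits(t: GuideTree) -> set[frozenset[str]]:
        out: set[frozenset[str]] = set()

        def walk(node: TreeNode) -> frozenset[str]:
            if node.is_leaf:
                return frozenset([node.name])
            below = frozenset().union(*(walk(c) for c in node.children))
            if 1 < len(below) < len(taxa) - 1:
                # store the smaller side canonically
                other = taxa - below
                out.add(min(below, other, key=sorted))
            return below

        walk(t.root)
        return out

    sa, sb = splits(a), splits(b)
    return len(sa ^ sb)
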