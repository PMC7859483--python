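"""Synthetic sequence-family generator with recorded homology.

Evolves a random root sequence down a (random or supplied) guide tree with
per-site substitutions and geometric-length indels, tracking every site's
identity so the *true* multiple alignment of the leaves is known exactly.
This gives the test-suite ground truth for tree-recovery and alignment
invariants without any external data.

The model is intentionally transparent rather than realistic: at most one
substitution event per site per edge (probability ``min(1, rate × branch
length)``, changing the residue to a uniformly chosen different one), and
indel events thinned per site at the indel rate, equally likely insertion
or deletion, with geometric run lengths.  All randomness flows from a
single seeded generator; there is no global random state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .guidetree import GuideTree, TreeNode
from .seqio import GAP, Alphabet, DNA, MultipleAlignment, Sequence, SequenceSet

__all__ = [
    "EvolutionParams",
    "random_tree",
    "evolve",
    "TOPOLOGY_RECOVERY_MIN",
]

# Minimum fraction of substitution-only replicates in which distance + NJ
# must recover the generating topology (Robinson–Foulds distance zero).
# A conservative bound used by the recovery tests.
TOPOLOGY_RECOVERY_MIN = 0.90

_BRANCH_RANGE = (0.05, 0.5)


@dataclass(frozen=True)
class EvolutionParams:
    """Rates and sizes for one simulated family.

    ``substitution_rate`` and ``indel_rate`` are per site per unit branch
    length, both in [0, 1]; ``mean_indel_length`` is the mean of the
    geometric run-length distribution.  The default root length of 500
    sites is a typical gene-fragment scale and leaves enough per-edge
    signal for distance-based tree recovery at low rates.
    """

    root_length: int = 500
    substitution_rate: float = 0.05
    indel_rate: float = 0.0
    mean_indel_length: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.root_length < 1:
            raise ValueError("root_length must be >= 1")
        for r in (self.substitution_rate, self.indel_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.mean_indel_length < 1.0:
            raise ValueError("mean_indel_length must be >= 1")


def random_tree(n_leaves: int, seed: int) -> GuideTree:
    """Random bifurcating tree via sequential random joins.

    Leaf ids are ``t1 … tn``; every branch length is drawn uniformly from
    [0.05, 0.5].  Deterministic for a given seed.
    """
    if n_leaves < 2:
        raise ValueError("need at least 2 leaves")
    rng = np.random.default_rng(seed)
    lo, hi = _BRANCH_RANGE
    nodes = [TreeNode(name=f"t{i + 1}") for i in range(n_leaves)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        a.length = float(rng.uniform(lo, hi))
        b.length = float(rng.uniform(lo, hi))
        parent = TreeNode(children=[a, b])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append(parent)
    return GuideTree(nodes[0])


def evolve(
    tree: GuideTree, params: EvolutionParams, alphabet: Alphabet = DNA
) -> tuple[SequenceSet, MultipleAlignment]:
    """Evolve a root sequence down the tree; return leaves + true alignment.

    Sequences are lists of site tokens with persistent identities: a
    substitution changes a token's residue, a deletion drops tokens, an
    insertion mints fresh tokens.  The global token order defines the true
    alignment columns; columns surviving in no leaf are dropped, so the
    returned alignment has no all-gap column and each row degaps to its
    leaf sequence exactly.
    """
    rng = np.random.default_rng(params.seed)
    # Simulated residues exclude the wildcard (unknown-residue) symbol.
    core = [s for s in alphabet.symbols if s != alphabet.wildcard]

    next_site = params.root_length
    order: list[int] = list(range(params.root_length))
    root_seq: list[tuple[int, str]] = [
        (i, core[int(rng.integers(len(core)))])
        for i in range(params.root_length)
    ]

    def mutate(parent_seq, branch_length):
        nonlocal next_site
        p_sub = min(1.0, params.substitution_rate * branch_length)
        p_ind = min(1.0, params.indel_rate * branch_length)
        geo_p = 1.0 / params.mean_indel_length
        child: list[tuple[int, str]] = []
        i = 0
        while i < len(parent_seq):
            sid, res = parent_seq[i]
            if p_sub and rng.random() < p_sub:
                choices = [c for c in core if c != res]
                res = choices[int(rng.integers(len(choices)))]
            child.append((sid, res))
            if p_ind and rng.random() < p_ind:
                run = int(rng.geometric(geo_p))
                if rng.random() < 0.5:
                    # Insert fresh tokens right after this site, both in the
                    # child sequence and in the global column order.
                    at = order.index(sid) + 1
                    for k in range(run):
                        token = next_site
                        next_site += 1
                        child.append(
                            (token, core[int(rng.integers(len(core)))])
                        )
                        order.insert(at + k, token)
                else:
                    # Delete the run following this site (the anchor always
                    # survives, so sequences can never become empty).
                    i += run
            i += 1
        return child

    leaf_seqs: dict[str, list[tuple[int, str]]] = {}

    def walk(node: TreeNode, seq) -> None:
        if node.is_leaf:
            leaf_seqs[node.name] = seq
            return
        for child in node.children:
            walk(child, mutate(seq, child.length))

    walk(tree.root, root_seq)

    leaf_order = [n.name for n in tree.root.leaves()]
    present: set[int] = set()
    for seq in leaf_seqs.values():
        present.update(sid for sid, _ in seq)
    columns = [sid for sid in order if sid in present]
    col_index = {sid: c for c, sid in enumerate(columns)}

    rows: list[tuple[str, str]] = []
    members: list[Sequence] = []
    for name in leaf_order:
        row = [GAP] * len(columns)
        chars = []
        for sid, res in leaf_seqs[name]:
            row[col_index[sid]] = res
            chars.append(res)
        rows.append((name, "".join(row)))
        members.append(Sequence(name, "".join(chars)))

    return SequenceSet(alphabet, members), MultipleAlignment(rows, alphabet)
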