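"""Tree-guided progressive alignment with profile-profile merging.

Implements the classic "once a gap, always a gap" strategy: each guide-tree
leaf starts as a one-row profile, and every internal node aligns its two
child profiles with a global DP over profile columns.  Inserting a gap into
a profile inserts an all-gap column into every row of that profile; existing
gaps are never removed, so each child profile remains recoverable from any
merged profile.

Column-pair scoring is the unweighted mean of substitution scores over all
residue/residue cross-pairs between the two columns (gap pairings excluded
from the mean); the gap model is charged per inserted column, per run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .guidetree import GuideTree, TreeNode
from .pairwise import ScoringScheme, align_generic, scheme_symbol_matrix
from .seqio import GAP, Alphabet, MultipleAlignment, SequenceSet

__all__ = [
    "Profile",
    "profile_profile_align",
    "progressive_align",
    "run_msa_pipeline",
]


@dataclass
class Profile:
    """A set of mutually aligned gapped rows treated as a unit."""

    rows: list[tuple[str, str]]
    alphabet: Alphabet

    def __post_init__(self) -> None:
        lengths = {len(text) for _, text in self.rows}
        if len(lengths) > 1:
            raise ValueError("profile rows must have equal length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.rows]

    def residue_counts(self, alphabet_index: dict[str, int]) -> np.ndarray:
        """Per-column residue count vectors, shape (columns, |alphabet|)."""
        counts = np.zeros((self.n_columns, len(alphabet_index)))
        for _, text in self.rows:
            for c, ch in enumerate(text):
                if ch != GAP:
                    counts[c, alphabet_index[ch]] += 1
        return counts


def profile_profile_align(
    p: Profile, q: Profile, scheme: ScoringScheme
) -> Profile:
    """Globally align two profiles column-against-column.

    The score of pairing a column of ``p`` with a column of ``q`` is the
    mean substitution score over all residue/residue combinations between
    them (a pairing with no residue/residue combination scores 0); inserted
    gap columns are charged through the gap model per run of columns.
    """
    if set(p.ids) & set(q.ids):
        raise ValueError(
            f"profiles share ids: {sorted(set(p.ids) & set(q.ids))}"
        )
    if p.alphabet != q.alphabet:
        raise ValueError("profiles must share one alphabet")
    index, S = scheme_symbol_matrix(scheme)
    cp = p.residue_counts(index)
    cq = q.residue_counts(index)
    # pair_scores[i, j]: total cross-pair substitution score of column i of p
    # against column j of q, divided by the number of residue/residue pairs.
    totals = cp @ S @ cq.T
    npairs = np.outer(cp.sum(axis=1), cq.sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        pair_scores = np.where(npairs > 0, totals / np.maximum(npairs, 1), 0.0)

    _, moves = align_generic(pair_scores, scheme.gaps)

    new_p = ["" for _ in p.rows]
    new_q = ["" for _ in q.rows]
    i = j = 0
    for mv in moves:
        take_p = mv in ("D", "U")
        take_q = mv in ("D", "L")
        for r, (_, text) in enumerate(p.rows):
            new_p[r] += text[i] if take_p else GAP
        for r, (_, text) in enumerate(q.rows):
            new_q[r] += text[j] if take_q else GAP
        i += take_p
        j += take_q
    rows = [(rid, new_p[r]) for r, (rid, _) in enumerate(p.rows)]
    rows += [(rid, new_q[r]) for r, (rid, _) in enumerate(q.rows)]
    return Profile(rows, p.alphabet)


def _subtree_height(node: TreeNode) -> float:
    if node.is_leaf:
        return 0.0
    return max(c.length + _subtree_height(c) for c in node.children)


def _smallest_leaf(node: TreeNode) -> str:
    return min(leaf.name for leaf in node.leaves())


def progressive_align(
    seqs: SequenceSet, tree: GuideTree, scheme: ScoringScheme
) -> MultipleAlignment:
    """Merge sequences up the guide tree into one multiple alignment.

    Post-order traversal: leaves become one-row profiles; each internal
    node merges its children's profiles with
    :func:`profile_profile_align`, visiting the child of smaller subtree
    height first (ties by smallest leaf id) so that closely related
    sequences align before distant ones.  Rows of the result are reported
    in input order.
    """
    tree_labels = set(tree.leaf_names())
    seq_labels = set(seqs.ids)
    if tree_labels != seq_labels:
        raise ValueError(
            "guide tree labels do not match sequences: missing "
            f"{sorted(seq_labels - tree_labels)}, unexpected "
            f"{sorted(tree_labels - seq_labels)}"
        )

    def build(node: TreeNode) -> Profile:
        if node.is_leaf:
            return Profile([(node.name, seqs[node.name].residues)],
                           seqs.alphabet)
        kids = sorted(
            node.children,
            key=lambda c: (_subtree_height(c), _smallest_leaf(c)),
        )
        profile = build(kids[0])
        for other in kids[1:]:
            profile = profile_profile_align(profile, build(other), scheme)
        return profile

    root = build(tree.root)
    by_id = dict(root.rows)
    rows = [(sid, by_id[sid]) for sid in seqs.ids]
    return MultipleAlignment(rows, seqs.alphabet)


def run_msa_pipeline(
    seqs: SequenceSet,
    scheme: ScoringScheme,
    aligner,
    distance_builder,
    clustering,
    objective,
    guide_tree: GuideTree | None = None,
):
    """Execute the three classic stages with injected components.

    1. all-pairs alignment (``aligner``) feeding ``distance_builder``;
    2. guide-tree construction (``clustering``);
    3. progressive alignment, then ``objective`` scoring of the result.

    A precomputed ``guide_tree`` bypasses stages 1–2.  Returns
    ``(alignment, objective_result, tree)``.
    """
    if guide_tree is None:
        matrix = distance_builder(seqs, aligner, scheme)
        guide_tree = clustering(matrix)
    msa = progressive_align(seqs, guide_tree, scheme)
    return msa, objective(msa, scheme), guide_tree
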