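"""Independent oracles used by the test suite.

Everything here is deliberately brute-force and shares no code with the
implementation paths it checks: alignment optima come from exhaustive
enumeration, and combination validity from a direct reading of the
constraint semantics.
"""

from __future__ import annotations

from typing import Iterable, Iterator

import numpy as np

from alnkit.distance import DistanceMatrix
from alnkit.pairwise import ScoringScheme, rescore_pair


def enumerate_global_alignments(a: str, b: str) -> Iterator[tuple[str, str]]:
    """Yield every global alignment of two strings (no gap/gap columns)."""
    if not a and not b:
        yield "", ""
        return
    if a:
        for ra, rb in enumerate_global_alignments(a[1:], b):
            yield a[0] + ra, "-" + rb
    if b:
        for ra, rb in enumerate_global_alignments(a, b[1:]):
            yield "-" + ra, b[0] + rb
    if a and b:
        for ra, rb in enumerate_global_alignments(a[1:], b[1:]):
            yield a[0] + ra, b[0] + rb


def best_score_by_enumeration(a: str, b: str, scheme: ScoringScheme) -> float:
    """Optimal global alignment score by scoring every alignment."""
    return max(
        rescore_pair(ra, rb, scheme)
        for ra, rb in enumerate_global_alignments(a, b)
    )


def combination_is_legal(
    selection: Iterable[str],
    groups,
    rules,
) -> bool:
    """Direct evaluation of the feature-model constraints on a selection.

    Cardinalities: exactly-one needs exactly one member selected,
    one-or-more at least one, optional-one at most one.  A dependency rule
    whose trigger is selected needs at least one of its ``requires`` and
    none of its ``conflicts``.
    """
    chosen = set(selection)
    for g in groups:
        n = sum(1 for m in g.members if m in chosen)
        if g.cardinality == "exactly-one" and n != 1:
            return False
        if g.cardinality == "one-or-more" and n == 0:
            return False
        if g.cardinality == "optional-one" and n > 1:
            return False
    for r in rules:
        if r.if_selected in chosen:
            if r.requires and not any(x in chosen for x in r.requires):
                return False
            if any(x in chosen for x in r.conflicts):
                return False
    return True


def random_ultrametric(
    n: int, rng: np.random.Generator
) -> tuple[DistanceMatrix, dict[frozenset, float]]:
    """A random ultrametric matrix built from a random clock tree.

    Clusters merge at strictly increasing heights; the distance between two
    leaves is twice the height of their lowest common ancestor, which is
    exactly what average-linkage clustering should reproduce.
    """
    labels = [f"L{i}" for i in range(n)]
    clusters = [[lab] for lab in labels]
    height = 0.0
    coph: dict[frozenset, float] = {}
    while len(clusters) > 1:
        height += float(rng.uniform(0.2, 1.0))
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        for x in clusters[i]:
            for y in clusters[j]:
                coph[frozenset((x, y))] = 2.0 * height
        merged = clusters[i] + clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = coph[frozenset((labels[i], labels[j]))]
            values[i, j] = values[j, i] = d
    return DistanceMatrix(labels, values), coph
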