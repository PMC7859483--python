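"""Distance matrix construction from all-pairs alignment.

The distance stage is generic over the pairwise aligner: any callable with
the :func:`alnkit.pairwise.align_global` signature can be injected, and the
distance measure itself is a pluggable component.  The shipped measure is
ClustalW-style percent divergence: one minus the fraction of identical
residue/residue columns, ignoring columns that contain a gap.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from .pairwise import PairwiseAlignmentResult, ScoringScheme
from .seqio import GAP, SequenceSet

__all__ = ["DistanceMatrix", "identity_distance", "build_distance_matrix"]

AlignerFn = Callable[..., PairwiseAlignmentResult]
MeasureFn = Callable[[PairwiseAlignmentResult], float]


class DistanceMatrix:
    """Symmetric non-negative dissimilarities with a zero diagonal.

    Labels follow the input :class:`~alnkit.seqio.SequenceSet` order.
    """

    def __init__(self, labels: list[str], values: np.ndarray):
        values = np.asarray(values, dtype=float)
        n = len(labels)
        if values.shape != (n, n):
            raise ValueError(f"values must be {n}x{n}")
        if not np.allclose(values, values.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(values), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        if (values < 0).any() or not np.isfinite(values).all():
            raise ValueError("distances must be finite and non-negative")
        if len(set(labels)) != n:
            raise ValueError("labels must be unique")
        self.labels = list(labels)
        self.values = values

    def __len__(self) -> int:
        return len(self.labels)

    def get(self, a: str, b: str) -> float:
        return float(
            self.values[self.labels.index(a), self.labels.index(b)]
        )

    def to_phylip(self) -> str:
        """Lower-triangular PHYLIP-style text, for inspection only."""
        lines = [str(len(self.labels))]
        for i, lab in enumerate(self.labels):
            row = " ".join(f"{self.values[i, j]:.6f}" for j in range(i))
            lines.append(f"{lab}\t{row}".rstrip())
        return "\n".join(lines) + "\n"


def identity_distance(result: PairwiseAlignmentResult) -> float:
    """Percent-divergence distance of an aligned pair, in [0, 1].

    d = 1 − (identical residue/residue columns) / (residue/residue columns);
    columns containing a gap count toward neither tally, and a pair with no
    residue/residue column at all has distance 1.  Wildcard residues are
    never identical to anything, themselves included.
    """
    wildcard = result.scheme.alphabet.wildcard
    residue_cols = 0
    identical = 0
    for ca, cb in zip(result.row_a, result.row_b):
        if ca == GAP or cb == GAP:
            continue
        residue_cols += 1
        if ca == cb and ca != wildcard:
            identical += 1
    if residue_cols == 0:
        return 1.0
    return 1.0 - identical / residue_cols


def build_distance_matrix(
    seqs: SequenceSet,
    aligner: AlignerFn,
    scheme: ScoringScheme,
    measure: MeasureFn = identity_distance,
) -> DistanceMatrix:
    """All-pairs distances: run ``aligner`` then ``measure`` on every pair.

    Both the aligner and the measure are injected components; the stage
    itself only loops over unordered pairs and mirrors the result.
    """
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    n = len(seqs)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = measure(aligner(seqs[i], seqs[j], scheme))
            values[i, j] = values[j, i] = d
    return DistanceMatrix(seqs.ids, values)
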