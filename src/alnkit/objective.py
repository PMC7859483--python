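"""Objective functions scoring a finished multiple alignment.

Two objectives are registered as interchangeable components: the
Carrillo–Lipman sum-of-pairs score (the standard column-decomposable MSA
objective, with linear gap accounting) and mean pairwise percent identity.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

from .pairwise import ScoringScheme
from .seqio import GAP, MultipleAlignment

__all__ = ["ObjectiveResult", "sp_score", "percent_identity"]


@dataclass(frozen=True)
class ObjectiveResult:
    """Named objective value, optionally decomposed per column."""

    name: str
    value: float
    per_column: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.per_column is not None and abs(
            sum(self.per_column) - self.value
        ) > 1e-9:
            raise ValueError("value must equal the sum of per_column")


def sp_score(msa: MultipleAlignment, scheme: ScoringScheme) -> ObjectiveResult:
    """Sum-of-pairs score with linear gap accounting.

    Per column, over all unordered row pairs: the substitution score for a
    residue/residue pair, the gap-open cost for residue/gap, and 0 for
    gap/gap.  The value decomposes exactly over columns (``per_column``).
    """
    sub = scheme.substitution
    open_cost = scheme.gaps.open
    per_column: list[float] = []
    for c in range(msa.n_columns):
        col = msa.column(c)
        total = 0.0
        for x, y in combinations(col, 2):
            if x == GAP and y == GAP:
                continue
            if x == GAP or y == GAP:
                total += open_cost
            else:
                total += sub.score(x, y)
        per_column.append(total)
    return ObjectiveResult("sp", sum(per_column), tuple(per_column))


def percent_identity(
    msa: MultipleAlignment, scheme: ScoringScheme | None = None
) -> ObjectiveResult:
    """Mean pairwise percent identity over gap-free columns.

    For each unordered row pair: 100 × identical residue/residue columns /
    residue/residue columns (wildcards never count as identical, matching
    the distance stage's convention); a pair with no residue/residue column
    contributes 0.  The mean over pairs is returned; single-row alignments
    score 100.
    """
    wildcard = msa.alphabet.wildcard
    pairs = list(combinations([text for _, text in msa.rows], 2))
    if not pairs:
        return ObjectiveResult("percent-identity", 100.0)
    total = 0.0
    for ra, rb in pairs:
        residue_cols = identical = 0
        for x, y in zip(ra, rb):
            if x == GAP or y == GAP:
                continue
            residue_cols += 1
            if x == y and x != wildcard:
                identical += 1
        if residue_cols:
            total += 100.0 * identical / residue_cols
    return ObjectiveResult("percent-identity", total / len(pairs))
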