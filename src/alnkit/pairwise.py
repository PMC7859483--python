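"""Dynamic-programming global pairwise alignment (Needleman–Wunsch / Gotoh).

The classic exact solution to pairwise alignment: a global DP over the two
sequences with either a linear gap model (each gap symbol costs ``open``) or
an affine one (a maximal gap run of length L costs ``open + extend*(L-1)``).
End gaps are penalized like internal gaps.

Both gap models run through one three-state engine (match / gap-in-b /
gap-in-a layers); the linear model is the affine engine with
``extend == open``, which charges exactly ``open`` per gap symbol.
Traceback ties resolve diagonal > up (gap in b's row) > left (gap in a's
row), so results are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from numba import njit

from .seqio import GAP, Alphabet, SeqIOError, Sequence, SubstitutionTable

__all__ = [
    "GapModel",
    "ScoringScheme",
    "PairwiseAlignmentResult",
    "align_global",
    "rescore_pair",
]

NEG_INF = float("-inf")


@dataclass(frozen=True)
class GapModel:
    """Gap penalty model.

    ``open`` is the cost of a gap symbol (linear) or of starting a gap run
    (affine); ``extend`` is the cost of each additional symbol in a run and
    is ignored for the linear kind.  Both are ≤ 0.
    """

    kind: str
    open: float
    extend: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "affine"):
            raise ValueError(f"unknown gap model kind {self.kind!r}")
        if self.open > 0:
            raise ValueError("gap open cost must be <= 0")
        if self.kind == "affine" and self.extend > 0:
            raise ValueError("gap extend cost must be <= 0")

    @property
    def effective_extend(self) -> float:
        """Per-symbol cost after the first: equals ``open`` for linear gaps."""
        return self.open if self.kind == "linear" else self.extend

    def run_cost(self, length: int) -> float:
        """Cost of one maximal gap run of the given length."""
        if length <= 0:
            return 0.0
        return self.open + self.effective_extend * (length - 1)


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution table + gap model + alphabet, as one unit."""

    substitution: SubstitutionTable
    gaps: GapModel
    alphabet: Alphabet

    def __post_init__(self) -> None:
        if not self.substitution.defined_for(self.alphabet):
            missing = [
                s for s in self.alphabet.symbols
                if s not in self.substitution.symbols
            ]
            raise ValueError(
                "substitution table does not cover alphabet symbols "
                f"{missing}"
            )


@dataclass(frozen=True)
class PairwiseAlignmentResult:
    """An optimal global alignment of two sequences and its score."""

    row_a: str
    row_b: str
    score: float
    scheme: ScoringScheme

    def __post_init__(self) -> None:
        if len(self.row_a) != len(self.row_b):
            raise ValueError("aligned rows must have equal length")


# ---------------------------------------------------------------------------
# Core engine, shared with profile-profile alignment.

# Move codes: D = consume one item of each side (diagonal),
#             U = consume a-side item, gap on b side (up),
#             L = consume b-side item, gap on a side (left).


@njit(cache=True)
def _gotoh_fill(S: np.ndarray, go: float, ge: float):  # pragma: no cover
    """Three-layer DP fill + traceback (compiled).

    Layers: M ends diagonal, X ends with a gap on the b side, Y ends with
    a gap on the a side; pointer values 0/1/2 name the predecessor layer.
    Ties prefer M > X > Y everywhere, which realises the diagonal > up >
    left traceback order.  Returns (best score, move codes) with move
    codes 0=D, 1=U, 2=L in alignment order.
    """
    n, m = S.shape
    neg = -1e30
    M = np.full((n + 1, m + 1), neg)
    X = np.full((n + 1, m + 1), neg)
    Y = np.full((n + 1, m + 1), neg)
    pM = np.zeros((n + 1, m + 1), dtype=np.int8)
    pX = np.zeros((n + 1, m + 1), dtype=np.int8)
    pY = np.zeros((n + 1, m + 1), dtype=np.int8)

    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = go + ge * (i - 1)
        pX[i, 0] = 0 if i == 1 else 1
    for j in range(1, m + 1):
        Y[0, j] = go + ge * (j - 1)
        pY[0, j] = 0 if j == 1 else 2

    for i in range(1, n + 1):
        for j in range(1, m + 1):
            # M: diagonal step from any layer at (i-1, j-1).
            vm, vx, vy = M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]
            if vm >= vx and vm >= vy:
                M[i, j] = vm + S[i - 1, j - 1]
                pM[i, j] = 0
            elif vx >= vy:
                M[i, j] = vx + S[i - 1, j - 1]
                pM[i, j] = 1
            else:
                M[i, j] = vy + S[i - 1, j - 1]
                pM[i, j] = 2
            # X: gap on the b side; opening from M/Y, extending from X.
            vm, vx, vy = M[i - 1, j] + go, X[i - 1, j] + ge, Y[i - 1, j] + go
            if vm >= vx and vm >= vy:
                X[i, j] = vm
                pX[i, j] = 0
            elif vx >= vy:
                X[i, j] = vx
                pX[i, j] = 1
            else:
                X[i, j] = vy
                pX[i, j] = 2
            # Y: gap on the a side; opening from M/X, extending from Y.
            vm, vx, vy = M[i, j - 1] + go, X[i, j - 1] + go, Y[i, j - 1] + ge
            if vm >= vx and vm >= vy:
                Y[i, j] = vm
                pY[i, j] = 0
            elif vx >= vy:
                Y[i, j] = vx
                pY[i, j] = 1
            else:
                Y[i, j] = vy
                pY[i, j] = 2

    vm, vx, vy = M[n, m], X[n, m], Y[n, m]
    if vm >= vx and vm >= vy:
        best, state = vm, 0
    elif vx >= vy:
        best, state = vx, 1
    else:
        best, state = vy, 2

    moves = np.empty(n + m, dtype=np.int8)
    k = n + m
    i, j = n, m
    while i > 0 or j > 0:
        k -= 1
        if state == 0:
            moves[k] = 0
            state = pM[i, j]
            i -= 1
            j -= 1
        elif state == 1:
            moves[k] = 1
            state = pX[i, j]
            i -= 1
        else:
            moves[k] = 2
            state = pY[i, j]
            j -= 1
    return best, moves[k:]


_MOVE_CODES = "DUL"


def align_generic(score_matrix: np.ndarray, gaps: GapModel) -> tuple[float, str]:
    """Optimal global alignment over a precomputed item-pair score matrix.

    ``score_matrix[i, j]`` is the substitution score of a-item i vs b-item
    j.  Returns the optimal score and the move string over {D, U, L}
    (D consumes one item of each side, U consumes an a-item against a gap,
    L a b-item against a gap).
    """
    S = np.ascontiguousarray(score_matrix, dtype=np.float64)
    n, m = S.shape
    if n == 0 or m == 0:  # forced all-gap alignment
        length = max(n, m)
        return gaps.run_cost(length), ("U" if m == 0 else "L") * length
    best, moves = _gotoh_fill(S, float(gaps.open), float(gaps.effective_extend))
    return float(best), "".join(_MOVE_CODES[c] for c in moves)


# ---------------------------------------------------------------------------


@lru_cache(maxsize=32)
def scheme_symbol_matrix(
    scheme: ScoringScheme,
) -> tuple[dict[str, int], np.ndarray]:
    """Alphabet-symbol index and dense substitution matrix for a scheme.

    Cached per scheme instance so repeated alignments avoid per-residue
    table lookups.
    """
    symbols = scheme.alphabet.symbols
    index = {s: i for i, s in enumerate(symbols)}
    mat = np.array(
        [[scheme.substitution.score(a, b) for b in symbols] for a in symbols]
    )
    return index, mat


def align_global(
    a: Sequence | str, b: Sequence | str, scheme: ScoringScheme
) -> PairwiseAlignmentResult:
    """Optimal global alignment of two sequences under the scheme.

    Needleman–Wunsch for linear gaps, three-state Gotoh for affine; in both
    cases end gaps are charged like internal ones.  The returned score is
    always consistent with :func:`rescore_pair` on the returned rows.
    Accepts :class:`~alnkit.seqio.Sequence` objects or bare residue strings
    (a bare string may be empty, forcing an all-gap row).
    """
    ra = a.residues if isinstance(a, Sequence) else a
    rb = b.residues if isinstance(b, Sequence) else b
    if not ra and not rb:
        raise ValueError("at least one sequence must be non-empty")
    index, mat = scheme_symbol_matrix(scheme)
    for residues in (ra, rb):
        for ch in residues:
            if ch not in index:
                raise SeqIOError(
                    f"residue {ch!r} is not covered by substitution table "
                    f"{scheme.substitution.name!r}"
                )
    ia = np.array([index[ch] for ch in ra], dtype=np.intp)
    ib = np.array([index[ch] for ch in rb], dtype=np.intp)
    S = mat[np.ix_(ia, ib)] if len(ra) and len(rb) else np.zeros((len(ra), len(rb)))
    best, moves = align_generic(S, scheme.gaps)

    out_a: list[str] = []
    out_b: list[str] = []
    i = j = 0
    for mv in moves:
        if mv == "D":
            out_a.append(ra[i])
            out_b.append(rb[j])
            i += 1
            j += 1
        elif mv == "U":
            out_a.append(ra[i])
            out_b.append(GAP)
            i += 1
        else:
            out_a.append(GAP)
            out_b.append(rb[j])
            j += 1
    return PairwiseAlignmentResult("".join(out_a), "".join(out_b), best, scheme)


def rescore_pair(row_a: str, row_b: str, scheme: ScoringScheme) -> float:
    """Score an already-aligned pair of rows under the scheme.

    Sum of substitution scores over residue/residue columns plus gap costs:
    linear charges ``open`` per gap symbol; affine charges
    ``open + extend*(run-1)`` per maximal gap run in either row.  This is
    the independent self-consistency oracle for :func:`align_global`.
    """
    if len(row_a) != len(row_b):
        raise ValueError("rows must have equal length")
    sub = scheme.substitution
    total = 0.0
    for ca, cb in zip(row_a, row_b):
        if ca == GAP and cb == GAP:
            raise ValueError("gap/gap column is not allowed in a pair")
        if ca != GAP and cb != GAP:
            total += sub.score(ca, cb)
    for row in (row_a, row_b):
        run = 0
        for ch in row + "\0":  # sentinel flushes the final run
            if ch == GAP:
                run += 1
            else:
                total += scheme.gaps.run_cost(run)
                run = 0
    return total
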