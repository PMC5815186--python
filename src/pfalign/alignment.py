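"""Semi-global (free-end-gap) pairwise alignment with affine gap penalties.

Conventions, pinned because learned gap penalties depend on them:

* an internal gap run of length k scores ``open + (k-1)*extend`` (a length-1
  run costs ``open``); runs of opposite gap type break each other;
* a gap run is *terminal* -- and free -- exactly when it contains the first
  or the last alignment column.  This is the set of layouts the standard
  zero-boundary semi-global recursion treats as free: in a mixed terminal
  region (gaps in both sequences at one end) only the outermost run is free;
* traceback tie-break: aligned pair (diagonal) over gap-in-B (up) over
  gap-in-A (left), applied identically in the DP and the brute-force oracle.

The DP is the three-state Gotoh recursion; the inner loops are compiled with
numba when available.  A brute-force enumerator over all monotone column
layouts serves as an exact oracle on tiny instances, accumulating scores in
the same left-to-right addition order as the DP so optimal scores agree
bitwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .profiles import GAP, PairwiseAlignment
from .scoring import ScoreMatrix

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        return wrap if not (args and callable(args[0])) else args[0]


NEG = -1e300


class AlignmentError(ValueError):
    """Invalid alignment input."""


@dataclass(frozen=True)
class GapPenalties:
    """Affine gap penalties (both <= 0; opening at least as costly)."""

    open: float
    extend: float

    def __post_init__(self):
        if not (np.isfinite(self.open) and np.isfinite(self.extend)):
            raise AlignmentError("gap penalties must be finite")
        if self.open > 0 or self.extend > 0:
            raise AlignmentError(
                f"gap penalties must be <= 0, got ({self.open}, {self.extend})"
            )
        if self.open > self.extend:
            raise AlignmentError(
                f"open ({self.open}) must be <= extend ({self.extend})"
            )


@dataclass(frozen=True)
class AlignmentResult:
    alignment: PairwiseAlignment
    score: float
    traceback_path: Tuple[str, ...]  # moves: 'D' diag, 'U' gap in B, 'L' gap in A


@njit(cache=False)
def _fill(S, go, ge):  # pragma: no cover - numba kernel
    la, lb = S.shape
    M = np.full((la + 1, lb + 1), NEG)
    X = np.full((la + 1, lb + 1), NEG)  # last column is (i, -): gap in B
    Y = np.full((la + 1, lb + 1), NEG)  # last column is (-, j): gap in A
    M[0, 0] = 0.0
    for i in range(1, la + 1):
        X[i, 0] = 0.0  # free leading gap in B
    for j in range(1, lb + 1):
        Y[0, j] = 0.0  # free leading gap in A
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            best = M[i - 1, j - 1]
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
            M[i, j] = best + S[i - 1, j - 1]

            bx = M[i - 1, j] + go
            t = X[i - 1, j] + ge
            if t > bx:
                bx = t
            t = Y[i - 1, j] + go
            if t > bx:
                bx = t
            X[i, j] = bx

            by = M[i, j - 1] + go
            t = X[i, j - 1] + go
            if t > by:
                by = t
            t = Y[i, j - 1] + ge
            if t > by:
                by = t
            Y[i, j] = by
    return M, X, Y


def _pick_end(M, X, Y, la, lb):
    """Deterministic argmax over the free-trailing boundary.

    Scan order: (la, lb), then last column upward, then last row leftward;
    states in priority M > X > Y; strictly-greater replacement.
    """
    best = NEG
    where = (la, lb, 0)
    cells = [(la, lb)]
    cells += [(i, lb) for i in range(la - 1, -1, -1)]
    cells += [(la, j) for j in range(lb - 1, -1, -1)]
    for i, j in cells:
        for s, mat in enumerate((M, X, Y)):
            if mat[i, j] > best:
                best = mat[i, j]
                where = (i, j, s)
    return best, where


def semi_global_align(S: ScoreMatrix, gaps: GapPenalties) -> AlignmentResult:
    """Maximum-score semi-global alignment under the module conventions."""
    values = S.values
    if values.size == 0:
        raise AlignmentError("empty score matrix")
    if not np.isfinite(values).all():
        raise AlignmentError("non-finite score matrix entry")
    la, lb = values.shape
    go, ge = gaps.open, gaps.extend
    M, X, Y = _fill(values, go, ge)
    score, (ei, ej, state) = _pick_end(M, X, Y, la, lb)

    columns: List[Tuple[Optional[int], Optional[int]]] = []
    # free trailing gaps for the unconsumed suffixes
    tail = [(k, GAP) for k in range(ei, la)] + [(GAP, k) for k in range(ej, lb)]

    i, j, s = ei, ej, state
    while True:
        if s == 0 and i == 0 and j == 0:
            break
        if s == 1 and j == 0:  # free leading gap in B covers A[0:i]
            columns.extend((k, GAP) for k in range(i - 1, -1, -1))
            break
        if s == 2 and i == 0:  # free leading gap in A covers B[0:j]
            columns.extend((GAP, k) for k in range(j - 1, -1, -1))
            break
        if s == 0:
            target = M[i, j]
            sij = values[i - 1, j - 1]
            columns.append((i - 1, j - 1))
            i, j = i - 1, j - 1
            # same additions as the fill, so equality is exact
            prev = (M[i, j] + sij, X[i, j] + sij, Y[i, j] + sij)
        elif s == 1:
            target = X[i, j]
            columns.append((i - 1, GAP))
            i = i - 1
            prev = (M[i, j] + go, X[i, j] + ge, Y[i, j] + go)
        else:
            target = Y[i, j]
            columns.append((GAP, j - 1))
            j = j - 1
            prev = (M[i, j] + go, X[i, j] + go, Y[i, j] + ge)
        # tie-break: diagonal > up > left
        for cand, val in enumerate(prev):
            if val == target:
                s = cand
                break
        else:  # pragma: no cover - defensive
            raise AssertionError("traceback lost the optimal path")

    columns.reverse()
    columns.extend(tail)
    moves = tuple(
        "D" if (i is not None and j is not None) else ("U" if i is not None else "L")
        for i, j in columns
    )
    aln = PairwiseAlignment(id_a="A", id_b="B", columns=tuple(columns))
    return AlignmentResult(alignment=aln, score=float(score), traceback_path=moves)


# ---------------------------------------------------------------------------
# Rescoring and the brute-force oracle
# ---------------------------------------------------------------------------

def _score_columns(columns, values, go, ge) -> float:
    """Score a column layout left to right under the module conventions.

    Uses the same per-column addition order as the DP so that, for the
    optimal layout, the floating-point sum is bitwise identical.
    """
    n = len(columns)
    la, lb = values.shape
    total = 0.0
    run_type = 0  # 0 none, 1 gap-in-B, 2 gap-in-A
    run_start = -1
    for k, (i, j) in enumerate(columns):
        if i is not None and j is not None:
            if i >= la or j >= lb:
                raise AlignmentError(f"column ({i}, {j}) outside score matrix")
            total = total + values[i, j]
            run_type = 0
        else:
            t = 1 if i is not None else 2
            if t != run_type:
                run_type, run_start = t, k
            # find run end lazily: free iff run contains column 0 or column n-1
            run_end = k
            m = k + 1
            while m < n:
                ci, cj = columns[m]
                tm = 0 if (ci is not None and cj is not None) else (1 if ci is not None else 2)
                if tm != t:
                    break
                run_end = m
                m += 1
            free = run_start == 0 or run_end == n - 1
            if not free:
                total = total + (go if k == run_start else ge)
    return total


def rescore_alignment(
    alignment: PairwiseAlignment, S: ScoreMatrix, gaps: GapPenalties
) -> float:
    """Recompute an alignment's score from its columns (terminal runs free)."""
    return float(_score_columns(list(alignment.columns), S.values, gaps.open, gaps.extend))


def brute_force_align(S: ScoreMatrix, gaps: GapPenalties) -> AlignmentResult:
    """Exhaustive enumeration of every monotone column layout (tiny inputs).

    Oracle for :func:`semi_global_align`; refuses instances above the
    L_A * L_B <= 36 enumeration bound.
    """
    values = S.values
    la, lb = values.shape
    if la * lb > 36:
        raise AlignmentError(f"instance {la}x{lb} above enumeration bound (36 cells)")
    go, ge = gaps.open, gaps.extend

    best_score = -np.inf
    best_cols = None

    cols: List[Tuple[Optional[int], Optional[int]]] = []

    def recurse(i, j):
        nonlocal best_score, best_cols
        if i == la and j == lb:
            sc = _score_columns(cols, values, go, ge)
            if sc > best_score:  # first-found wins ties: D > U > L move order
                best_score = sc
                best_cols = list(cols)
            return
        if i < la and j < lb:
            cols.append((i, j))
            recurse(i + 1, j + 1)
            cols.pop()
        if i < la:
            cols.append((i, GAP))
            recurse(i + 1, j)
            cols.pop()
        if j < lb:
            cols.append((GAP, j))
            recurse(i, j + 1)
            cols.pop()

    recurse(0, 0)
    moves = tuple(
        "D" if (i is not None and j is not None) else ("U" if i is not None else "L")
        for i, j in best_cols
    )
    aln = PairwiseAlignment(id_a="A", id_b="B", columns=tuple(best_cols))
    return AlignmentResult(alignment=aln, score=float(best_score), traceback_path=moves)


def count_monotone_layouts(la: int, lb: int) -> int:
    """Number of distinct monotone column layouts (Delannoy recursion)."""
    d = np.zeros((la + 1, lb + 1), dtype=object)
    d[0, :] = 1
    d[:, 0] = 1
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            d[i, j] = d[i - 1, j - 1] + d[i - 1, j] + d[i, j - 1]
    return int(d[la, lb])
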