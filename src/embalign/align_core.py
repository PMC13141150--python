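"""Exact global affine-gap alignment (Needleman-Wunsch-Gotoh).

The recursion runs over three states M / Ix / Iy, where Ix consumes the
left (profile) axis against a gap in the right sequence and Iy the
converse.  A length-L gap costs gap_open + (L-1) * gap_extend; terminal
gaps are charged like internal ones.  Ties are broken with the fixed state
preference M > Ix > Iy so tracebacks are reproducible.

This module deliberately knows nothing about scoring backends: it accepts
a fixed numeric matrix and never invokes a scoring callback.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_NEG_INF = float("-inf")

# traceback state codes
_M, _IX, _IY = 0, 1, 2


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class GapPenalties:
    gap_open: float
    gap_extend: float

    def __post_init__(self) -> None:
        if not (self.gap_open <= self.gap_extend <= 0.0):
            raise AlignmentError(
                f"require gap_open <= gap_extend <= 0, got "
                f"({self.gap_open}, {self.gap_extend})"
            )

    def scaled(self, factor: float) -> "GapPenalties":
        return GapPenalties(self.gap_open * factor, self.gap_extend * factor)

    def gap_cost(self, length: int) -> float:
        if length <= 0:
            return 0.0
        return self.gap_open + (length - 1) * self.gap_extend


@dataclass(frozen=True)
class PairwiseAlignmentResult:
    """Gapped index traces over the two axes plus the optimal score.

    ``aligned_left[k]`` is the left-axis unit index placed at alignment
    position k, or None for a gap; likewise ``aligned_right``.
    """

    aligned_left: tuple[int | None, ...]
    aligned_right: tuple[int | None, ...]
    total_score: float
    cell_count: tuple[int, int]


def _as_matrix(scores) -> np.ndarray:
    arr = np.asarray(getattr(scores, "scores", scores), dtype=float)
    if arr.ndim != 2:
        raise AlignmentError("score input must be a 2-D matrix")
    if arr.size and not np.all(np.isfinite(arr)):
        i, j = np.argwhere(~np.isfinite(arr))[0]
        raise AlignmentError(f"non-finite score entry at ({i}, {j})")
    return arr


def _best3(vm: float, vx: float, vy: float) -> tuple[float, int]:
    # fixed tie preference M > Ix > Iy
    if vm >= vx and vm >= vy:
        return vm, _M
    if vx >= vy:
        return vx, _IX
    return vy, _IY


def gotoh_align(scores, penalties: GapPenalties) -> PairwiseAlignmentResult:
    """Optimal global alignment of an n x m score matrix.

    Accepts a plain array or any object exposing a ``.scores`` array.
    """
    S = _as_matrix(scores)
    n, m = S.shape
    po, pe = penalties.gap_open, penalties.gap_extend

    if n == 0 and m == 0:
        return PairwiseAlignmentResult((), (), 0.0, (0, 0))
    if n == 0:
        return PairwiseAlignmentResult(
            tuple([None] * m), tuple(range(m)), penalties.gap_cost(m), (0, m)
        )
    if m == 0:
        return PairwiseAlignmentResult(
            tuple(range(n)), tuple([None] * n), penalties.gap_cost(n), (n, 0)
        )

    width = m + 1
    # flat (n+1) x (m+1) DP tables
    M = [_NEG_INF] * ((n + 1) * width)
    Ix = [_NEG_INF] * ((n + 1) * width)
    Iy = [_NEG_INF] * ((n + 1) * width)
    ptrM = [0] * ((n + 1) * width)
    ptrIx = [0] * ((n + 1) * width)
    ptrIy = [0] * ((n + 1) * width)

    M[0] = 0.0
    for i in range(1, n + 1):
        Ix[i * width] = po + (i - 1) * pe
        ptrIx[i * width] = _M if i == 1 else _IX
    for j in range(1, m + 1):
        Iy[j] = po + (j - 1) * pe
        ptrIy[j] = _M if j == 1 else _IY

    Srows = S.tolist()
    for i in range(1, n + 1):
        srow = Srows[i - 1]
        base = i * width
        prev = base - width
        for j in range(1, m + 1):
            d = prev + j - 1
            vm, st = _best3(M[d], Ix[d], Iy[d])
            M[base + j] = vm + srow[j - 1]
            ptrM[base + j] = st

            u = prev + j
            vx, stx = _best3(M[u] + po, Ix[u] + pe, Iy[u] + po)
            Ix[base + j] = vx
            ptrIx[base + j] = stx

            left = base + j - 1
            vy, sty = _best3(M[left] + po, Ix[left] + po, Iy[left] + pe)
            Iy[base + j] = vy
            ptrIy[base + j] = sty

    end = n * width + m
    total, state = _best3(M[end], Ix[end], Iy[end])

    left_trace: list[int | None] = []
    right_trace: list[int | None] = []
    i, j = n, m
    while i > 0 or j > 0:
        idx = i * width + j
        if state == _M:
            left_trace.append(i - 1)
            right_trace.append(j - 1)
            state = ptrM[idx]
            i -= 1
            j -= 1
        elif state == _IX:
            left_trace.append(i - 1)
            right_trace.append(None)
            state = ptrIx[idx]
            i -= 1
        else:
            left_trace.append(None)
            right_trace.append(j - 1)
            state = ptrIy[idx]
            j -= 1
    left_trace.reverse()
    right_trace.reverse()
    return PairwiseAlignmentResult(
        tuple(left_trace), tuple(right_trace), float(total), (n, m)
    )


def _check_traces(
    aligned_left: tuple[int | None, ...],
    aligned_right: tuple[int | None, ...],
    n: int,
    m: int,
) -> None:
    if len(aligned_left) != len(aligned_right):
        raise AlignmentError("traces have different lengths")
    left_idx = [k for k in aligned_left if k is not None]
    right_idx = [k for k in aligned_right if k is not None]
    for a, b in zip(aligned_left, aligned_right):
        if a is None and b is None:
            raise AlignmentError("position gapped on both axes")
    if left_idx != list(range(n)):
        raise AlignmentError(f"left trace does not enumerate 0..{n - 1} in order")
    if right_idx != list(range(m)):
        raise AlignmentError(f"right trace does not enumerate 0..{m - 1} in order")


def score_alignment(
    aligned_left,
    aligned_right,
    scores,
    penalties: GapPenalties,
) -> float:
    """Independently re-score a pair of traces under the same conventions.

    Each maximal run of gaps within one trace counts as a single gap event
    costing gap_open + (run_length - 1) * gap_extend.
    """
    S = _as_matrix(scores)
    n, m = S.shape
    aligned_left = tuple(aligned_left)
    aligned_right = tuple(aligned_right)
    _check_traces(aligned_left, aligned_right, n, m)

    total = 0.0
    left_run = 0
    right_run = 0
    for a, b in zip(aligned_left, aligned_right):
        if a is not None and b is not None:
            total += S[a, b]
            left_run = right_run = 0
        elif a is None:
            left_run += 1
            right_run = 0
            total += penalties.gap_open if left_run == 1 else penalties.gap_extend
        else:
            right_run += 1
            left_run = 0
            total += penalties.gap_open if right_run == 1 else penalties.gap_extend
    return total
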