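"""Local dynamic-programming alignment between a PWM and a DNA window.

The aligner is Smith-Waterman over (window positions x matrix columns) with a
linear gap penalty.  The substitution score for placing window base i against
matrix column j is the PWM weight of the ordered dinucleotide (previous
window base, current base) at that column, so neighbouring-base correlation
enters the similarity directly.  The first window position, and any position
whose own or preceding base is N, scores 0 (neutral - never a match bonus).

``F_max`` is the maximum cell of the DP matrix; the trace is recovered by
deterministic backtracking (diagonal preferred over gap-in-window over
gap-in-profile).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .genome import encode
from .pwm import PWM, dinucleotide_row

NEG = -1


@dataclass
class AlignmentTrace:
    """Paired window-symbol / matrix-column path with its local score.

    ``s1`` holds window base codes with -1 marking a deletion in the sequence
    (a profile column consumed with no base); ``s2`` holds 1-based matrix
    column indices with -1 marking a deletion in the profile (a base consumed
    with no column).  ``win_start``/``win_end`` are 1-based window positions
    of the first/last consumed base; ``window_offset`` is the 1-based
    concatenated-genome coordinate of the window start, so the aligned
    genomic segment is ``[window_offset + win_start - 1,
    window_offset + win_end - 1]``.
    """

    s1: np.ndarray
    s2: np.ndarray
    score: float
    window_offset: int = 1
    win_start: int = 0
    win_end: int = 0

    @property
    def k(self) -> int:
        return len(self.s1)

    @property
    def genomic_span(self) -> tuple[int, int]:
        """1-based inclusive concatenated coordinates of the aligned bases."""
        if self.k == 0:
            return (0, -1)
        return (self.window_offset + self.win_start - 1,
                self.window_offset + self.win_end - 1)


def match_score(prev_base, base, column_j: int, pwm: PWM) -> float:
    """Weight of aligning ``base`` (with left context ``prev_base``) to column j.

    Bases may be characters or integer codes; ``None``/N context or an N base
    yields the neutral score 0.
    """
    def _code(b):
        if b is None:
            return NEG
        if isinstance(b, str):
            return int(encode(b)[0])
        return int(b)

    p, c = _code(prev_base), _code(base)
    if p < 0 or c < 0:
        return 0.0
    if not 1 <= column_j <= pwm.L:
        raise ValueError(f"column {column_j} outside [1, {pwm.L}]")
    return float(pwm.weights[dinucleotide_row(p, c), column_j - 1])


@njit(cache=True)
def _fill_H(win, weights, g):  # pragma: no cover - exercised via wrappers
    w = win.shape[0]
    L = weights.shape[1]
    H = np.zeros((w + 1, L + 1))
    best = 0.0
    bi = 0
    bj = 0
    for i in range(1, w + 1):
        c = win[i - 1]
        p = win[i - 2] if i >= 2 else -1
        for j in range(1, L + 1):
            if p < 0 or c < 0:
                s = 0.0
            else:
                s = weights[p + 4 * c, j - 1]
            v = H[i - 1, j - 1] + s
            u = H[i - 1, j] - g
            if u > v:
                v = u
            l = H[i, j - 1] - g
            if l > v:
                v = l
            if v < 0.0:
                v = 0.0
            H[i, j] = v
            if v > best:
                best = v
                bi = i
                bj = j
    return H, best, bi, bj


@njit(cache=True)
def _score_window(win, weights, g):  # pragma: no cover
    """F_max only, with O(L) memory (used by the genome scanner)."""
    w = win.shape[0]
    L = weights.shape[1]
    prev_row = np.zeros(L + 1)
    cur_row = np.zeros(L + 1)
    best = 0.0
    for i in range(1, w + 1):
        c = win[i - 1]
        p = win[i - 2] if i >= 2 else -1
        cur_row[0] = 0.0
        for j in range(1, L + 1):
            if p < 0 or c < 0:
                s = 0.0
            else:
                s = weights[p + 4 * c, j - 1]
            v = prev_row[j - 1] + s
            u = prev_row[j] - g
            if u > v:
                v = u
            l = cur_row[j - 1] - g
            if l > v:
                v = l
            if v < 0.0:
                v = 0.0
            cur_row[j] = v
            if v > best:
                best = v
        tmp = prev_row
        prev_row = cur_row
        cur_row = tmp
    return best


def align_local(pwm: PWM, window, gap_penalty: float = 2.0,
                window_offset: int = 1) -> AlignmentTrace:
    """Best local alignment between a PWM and a DNA window.

    ``window`` may be a string or an int8 code array.  Returns an empty trace
    with score 0 when nothing scores positive or the window is shorter than
    two bases.
    """
    win = encode(window) if isinstance(window, str) else np.asarray(window, dtype=np.int8)
    if len(win) < 2:
        return AlignmentTrace(np.empty(0, np.int64), np.empty(0, np.int64),
                              0.0, window_offset)
    H, best, bi, bj = _fill_H(win, pwm.weights, float(gap_penalty))
    if best <= 0.0:
        return AlignmentTrace(np.empty(0, np.int64), np.empty(0, np.int64),
                              0.0, window_offset)
    s1_rev: list[int] = []
    s2_rev: list[int] = []
    i, j = int(bi), int(bj)
    win_end = i
    win_start = i
    g = float(gap_penalty)
    while i > 0 and j > 0 and H[i, j] > 0.0:
        c = int(win[i - 1])
        p = int(win[i - 2]) if i >= 2 else -1
        s = 0.0 if (p < 0 or c < 0) else float(pwm.weights[p + 4 * c, j - 1])
        # preference: diagonal > gap-in-window (up) > gap-in-profile (left)
        if np.isclose(H[i, j], H[i - 1, j - 1] + s):
            s1_rev.append(c)
            s2_rev.append(j)
            win_start = i
            i -= 1
            j -= 1
        elif np.isclose(H[i, j], H[i - 1, j] - g):
            s1_rev.append(c)
            s2_rev.append(NEG)
            win_start = i
            i -= 1
        else:
            s1_rev.append(NEG)
            s2_rev.append(j)
            j -= 1
    s1 = np.array(s1_rev[::-1], dtype=np.int64)
    s2 = np.array(s2_rev[::-1], dtype=np.int64)
    return AlignmentTrace(s1, s2, float(best), window_offset,
                          win_start, win_end)
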