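"""Banded global alignment with affine gap penalties.

Reads are end-to-end alignments of a short amplicon against its design
sequence, so a global (Needleman-Wunsch) alignment inside a diagonal band is
both exact and fast.  Scoring defaults: match +1, mismatch -2, gap open -4,
gap extend -1; a gap of length k costs ``gap_open + k * gap_extend``.

Ties are broken deterministically: a substitution is preferred over a gap, a
deletion over an insertion, and every indel in the reported edit path is
left-normalized afterwards (see :mod:`cloneval.edits`), so co-optimal gap
placements inside homopolymers always collapse to the leftmost one.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

NEG = -1e18

_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _LUT[ord(_b)] = _i
    _LUT[ord(_b.lower())] = _i


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes (A,C,G,T -> 0..3; other -> 4)."""
    return _LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]


@dataclass(frozen=True)
class Scoring:
    match: float = 1.0
    mismatch: float = -2.0
    gap_open: float = -4.0
    gap_extend: float = -1.0
    #: alignments scoring below ``floor_fraction * match * min(len)`` are rejected
    floor_fraction: float = 0.5


class UnalignableReadError(ValueError):
    """Raised when the optimal alignment scores below the configured floor."""

    def __init__(self, read_id: str, score: float, floor: float):
        self.read_id, self.score, self.floor = read_id, score, floor
        super().__init__(
            f"read {read_id!r} unalignable: score {score:.1f} below floor {floor:.1f}"
        )


@njit(cache=True)
def _band_align(read, ref, band, match, mismatch, gap_open, gap_extend):
    """Banded global affine DP.  Returns (score, ops) with ops reversed:
    0 = diagonal (match/mismatch), 1 = deletion (consumes ref),
    2 = insertion (consumes read)."""
    n = read.shape[0]
    m = ref.shape[0]
    dmin = min(0, m - n) - band
    dmax = max(0, m - n) + band
    width = dmax - dmin + 1

    M = np.full((n + 1, width), NEG)
    X = np.full((n + 1, width), NEG)  # gap in read (deletion from ref)
    Y = np.full((n + 1, width), NEG)  # gap in ref (insertion in read)
    pM = np.zeros((n + 1, width), dtype=np.uint8)  # 0/1/2: prev state M/X/Y
    pX = np.zeros((n + 1, width), dtype=np.uint8)  # 0 open from M, 1 extend
    pY = np.zeros((n + 1, width), dtype=np.uint8)

    go = gap_open + gap_extend  # cost of the first gap base

    k0 = -dmin  # k index of j == i diagonal at i == 0
    M[0, k0] = 0.0
    for k in range(k0 + 1, width):
        j = k + dmin  # i == 0
        if j > m:
            break
        if k == k0 + 1:
            X[0, k] = go
            pX[0, k] = 0
        else:
            X[0, k] = X[0, k - 1] + gap_extend
            pX[0, k] = 1

    for i in range(1, n + 1):
        for k in range(width):
            j = i + dmin + k
            if j < 0 or j > m:
                continue
            if j == 0:
                # only insertions can reach column 0
                if i == 1:
                    Y[i, k] = go
                    pY[i, k] = 0
                elif k + 1 < width:
                    Y[i, k] = Y[i - 1, k + 1] + gap_extend
                    pY[i, k] = 1
                continue
            # M: diagonal move, same k at row i-1
            best = M[i - 1, k]
            src = 0
            if X[i - 1, k] > best:
                best = X[i - 1, k]
                src = 1
            if Y[i - 1, k] > best:
                best = Y[i - 1, k]
                src = 2
            if best > NEG / 2:
                a = read[i - 1]
                b = ref[j - 1]
                s = match if (a == b and a < 4) else mismatch
                M[i, k] = best + s
                pM[i, k] = src
            # X: horizontal move, k-1 in same row
            if k - 1 >= 0:
                open_s = M[i, k - 1] + go
                ext_s = X[i, k - 1] + gap_extend
                if open_s >= ext_s:
                    X[i, k] = open_s
                    pX[i, k] = 0
                else:
                    X[i, k] = ext_s
                    pX[i, k] = 1
            # Y: vertical move, k+1 in previous row
            if k + 1 < width:
                open_s = M[i - 1, k + 1] + go
                ext_s = Y[i - 1, k + 1] + gap_extend
                if open_s >= ext_s:
                    Y[i, k] = open_s
                    pY[i, k] = 0
                else:
                    Y[i, k] = ext_s
                    pY[i, k] = 1

    k_end = m - n - dmin
    score = M[n, k_end]
    state = 0
    if X[n, k_end] > score:
        score = X[n, k_end]
        state = 1
    if Y[n, k_end] > score:
        score = Y[n, k_end]
        state = 2

    ops = np.empty(n + m, dtype=np.uint8)
    nops = 0
    i = n
    k = k_end
    while True:
        j = i + dmin + k
        if i == 0 and j == 0:
            break
        if state == 0:
            ops[nops] = 0
            nops += 1
            state = pM[i, k]
            i -= 1
        elif state == 1:
            ops[nops] = 1
            nops += 1
            nxt = pX[i, k]
            k -= 1
            state = 0 if nxt == 0 else 1
        else:
            ops[nops] = 2
            nops += 1
            nxt = pY[i, k]
            i -= 1
            k += 1
            state = 0 if nxt == 0 else 2
    return score, ops[:nops][::-1].copy()


@dataclass(frozen=True)
class AlignedRead:
    """An end-to-end alignment of one read against the reference."""

    read_id: str
    ref_start: int
    ref_end: int
    cigar: tuple[tuple[str, int], ...]  # ops among '=', 'X', 'I', 'D'
    strand: str = "+"
    score: float = 0.0

    def consumes(self) -> tuple[int, int]:
        """(read bases, reference bases) consumed by the edit path."""
        r = sum(n for op, n in self.cigar if op in "=XI")
        g = sum(n for op, n in self.cigar if op in "=XD")
        return r, g


def _ops_to_cigar(ops: np.ndarray, read: str, ref: str) -> tuple[tuple[str, int], ...]:
    cigar: list[list] = []
    i = j = 0
    for op in ops:
        if op == 0:
            c = "=" if read[i] == ref[j] else "X"
            i += 1
            j += 1
        elif op == 1:
            c = "D"
            j += 1
        else:
            c = "I"
            i += 1
        if cigar and cigar[-1][0] == c:
            cigar[-1][1] += 1
        else:
            cigar.append([c, 1])
    return tuple((c, n) for c, n in cigar)


def align_read(
    read_seq: str,
    reference: str,
    band_width: int = 16,
    scoring: Scoring = Scoring(),
    read_id: str = "",
) -> AlignedRead:
    """Optimal banded global alignment of ``read_seq`` against ``reference``.

    ``band_width`` must be at least the largest expected net indel span; with
    the defaults the band always covers the length difference plus the band.
    Raises :class:`UnalignableReadError` below the score floor.
    """
    if not read_seq or not reference:
        raise ValueError("read and reference must be non-empty")
    if band_width < 1:
        raise ValueError("band_width must be positive")
    if read_seq == reference:  # exact-match fast path
        return AlignedRead(
            read_id, 0, len(reference), (("=", len(reference)),),
            score=scoring.match * len(reference),
        )
    score, ops = _band_align(
        encode(read_seq),
        encode(reference),
        int(band_width),
        scoring.match,
        scoring.mismatch,
        scoring.gap_open,
        scoring.gap_extend,
    )
    floor = scoring.floor_fraction * scoring.match * min(len(read_seq), len(reference))
    if score < floor:
        raise UnalignableReadError(read_id, float(score), float(floor))
    return AlignedRead(
        read_id, 0, len(reference), _ops_to_cigar(ops, read_seq, reference),
        score=float(score),
    )


def full_dp_align(
    read_seq: str, reference: str, scoring: Scoring = Scoring(), read_id: str = ""
) -> AlignedRead:
    """Unbanded global alignment (band spanning the whole DP matrix)."""
    band = len(read_seq) + len(reference) + 1
    return align_read(read_seq, reference, band, scoring, read_id)
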