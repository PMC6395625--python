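"""Reference-anchored sequence edits.

Every discrepancy between a read (or molecule) and the reference is represented
as an :class:`Edit` in reference coordinates (0-based, half-open; insertions sit
*before* the given reference base).  Indels are stored in canonical left-shifted
form so that the same physical change always has the same coordinates no matter
how it was produced (simulator, aligner, or pileup consensus).
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

BASES = "ACGT"

SUB = "substitution"
INS = "insertion"
DEL = "deletion"
KINDS = (SUB, INS, DEL)

# origin labels for simulated discrepancies
ORIGIN_TEMPLATE = "template_variant"
ORIGIN_PCR = "pcr_error"
ORIGIN_SEQ = "sequencer_error"
ORIGIN_VALIDATION = "validation_artifact"
ORIGINS = (ORIGIN_TEMPLATE, ORIGIN_PCR, ORIGIN_SEQ, ORIGIN_VALIDATION)


@dataclass(frozen=True)
class Edit:
    """A single difference vs the reference.

    pos
        0-based reference coordinate.  For a substitution/deletion it is the
        first affected base; for an insertion the inserted sequence precedes
        reference base ``pos``.
    ref / alt
        Reference and alternate alleles.  Substitutions have equal-length
        alleles, insertions an empty ``ref``, deletions an empty ``alt``.
    origin
        Ground-truth provenance label (simulated data only); ``None`` for
        edits recovered from real alignments.
    """

    pos: int
    kind: str
    ref: str
    alt: str
    origin: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown edit kind: {self.kind!r}")
        if self.kind == SUB and len(self.ref) != len(self.alt):
            raise ValueError("substitution alleles must have equal length")
        if self.kind == INS and (self.ref != "" or self.alt == ""):
            raise ValueError("insertion must have empty ref and non-empty alt")
        if self.kind == DEL and (self.alt != "" or self.ref == ""):
            raise ValueError("deletion must have empty alt and non-empty ref")
        if self.pos < 0:
            raise ValueError("negative reference position")

    @property
    def sort_key(self) -> tuple:
        # insertions before the base sort ahead of edits *on* the base
        return (self.pos, 0 if self.kind == INS else 1, self.kind, self.alt)

    def drop_origin(self) -> "Edit":
        return replace(self, origin=None)


def normalize_edit(reference: str, edit: Edit) -> Edit:
    """Left-shift an indel to its canonical position.

    A deletion or insertion inside a repeat (e.g. a homopolymer) describes the
    same alternate sequence at several offsets; the leftmost representation is
    the canonical one (same convention as left-aligned VCF normalisation).
    Substitutions are returned unchanged.
    """
    if edit.kind == SUB:
        if reference[edit.pos : edit.pos + len(edit.ref)] != edit.ref:
            raise ValueError("substitution ref allele does not match reference")
        return edit
    if edit.kind == DEL:
        pos, k = edit.pos, len(edit.ref)
        if reference[pos : pos + k] != edit.ref:
            raise ValueError("deletion ref allele does not match reference")
        while pos > 0 and reference[pos - 1] == reference[pos + k - 1]:
            pos -= 1
        return replace(edit, pos=pos, ref=reference[pos : pos + k])
    # insertion
    pos, alt = edit.pos, edit.alt
    while pos > 0 and alt[-1] == reference[pos - 1]:
        alt = reference[pos - 1] + alt[:-1]
        pos -= 1
    return replace(edit, pos=pos, alt=alt)


def apply_edits(reference: str, edits: Iterable[Edit]) -> str:
    """Materialize the sequence produced by applying ``edits`` to ``reference``.

    Edits must not overlap; positions are validated against the reference.
    """
    out: list[str] = []
    i = 0
    for e in sorted(edits, key=lambda e: e.sort_key):
        if e.pos < i:
            raise ValueError(f"overlapping edits at reference position {e.pos}")
        out.append(reference[i : e.pos])
        if e.kind == SUB:
            if reference[e.pos : e.pos + len(e.ref)] != e.ref:
                raise ValueError("edit ref allele does not match reference")
            out.append(e.alt)
            i = e.pos + len(e.ref)
        elif e.kind == DEL:
            if reference[e.pos : e.pos + len(e.ref)] != e.ref:
                raise ValueError("edit ref allele does not match reference")
            i = e.pos + len(e.ref)
        else:  # insertion
            out.append(e.alt)
            i = e.pos
    out.append(reference[i:])
    return "".join(out)


def materialize(
    reference: str, edits: Sequence[Edit], ref_quals: np.ndarray | None = None
) -> tuple[str, np.ndarray | None]:
    """Like :func:`apply_edits` but also carries per-base qualities along.

    Inserted bases inherit the quality of the reference base they precede
    (or the last base, for an end insertion); deleted bases drop theirs.
    """
    seq = apply_edits(reference, edits)
    if ref_quals is None:
        return seq, None
    quals: list[np.ndarray] = []
    i = 0
    for e in sorted(edits, key=lambda e: e.sort_key):
        quals.append(ref_quals[i : e.pos])
        if e.kind == SUB:
            quals.append(ref_quals[e.pos : e.pos + len(e.ref)])
            i = e.pos + len(e.ref)
        elif e.kind == DEL:
            i = e.pos + len(e.ref)
        else:
            anchor = min(e.pos, len(reference) - 1)
            quals.append(np.repeat(ref_quals[anchor], len(e.alt)))
            i = e.pos
    quals.append(ref_quals[i:])
    q = np.concatenate(quals).astype(np.int16)
    assert len(q) == len(seq)
    return seq, q


def homopolymer_lengths(reference: str) -> np.ndarray:
    """Length of the homopolymer run containing each reference position."""
    ref = np.frombuffer(reference.encode(), dtype=np.uint8)
    n = len(ref)
    runs = np.empty(n, dtype=np.int32)
    i = 0
    while i < n:
        j = i
        while j < n and ref[j] == ref[i]:
            j += 1
        runs[i:j] = j - i
        i = j
    return runs


def mask_to_bool(intervals: Sequence[tuple[int, int]], length: int) -> np.ndarray:
    """Convert 0-based half-open intervals to a boolean mask of ``length``."""
    m = np.zeros(length, dtype=bool)
    for s, e in intervals:
        if not (0 <= s <= e <= length):
            raise ValueError(f"interval ({s}, {e}) outside reference of length {length}")
        m[s:e] = True
    return m


def in_intervals(pos: int, intervals: Sequence[tuple[int, int]]) -> bool:
    return any(s <= pos < e for s, e in intervals)
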