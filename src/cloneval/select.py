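"""Selecting erroneous reads and indexing them to chip coordinates.

After alignment, every per-read difference against the design sequence becomes
a :class:`VariantCall`; reads carrying calls (all of them, or only those at
positions of interest) are the clones to retrieve and validate.  Calls inside
primer intervals are retained but flagged ``in_primer`` so that error-rate
denominators can exclude synthesis errors while whole-run counts keep them.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _st

from .alignment import AlignedRead, Scoring, UnalignableReadError, align_read
from .edits import DEL, INS, SUB, Edit, in_intervals, normalize_edit


@dataclass
class Read:
    """A sequencing read with per-base Phred qualities and an optional
    pointer to its DNA cluster on the chip."""

    read_id: str
    sequence: str
    quals: np.ndarray
    cluster_ref: str | None = None

    def __post_init__(self) -> None:
        self.quals = np.asarray(self.quals, dtype=np.int16)
        if len(self.quals) != len(self.sequence):
            raise ValueError(
                f"read {self.read_id!r}: {len(self.quals)} qualities for "
                f"{len(self.sequence)} bases"
            )

    @property
    def mean_q(self) -> float:
        return float(self.quals.mean())


@dataclass(frozen=True)
class VariantCall:
    """A read-level difference vs the reference (0-based, left-normalized)."""

    read_id: str
    pos: int
    kind: str
    ref: str
    alt: str
    in_primer: bool = False

    @property
    def n_bases(self) -> int:
        """Bases attributed to this call (substituted, inserted or deleted)."""
        return max(len(self.ref), len(self.alt))

    def allele_key(self) -> tuple:
        return (self.pos, self.kind, self.alt)


def calls_from_cigar(
    cigar: Sequence[tuple[str, int]], read_seq: str, reference: str
) -> list[Edit]:
    """Convert an edit path into left-normalized :class:`Edit` objects,
    merging runs of gap columns into single indel events."""
    edits: list[Edit] = []
    i = j = 0
    for op, n in cigar:
        if op == "=":
            i += n
            j += n
        elif op == "X":
            for t in range(n):  # one call per substituted base
                edits.append(Edit(j + t, SUB, reference[j + t], read_seq[i + t]))
            i += n
            j += n
        elif op == "D":
            edits.append(
                normalize_edit(reference, Edit(j, DEL, reference[j : j + n], ""))
            )
            j += n
        elif op == "I":
            edits.append(
                normalize_edit(reference, Edit(j, INS, "", read_seq[i : i + n]))
            )
            i += n
        else:
            raise ValueError(f"unsupported CIGAR op {op!r}")
    if i != len(read_seq) or j != len(reference):
        raise ValueError("edit path does not consume read and reference exactly")
    return sorted(edits, key=lambda e: e.sort_key)


def call_read_variants(
    aligned: AlignedRead,
    read_seq: str,
    reference: str,
    primer_mask: Sequence[tuple[int, int]] = (),
) -> list[VariantCall]:
    """One :class:`VariantCall` per difference in the edit path."""
    edits = calls_from_cigar(aligned.cigar, read_seq, reference)
    return [
        VariantCall(
            aligned.read_id, e.pos, e.kind, e.ref, e.alt,
            in_primer=in_intervals(e.pos, primer_mask),
        )
        for e in edits
    ]


def align_and_call(
    reads: Iterable[Read],
    reference: str,
    primer_mask: Sequence[tuple[int, int]] = (),
    band_width: int = 16,
    scoring: Scoring = Scoring(),
) -> tuple[list[VariantCall], dict[str, AlignedRead], list[tuple[str, str]]]:
    """Align a batch of reads and call their variants.

    Returns ``(calls, alignments, excluded)`` where ``excluded`` lists
    ``(read_id, reason)`` for unalignable reads.
    """
    calls: list[VariantCall] = []
    alignments: dict[str, AlignedRead] = {}
    excluded: list[tuple[str, str]] = []
    for read in reads:
        try:
            aln = align_read(read.sequence, reference, band_width, scoring, read.read_id)
        except UnalignableReadError as err:
            excluded.append((read.read_id, str(err)))
            continue
        alignments[read.read_id] = aln
        calls.extend(call_read_variants(aln, read.sequence, reference, primer_mask))
    return calls, alignments, excluded


ALL_VARIANT_READS = "all_variant_reads"
POSITIONAL = "positional"


def select_targets(
    calls: Iterable[VariantCall],
    mode: str = ALL_VARIANT_READS,
    positions: Sequence[int] | None = None,
) -> list[str]:
    """Read ids to retrieve, in deterministic (lexicographic) order.

    ``all_variant_reads`` selects every read with at least one call;
    ``positional`` only reads with a call at one of ``positions``.
    """
    if mode not in (ALL_VARIANT_READS, POSITIONAL):
        raise ValueError(f"unknown selection mode {mode!r}")
    if mode == POSITIONAL:
        if not positions:
            raise ValueError("positional selection requires a non-empty position list")
        wanted = set(positions)
        ids = {c.read_id for c in calls if c.pos in wanted}
    else:
        ids = {c.read_id for c in calls}
    return sorted(ids)


@dataclass
class CoordinateIndex:
    """Hash table from read id to chip pixel coordinates (and, once a
    retrieval plan exists, the assigned well)."""

    entries: dict[str, tuple[float, float]] = field(default_factory=dict)
    wells: dict[str, tuple[str, str]] = field(default_factory=dict)  # id -> (plate, well)

    def __len__(self) -> int:
        return len(self.entries)

    def lookup(self, read_id: str) -> tuple[float, float]:
        return self.entries[read_id]

    def pixel_array(self) -> tuple[list[str], np.ndarray]:
        ids = list(self.entries)
        return ids, np.array([self.entries[i] for i in ids], dtype=float)


def build_coordinate_index(
    selected_ids: Sequence[str],
    layout_table: "pd.DataFrame | Mapping[str, tuple[float, float]]",
) -> CoordinateIndex:
    """Index the selected reads into chip pixel space.

    ``layout_table`` is either a mapping ``read_id -> (pixel_x, pixel_y)`` or a
    DataFrame with columns ``read_id, pixel_x, pixel_y``.  Missing ids raise a
    KeyError naming them; duplicate table ids are rejected.
    """
    if isinstance(layout_table, pd.DataFrame):
        if layout_table["read_id"].duplicated().any():
            dupes = layout_table["read_id"][layout_table["read_id"].duplicated()]
            raise ValueError(f"duplicate read ids in layout table: {sorted(set(dupes))}")
        table = {
            r.read_id: (float(r.pixel_x), float(r.pixel_y))
            for r in layout_table.itertuples()
        }
    else:
        table = dict(layout_table)
    missing = [i for i in selected_ids if i not in table]
    if missing:
        raise KeyError(f"read ids absent from layout table: {missing}")
    if len(set(selected_ids)) != len(selected_ids):
        raise ValueError("duplicate ids in selection")
    return CoordinateIndex({i: table[i] for i in selected_ids})


def sample_size(
    population_n: float,
    confidence: float = 0.95,
    margin: float = 0.03,
    p0: float = 0.5,
) -> int:
    """Required validation sample size, normal approximation with
    finite-population correction.

    ``n0 = z^2 p0 (1 - p0) / margin^2``; ``n = n0 / (1 + (n0 - 1) / N)``,
    rounded up.  Pass ``population_n=math.inf`` for the uncorrected size.
    """
    if population_n < 1:
        raise ValueError("population_n must be >= 1")
    if not 0 < margin < 1:
        raise ValueError("margin must be in (0, 1)")
    z = _st.norm.ppf(1 - (1 - confidence) / 2)
    n0 = z * z * p0 * (1 - p0) / (margin * margin)
    if math.isinf(population_n):
        n = n0
    else:
        n = n0 / (1 + (n0 - 1) / population_n)
    return int(math.ceil(n - 1e-9))
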