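"""Turning per-clone validation pileups into verdicts.

A retrieved DNA clone is re-sequenced independently; only bases physically
present in the molecule replicate, so a sequencer miscall in the original run
shows up as a clean reference consensus, while a true variant is supported by
(nearly) all validation reads.  Each originally flagged variant is classified
against its clone's pileup:

``true_variant``
    the flagged alternate allele reaches the consensus threshold;
``artifact``
    the reference state reaches the threshold (the molecule never carried the
    variant - the original call was a sequencer miscall);
``validation_artifact``
    a third allele reaches the threshold (the molecule was damaged, degraded
    or PCR-mutated during the validation process itself);
``indeterminate``
    low depth or a mixed pileup; never silently counted either way.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .edits import DEL, INS, SUB, Edit
from .select import VariantCall

ALLELES = "ACGT-"  # '-' is the deletion (gap) allele
_AIDX = {b: i for i, b in enumerate(ALLELES)}

ARTIFACT = "artifact"
TRUE_VARIANT = "true_variant"
VALIDATION_ARTIFACT = "validation_artifact"
INDETERMINATE = "indeterminate"
CATEGORIES = (ARTIFACT, TRUE_VARIANT, VALIDATION_ARTIFACT, INDETERMINATE)


@dataclass
class ValidationPileup:
    """Per-position allele counts from re-sequencing one clone.

    ``base_counts`` has one row per reference position and one column per
    allele in ``ACGT-``; insertion alleles are keyed separately by
    ``(position, inserted sequence)`` because they live between reference
    positions.
    """

    clone_id: str
    reference: str
    base_counts: np.ndarray  # (L, 5) int
    ins_counts: dict[tuple[int, str], int] = field(default_factory=dict)
    damage_edits: tuple[Edit, ...] = ()

    def __post_init__(self) -> None:
        self.base_counts = np.asarray(self.base_counts, dtype=np.int64)
        if self.base_counts.shape != (len(self.reference), 5):
            raise ValueError("base_counts must be (reference length, 5)")
        if (self.base_counts < 0).any() or any(v < 0 for v in self.ins_counts.values()):
            raise ValueError("negative allele counts")

    @property
    def depth(self) -> np.ndarray:
        return self.base_counts.sum(axis=1)

    @property
    def mean_depth(self) -> float:
        return float(self.depth.mean())

    def span(self) -> int:
        return len(self.reference)


def consensus_call(
    pileup: ValidationPileup, position: int, min_depth_fraction: float = 0.02
) -> tuple[str, float, bool]:
    """Majority allele at ``position`` with its supporting fraction.

    Positions whose depth is at or below ``min_depth_fraction`` of the clone's
    mean depth are unusable (the low-coverage exclusion applied to validation
    sequencing results).  Ties break to the lexicographically first allele in
    ``ACGT-``.
    """
    if not 0 <= position < pileup.span():
        raise IndexError(f"position {position} outside pileup span")
    depth = int(pileup.depth[position])
    if depth == 0 or depth <= min_depth_fraction * pileup.mean_depth:
        return ("", 0.0, False)
    counts = pileup.base_counts[position]
    best = int(np.argmax(counts))  # argmax takes the first maximum: ACGT- order
    return (ALLELES[best], float(counts[best]) / depth, True)


def _allele_fractions(pileup: ValidationPileup, position: int) -> tuple[np.ndarray, int]:
    depth = int(pileup.depth[position])
    return pileup.base_counts[position] / max(depth, 1), depth


@dataclass(frozen=True)
class Verdict:
    variant: VariantCall
    category: str
    consensus_fraction: float  # support for the flagged allele
    usable: bool = True


def classify_variant(
    variant: VariantCall,
    pileup: ValidationPileup,
    consensus_threshold: float = 0.80,
    min_depth_fraction: float = 0.02,
) -> Verdict:
    """Classify one flagged variant against its clone's validation pileup."""
    if not 0.80 <= consensus_threshold <= 0.95:
        raise ValueError("consensus_threshold must lie in [0.80, 0.95]")
    pos = variant.pos
    if variant.kind == INS:
        pos = min(pos, pileup.span() - 1)
    if not 0 <= pos < pileup.span():
        raise IndexError(f"variant position {variant.pos} outside pileup span")

    _, _, usable = consensus_call(pileup, pos, min_depth_fraction)
    depth = int(pileup.depth[pos])
    if not usable:
        return Verdict(variant, INDETERMINATE, 0.0, usable=False)

    if variant.kind == INS:
        ins_here = {
            alt: n for (p, alt), n in pileup.ins_counts.items() if p == variant.pos
        }
        alt_frac = ins_here.get(variant.alt, 0) / depth
        none_frac = max(0.0, 1.0 - sum(ins_here.values()) / depth)
        other_frac = max(
            (n / depth for alt, n in ins_here.items() if alt != variant.alt),
            default=0.0,
        )
    else:
        frac, depth = _allele_fractions(pileup, pos)
        alt_allele = "-" if variant.kind == DEL else variant.alt
        ref_allele = variant.ref[0]
        alt_frac = float(frac[_AIDX[alt_allele]])
        none_frac = float(frac[_AIDX[ref_allele]])
        other_frac = max(
            (float(frac[_AIDX[a]]) for a in ALLELES if a not in (alt_allele, ref_allele)),
            default=0.0,
        )

    if alt_frac >= consensus_threshold:
        return Verdict(variant, TRUE_VARIANT, alt_frac)
    if none_frac >= consensus_threshold:
        return Verdict(variant, ARTIFACT, alt_frac)
    if other_frac >= consensus_threshold:
        return Verdict(variant, VALIDATION_ARTIFACT, alt_frac)
    return Verdict(variant, INDETERMINATE, alt_frac)


@dataclass
class ValidationSummary:
    counts: dict[str, int]
    counts_by_kind: dict[str, dict[str, int]]
    total: int
    decided: int

    @property
    def artifact_fraction(self) -> float:
        if self.decided == 0:
            return float("nan")
        return (self.counts[ARTIFACT] + self.counts[VALIDATION_ARTIFACT]) / self.decided

    @property
    def true_fraction(self) -> float:
        if self.decided == 0:
            return float("nan")
        return self.counts[TRUE_VARIANT] / self.decided

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"kind": kind, **{c: by.get(c, 0) for c in CATEGORIES}}
            for kind, by in sorted(self.counts_by_kind.items())
        ]
        rows.append({"kind": "all", **self.counts})
        return pd.DataFrame(rows).set_index("kind")


def summarize_validation(verdicts: Sequence[Verdict]) -> ValidationSummary:
    """Counts and fractions by category and by variant kind.

    Fractions are over *decided* verdicts (everything but indeterminate).
    """
    if not verdicts:
        raise ValueError("no verdicts to summarize")
    counts = Counter(v.category for v in verdicts)
    by_kind: dict[str, Counter] = {}
    for v in verdicts:
        by_kind.setdefault(v.variant.kind, Counter())[v.category] += 1
    decided = sum(n for c, n in counts.items() if c != INDETERMINATE)
    return ValidationSummary(
        counts={c: counts.get(c, 0) for c in CATEGORIES},
        counts_by_kind={k: {c: n for c, n in v.items()} for k, v in by_kind.items()},
        total=len(verdicts),
        decided=decided,
    )


def recompute_vf(
    calls: Sequence[VariantCall],
    coverage: "int | Mapping[int, int]",
    verdicts: Sequence[Verdict],
    indeterminate: str = "drop",
) -> pd.DataFrame:
    """Variant-frequency table before and after validation.

    ``vf_before`` counts every original alternate call; ``vf_after`` keeps only
    calls whose verdict is ``true_variant``.  Calls classified as artifact or
    validation artifact are removed; indeterminate calls are removed too by
    default (``indeterminate='drop'``) but stay countable in their own column,
    or kept with ``indeterminate='keep'``.
    """
    if indeterminate not in ("drop", "keep"):
        raise ValueError("indeterminate must be 'drop' or 'keep'")
    verdict_of = {
        (v.variant.read_id, v.variant.allele_key()): v.category for v in verdicts
    }

    def cov(pos: int) -> int:
        c = coverage if isinstance(coverage, (int, np.integer)) else coverage[pos]
        if c <= 0:
            raise ValueError(f"non-positive coverage at position {pos}")
        return int(c)

    rows: dict[tuple, dict] = {}
    for c in calls:
        key = c.allele_key()
        row = rows.setdefault(
            key,
            {
                "pos": c.pos, "kind": c.kind, "ref": c.ref, "alt": c.alt,
                "n_before": 0, "n_true": 0, "n_artifact": 0,
                "n_validation_artifact": 0, "n_indeterminate": 0,
                "n_unvalidated": 0,
            },
        )
        row["n_before"] += 1
        cat = verdict_of.get((c.read_id, key))
        if cat is None:
            row["n_unvalidated"] += 1
        elif cat == TRUE_VARIANT:
            row["n_true"] += 1
        elif cat == ARTIFACT:
            row["n_artifact"] += 1
        elif cat == VALIDATION_ARTIFACT:
            row["n_validation_artifact"] += 1
        else:
            row["n_indeterminate"] += 1
    records = []
    for key in sorted(rows):
        row = rows[key]
        n_after = row["n_true"]
        if indeterminate == "keep":
            n_after += row["n_indeterminate"]
        row["vf_before"] = row["n_before"] / cov(row["pos"])
        row["vf_after"] = n_after / cov(row["pos"])
        records.append(row)
    df = pd.DataFrame(
        records,
        columns=[
            "pos", "kind", "ref", "alt", "n_before", "n_true", "n_artifact",
            "n_validation_artifact", "n_indeterminate", "n_unvalidated",
            "vf_before", "vf_after",
        ],
    )
    assert (df["vf_after"] <= df["vf_before"] + 1e-12).all()
    return df


def pileup_from_tsv(path, reference: str, clone_id: str = "") -> ValidationPileup:
    """Load a per-position count matrix (columns ``pos0, A, C, G, T, gap``).

    Insertion-allele counts cannot be represented in the flat matrix; pileups
    carrying insertion consensus must come from SAM ingestion or simulation.
    """
    df = pd.read_csv(str(path), sep="\t")
    counts = np.zeros((len(reference), 5), dtype=np.int64)
    for r in df.itertuples():
        counts[int(r.pos0)] = [r.A, r.C, r.G, r.T, r.gap]
    return ValidationPileup(clone_id, reference, counts)


def pileup_to_tsv(pileup: ValidationPileup, path) -> None:
    df = pd.DataFrame(pileup.base_counts, columns=["A", "C", "G", "T", "gap"])
    df.insert(0, "pos0", np.arange(pileup.span()))
    df.to_csv(path, sep="\t", index=False)


def pileup_from_sam(path, reference: str, clone_id: str = "") -> ValidationPileup:
    """Build a validation pileup from the clone's re-sequencing reads in SAM.

    Counts are accumulated by walking each record's edit path against the
    reference; insertion alleles are keyed by (position, inserted sequence).
    """
    from .io import read_sam_alignments

    counts = np.zeros((len(reference), 5), dtype=np.int64)
    ins_counts: dict[tuple[int, str], int] = {}
    for read, aln in read_sam_alignments(path, reference):
        i, j = 0, aln.ref_start
        for op, n in aln.cigar:
            if op in "=X":
                for t in range(n):
                    counts[j + t, _AIDX[read.sequence[i + t]]] += 1
                i += n
                j += n
            elif op == "D":
                counts[j : j + n, _AIDX["-"]] += 1
                j += n
            elif op == "I":
                key = (j, read.sequence[i : i + n])
                ins_counts[key] = ins_counts.get(key, 0) + 1
                i += n
    return ValidationPileup(clone_id, reference, counts, ins_counts)


def clone_consensus_variants(
    pileup: ValidationPileup,
    consensus_threshold: float = 0.80,
    min_depth_fraction: float = 0.02,
) -> list[Edit]:
    """All positions where the clone's consensus differs from the reference.

    Used to confirm that clones of error-free reads really carry no variants,
    and to spot damage acquired during validation.
    """
    out: list[Edit] = []
    for pos in range(pileup.span()):
        allele, frac, usable = consensus_call(pileup, pos, min_depth_fraction)
        if not usable or frac < consensus_threshold:
            continue
        ref = pileup.reference[pos]
        if allele == ref:
            continue
        if allele == "-":
            out.append(Edit(pos, DEL, ref, ""))
        else:
            out.append(Edit(pos, SUB, ref, allele))
    depth = pileup.mean_depth
    for (pos, alt), n in sorted(pileup.ins_counts.items()):
        d = pileup.depth[min(pos, pileup.span() - 1)]
        if d > 0 and d > min_depth_fraction * depth and n / d >= consensus_threshold:
            out.append(Edit(pos, INS, "", alt))
    return sorted(out, key=lambda e: e.sort_key)
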