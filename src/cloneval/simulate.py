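"""Ground-truth-labelled synthetic data for the whole validation workflow.

The generator emulates the physical experiment end to end: a short amplicon
(261 bp with two 20 bp primer regions, so 221 assayable bases), optional
spike-in templates mixed at designed fractions, PCR error accumulation over a
configurable number of doubling events, pyrosequencing-style reads whose error
rate rises along the read and at homopolymers, a chip layout with overlapping
camera frames, and per-clone validation re-reads.  Every non-reference base in
every emitted read carries exactly one origin label (template variant, PCR
error, or sequencer error), so downstream classification can be scored
exactly.

To keep that single-origin bookkeeping exact, error processes never stack on
one site: edits on the same read are kept at least 5 reference bases apart and
indels are stored left-normalized.  At the rates simulated here (<=1% per
base) multi-hit sites are a ~1e-4 per-read event, so this simplification is
far below the statistical resolution of any analysis built on top.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .edits import (
    BASES,
    DEL,
    INS,
    ORIGIN_PCR,
    ORIGIN_SEQ,
    ORIGIN_TEMPLATE,
    ORIGIN_VALIDATION,
    SUB,
    Edit,
    apply_edits,
    homopolymer_lengths,
    mask_to_bool,
    materialize,
    normalize_edit,
)
from .registration import SimilarityTransform
from .select import Read
from .validation import ALLELES, ValidationPileup

#: minimum separation (reference bases) between edits on one read
EDIT_GUARD = 4


def default_reference(
    length: int = 261,
    primer_len: int = 20,
    homopolymer_at: Sequence[int] = (172, 190),
    seed: int = 20190228,
) -> tuple[str, tuple[tuple[int, int], ...]]:
    """A deterministic synthetic amplicon with planted 'GGG' homopolymers.

    The default geometry mirrors the study system: 261 bases, 20 bp primers at
    either end (masked from error accounting, leaving 221 assayable bases) and
    G homopolymers around the 173rd and 191st base where pyrosequencing indels
    cluster.
    """
    rng = np.random.default_rng(seed)
    seq: list[str] = []
    for _ in range(length):
        choices = [b for b in BASES if not (len(seq) >= 2 and seq[-1] == seq[-2] == b)]
        seq.append(choices[rng.integers(len(choices))])
    for start in homopolymer_at:
        for k in range(start, start + 3):
            seq[k] = "G"
        for flank in (start - 1, start + 3):
            if 0 <= flank < length and seq[flank] == "G":
                seq[flank] = "A" if flank % 2 else "T"
    primer_mask = ((0, primer_len), (length - primer_len, length))
    return "".join(seq), primer_mask


DEFAULT_REFERENCE, DEFAULT_PRIMER_MASK = default_reference()


# ---------------------------------------------------------------------------
# templates


@dataclass(frozen=True)
class Template:
    label: str
    edits: tuple[Edit, ...]
    fraction: float


@dataclass(frozen=True)
class TemplateSet:
    """Reference plus the designed template mixture (a spike-in ladder)."""

    reference: str
    templates: tuple[Template, ...]
    primer_mask: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        total = sum(t.fraction for t in self.templates)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"template fractions sum to {total}, expected 1")
        mask_to_bool(self.primer_mask, len(self.reference))  # bounds check
        for t in self.templates:
            apply_edits(self.reference, t.edits)  # validates end-to-end fit

    def fractions(self) -> np.ndarray:
        return np.array([t.fraction for t in self.templates])

    def sequence(self, idx: int) -> str:
        return apply_edits(self.reference, self.templates[idx].edits)

    def nonprimer_positions(self) -> np.ndarray:
        masked = mask_to_bool(self.primer_mask, len(self.reference))
        return np.where(~masked)[0]


def _as_edit(reference: str, spec) -> Edit:
    if isinstance(spec, Edit):
        e = spec
    else:
        pos, kind, ref, alt = spec
        e = Edit(pos, kind, ref, alt)
    e = normalize_edit(reference, replace(e, origin=ORIGIN_TEMPLATE))
    return e


def make_spikein_templates(
    reference: str,
    variant_specs: Sequence,
    fractions: Sequence[float],
    labels: Sequence[str] | None = None,
    primer_mask: Sequence[tuple[int, int]] = (),
) -> TemplateSet:
    """Build a spike-in template mixture.

    ``variant_specs[i]`` describes template i: ``None`` for the wild type, a
    single ``(pos, kind, ref, alt)`` tuple / :class:`Edit`, or a list of them.
    Designed variants must sit at distinct reference positions across all
    templates - otherwise reads cannot be attributed to one template and the
    mixture is rejected.  Fractions are normalized to sum to 1.
    """
    if len(variant_specs) != len(fractions):
        raise ValueError("variant_specs and fractions must have equal length")
    fr = np.asarray(fractions, dtype=float)
    if (fr <= 0).any():
        raise ValueError("fractions must be positive")
    fr = fr / fr.sum()
    templates = []
    seen: set[int] = set()
    for i, spec in enumerate(variant_specs):
        if spec is None:
            edits: tuple[Edit, ...] = ()
        elif isinstance(spec, (tuple, Edit)) and not (
            isinstance(spec, tuple) and spec and isinstance(spec[0], (tuple, Edit))
        ):
            edits = (_as_edit(reference, spec),)
        else:
            edits = tuple(_as_edit(reference, s) for s in spec)
        for e in edits:
            if e.pos in seen:
                raise ValueError(
                    f"variant position {e.pos} appears in more than one template; "
                    "spike-in variants must be distinguishable"
                )
            seen.add(e.pos)
        label = labels[i] if labels else (f"template_{i}" if edits else "wild_type")
        templates.append(Template(label, edits, float(fr[i])))
    return TemplateSet(reference, tuple(templates), tuple(tuple(x) for x in primer_mask))


# ---------------------------------------------------------------------------
# PCR

POISSON_APPROX = "poisson_approx"
LINEAGE_TREE = "lineage_tree"


@dataclass(frozen=True)
class PcrModel:
    """Error accumulation over ``doublings`` effective population doublings.

    ``poisson_approx`` treats each sampled lineage as ``doublings``
    independent replication opportunities (expected mutations per base =
    rate x doublings); ``lineage_tree`` simulates the replication tree
    explicitly for small doubling counts, capturing jackpot clustering.
    """

    doublings: float
    sub_rate: float
    indel_rate: float = 0.0
    mode: str = POISSON_APPROX

    def __post_init__(self) -> None:
        if self.doublings <= 0:
            raise ValueError("doublings must be positive")
        for r in (self.sub_rate, self.indel_rate):
            if not 0 <= r <= 1e-2:
                raise ValueError("per-doubling rates must lie in [0, 1e-2]")
        if self.mode not in (POISSON_APPROX, LINEAGE_TREE):
            raise ValueError(f"unknown PCR mode {self.mode!r}")

    @property
    def total_rate(self) -> float:
        return self.sub_rate + self.indel_rate


@dataclass
class MoleculePool:
    """Molecules sampled from the post-PCR library, with their mutations."""

    templates: TemplateSet
    template_idx: np.ndarray  # (n,) template index per molecule
    extra_edits: dict[int, tuple[Edit, ...]] = field(default_factory=dict)
    composition: str = "multinomial"

    def __len__(self) -> int:
        return len(self.template_idx)

    def molecule_edits(self, i: int) -> tuple[Edit, ...]:
        base = self.templates.templates[int(self.template_idx[i])].edits
        extra = self.extra_edits.get(int(i), ())
        return tuple(sorted(base + extra, key=lambda e: e.sort_key))

    def molecule_sequence(self, i: int) -> str:
        return apply_edits(self.templates.reference, self.molecule_edits(i))

    def indices_for_template(self, t: int) -> np.ndarray:
        return np.where(self.template_idx == t)[0]


def _template_counts(rng, fractions: np.ndarray, n: int, composition: str) -> np.ndarray:
    if composition == "multinomial":
        return rng.multinomial(n, fractions)
    if composition == "expected":
        # largest-remainder rounding: the mixture contains exactly the
        # expected number of molecules of each template (a pipetted spike-in)
        raw = fractions * n
        base = np.floor(raw).astype(int)
        rem = n - base.sum()
        order = np.argsort(-(raw - base))
        base[order[:rem]] += 1
        return base
    raise ValueError(f"unknown composition mode {composition!r}")


def _draw_edit(
    rng,
    reference: str,
    cdf: np.ndarray,
    positions: np.ndarray,
    sub_frac_at,
    hp_runs: np.ndarray,
    taken: list[int],
    origin: str,
    hp_duplication: bool,
) -> Edit | None:
    """One error edit at a weighted random position, canonicalized and kept
    clear of already-edited sites.  Returns None if no free site was found."""
    for _ in range(50):
        pos = int(positions[int(np.searchsorted(cdf, rng.random(), side="right"))])
        ref_base = reference[pos]
        if rng.random() < sub_frac_at(pos):
            others = [b for b in BASES if b != ref_base]
            e = Edit(pos, SUB, ref_base, others[rng.integers(3)], origin)
        elif rng.random() < 0.5:
            if hp_duplication and hp_runs[pos] >= 3:
                ins = ref_base  # pyrosequencing over-call duplicates the run base
            else:
                ins = BASES[rng.integers(4)]
            e = normalize_edit(reference, Edit(pos, INS, "", ins, origin))
        else:
            e = normalize_edit(reference, Edit(pos, DEL, ref_base, "", origin))
        if all(abs(e.pos - t) > EDIT_GUARD for t in taken):
            taken.append(e.pos)
            return e
    return None


def simulate_pcr(
    templates: TemplateSet,
    model: PcrModel,
    n_molecules: int,
    seed: int,
    composition: str = "multinomial",
    n_initial: int = 1,
) -> MoleculePool:
    """Sample ``n_molecules`` from the post-PCR library.

    In ``poisson_approx`` mode each molecule carries
    ``K ~ Poisson(L_eff * total_rate * doublings)`` mutations at uniformly
    random non-primer positions.  ``lineage_tree`` mode grows an explicit
    replication tree from ``n_initial`` founder molecules (each doubling every
    daughter adds ``Binomial(L_eff, rate)`` fresh mutations on its newly
    synthesized strand) and samples the final population.
    """
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    rng = np.random.default_rng(seed)
    ref = templates.reference
    hp_runs = homopolymer_lengths(ref)
    nonprimer = templates.nonprimer_positions()
    counts = _template_counts(rng, templates.fractions(), n_molecules, composition)
    template_idx = np.repeat(np.arange(len(counts)), counts)
    template_idx = rng.permutation(template_idx)
    pool = MoleculePool(templates, template_idx, composition=composition)
    if model.total_rate == 0:
        return pool

    sub_frac = model.sub_rate / model.total_rate

    def candidates_for(t: int) -> tuple[np.ndarray, np.ndarray]:
        tpos = [e.pos for e in templates.templates[t].edits]
        ok = np.array(
            [all(abs(p - q) > EDIT_GUARD for q in tpos) for p in nonprimer], dtype=bool
        )
        pos = nonprimer[ok]
        cdf = np.arange(1, len(pos) + 1) / len(pos)
        return pos, cdf

    cand = {t: candidates_for(t) for t in range(len(templates.templates))}

    if model.mode == POISSON_APPROX:
        lam = np.array(
            [
                len(cand[int(t)][0]) * model.total_rate * model.doublings
                for t in template_idx
            ]
        )
        n_mut = rng.poisson(lam)
        for i in np.nonzero(n_mut)[0]:
            t = int(template_idx[i])
            pos, cdf = cand[t]
            taken = [e.pos for e in templates.templates[t].edits]
            edits = []
            for _ in range(n_mut[i]):
                e = _draw_edit(
                    rng, ref, cdf, pos, lambda _: sub_frac, hp_runs, taken,
                    ORIGIN_PCR, hp_duplication=False,
                )
                if e is not None:
                    edits.append(e)
            if edits:
                pool.extra_edits[int(i)] = tuple(sorted(edits, key=lambda e: e.sort_key))
        return pool

    # lineage_tree
    d = int(round(model.doublings))
    if abs(d - model.doublings) > 1e-9 or d < 1:
        raise ValueError("lineage_tree mode requires a positive integer doubling count")
    if n_initial * (2 ** d) > 2 ** 20:
        raise ValueError(
            "lineage tree too large; use poisson_approx for many doublings"
        )
    founders = rng.choice(
        len(templates.templates), size=n_initial, p=templates.fractions()
    )
    population: list[tuple[int, tuple[Edit, ...]]] = [(int(t), ()) for t in founders]
    for _ in range(d):
        next_pop: list[tuple[int, tuple[Edit, ...]]] = []
        for t, inherited in population:
            pos, cdf = cand[t]
            for _daughter in range(2):
                k = rng.binomial(len(pos), model.total_rate)
                taken = [e.pos for e in templates.templates[t].edits] + [
                    e.pos for e in inherited
                ]
                new = list(inherited)
                for _ in range(k):
                    e = _draw_edit(
                        rng, ref, cdf, pos, lambda _: sub_frac, hp_runs, taken,
                        ORIGIN_PCR, hp_duplication=False,
                    )
                    if e is not None:
                        new.append(e)
                next_pop.append((t, tuple(sorted(new, key=lambda e: e.sort_key))))
        population = next_pop
    picks = rng.integers(0, len(population), n_molecules)
    template_idx = np.array([population[p][0] for p in picks])
    pool = MoleculePool(templates, template_idx, composition=composition)
    for i, p in enumerate(picks):
        edits = population[int(p)][1]
        if edits:
            pool.extra_edits[i] = edits
    return pool


# ---------------------------------------------------------------------------
# sequencer error model


@dataclass
class SeqErrorModel:
    """Aggregate per-base error rates with positional and homopolymer structure.

    ``base_sub_rate`` is the run-average substitution probability per base;
    ``indel_rate_by_homopolymer`` maps the length of the homopolymer run a
    base sits in to its per-base indel probability (longest listed run length
    applies to anything longer).  ``positional_gain`` is a non-decreasing
    multiplier along the read (normalized internally to mean 1, so the
    aggregates stay calibrated).  Phred scores are emitted from the realized
    per-base error probability, Q = -10 log10 P, integer-rounded and clipped
    to [2, 41], with optional Gaussian jitter; ``read_rate_sigma`` spreads a
    lognormal per-read error multiplier (mean 1), which is what makes read
    mean quality informative about read accuracy.
    """

    base_sub_rate: float = 0.00148
    indel_rate_by_homopolymer: dict = field(
        default_factory=lambda: {1: 0.00147, 2: 0.00147, 3: 0.0147, 4: 0.0294}
    )
    positional_gain: tuple[float, float] = (0.5, 1.5)  # linear start -> end
    q_jitter_sd: float = 0.0
    read_rate_sigma: float = 0.0
    hp_duplication: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.base_sub_rate <= 1:
            raise ValueError("base_sub_rate must be a probability")
        for v in self.indel_rate_by_homopolymer.values():
            if not 0 <= v <= 1:
                raise ValueError("homopolymer indel rates must be probabilities")
        lo, hi = self.positional_gain
        if lo < 0 or hi < lo:
            raise ValueError("positional_gain must be non-negative and non-decreasing")

    @classmethod
    def flat(cls, sub_rate: float, indel_rate: float = 0.0, **kw) -> "SeqErrorModel":
        """A model with no positional or homopolymer structure."""
        return cls(
            base_sub_rate=sub_rate,
            indel_rate_by_homopolymer={1: indel_rate},
            positional_gain=(1.0, 1.0),
            **kw,
        )

    @classmethod
    def from_aggregate(
        cls,
        reference: str,
        sub_rate: float,
        indel_rate: float,
        hp_multipliers: dict | None = None,
        positional_gain: tuple[float, float] = (0.5, 1.5),
        **kw,
    ) -> "SeqErrorModel":
        """Calibrate the homopolymer table so the run-average indel rate over
        ``reference`` equals ``indel_rate`` while keeping the requested
        relative multipliers between run lengths."""
        mult = dict(hp_multipliers or {1: 1.0, 2: 1.0, 3: 10.0, 4: 20.0})
        runs = homopolymer_lengths(reference)
        per_pos = np.array([_lookup(mult, int(r)) for r in runs])
        scale = indel_rate / per_pos.mean() if per_pos.mean() > 0 else 0.0
        table = {k: v * scale for k, v in mult.items()}
        return cls(
            base_sub_rate=sub_rate,
            indel_rate_by_homopolymer=table,
            positional_gain=positional_gain,
            **kw,
        )

    def gain(self, length: int) -> np.ndarray:
        lo, hi = self.positional_gain
        g = np.linspace(lo, hi, length)
        return g / g.mean()

    def position_rates(self, reference: str) -> tuple[np.ndarray, np.ndarray]:
        """(substitution, indel) probability per reference position."""
        runs = homopolymer_lengths(reference)
        gain = self.gain(len(reference))
        sub_p = self.base_sub_rate * gain
        indel_p = np.array(
            [_lookup(self.indel_rate_by_homopolymer, int(r)) for r in runs]
        ) * gain
        return sub_p, np.clip(indel_p, 0, 1)

    def aggregate_rate(self, reference: str) -> float:
        sub_p, indel_p = self.position_rates(reference)
        return float((sub_p + indel_p).mean())

    def q_from_p(self, p: np.ndarray, rng=None) -> np.ndarray:
        p = np.clip(np.asarray(p, dtype=float), 10 ** -4.15, 1.0)
        q = -10.0 * np.log10(p)
        if self.q_jitter_sd > 0:
            if rng is None:
                raise ValueError("q jitter requires an RNG")
            q = q + rng.normal(0.0, self.q_jitter_sd, size=q.shape)
        return np.clip(np.rint(q), 2, 41).astype(np.int16)


def _lookup(table: dict, run_len: int) -> float:
    if run_len in table:
        return table[run_len]
    keys = sorted(table)
    for k in reversed(keys):
        if run_len >= k:
            return table[k]
    return table[keys[0]]


# ---------------------------------------------------------------------------
# chip layout


@dataclass
class ChipLayoutConfig:
    frame_grid: tuple[int, int] = (1, 1)  # rows, cols
    frame_size: tuple[int, int] = (512, 512)  # height, width in px
    overlap: float = 48.0  # px shared between adjacent frames
    offset_jitter: float = 1.5  # px of (fractional) error on nominal offsets
    min_separation: float = 6.0  # px between cluster centers
    spot_sigma: float = 1.4  # px, Gaussian spot width for rendering
    transform: SimilarityTransform = field(
        default_factory=lambda: SimilarityTransform(0.65, 0.03, 1500.0, -900.0)
    )

    def __post_init__(self) -> None:
        if self.overlap <= 0:
            raise ValueError("frame overlap must be positive")
        h, w = self.frame_size
        if self.overlap >= min(h, w):
            raise ValueError("frame overlap must be smaller than the frame")


@dataclass
class ChipLayout:
    """True cluster positions in stitched pixel space and on the stage."""

    read_ids: list[str]
    pixel: np.ndarray  # (n, 2) global stitched pixel coordinates (x, y)
    stage: np.ndarray  # (n, 2) = truth_transform(pixel)
    frames: dict  # (row, col) -> true float offset (x, y)
    frame_size: tuple[int, int]
    overlap: float
    truth_transform: SimilarityTransform
    spot_sigma: float = 1.4

    def __post_init__(self) -> None:
        if len(set(self.read_ids)) != len(self.read_ids):
            raise ValueError("cluster read ids must be unique")

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "read_id": self.read_ids,
                "pixel_x": self.pixel[:, 0],
                "pixel_y": self.pixel[:, 1],
                "stage_x": self.stage[:, 0],
                "stage_y": self.stage[:, 1],
            }
        )

    def frame_adjacency(self) -> list[tuple]:
        """4-neighbor edges with *nominal* (integer-raster) relative offsets."""
        h, w = self.frame_size
        rows = max(r for r, _ in self.frames) + 1
        cols = max(c for _, c in self.frames) + 1
        edges = []
        for r in range(rows):
            for c in range(cols):
                if c + 1 < cols:
                    edges.append(((r, c), (r, c + 1), np.array([w - self.overlap, 0.0])))
                if r + 1 < rows:
                    edges.append(((r, c), (r + 1, c), np.array([0.0, h - self.overlap])))
        return edges

    def local_spots(self, frame_id) -> tuple[np.ndarray, np.ndarray]:
        """(indices, frame-local xy) of clusters falling inside a frame."""
        off = self.frames[frame_id]
        h, w = self.frame_size
        local = self.pixel - off
        inside = (
            (local[:, 0] >= 0)
            & (local[:, 0] <= w - 1)
            & (local[:, 1] >= 0)
            & (local[:, 1] <= h - 1)
        )
        return np.where(inside)[0], local[inside]


def build_chip_layout(cfg: ChipLayoutConfig, read_ids: Sequence[str], rng) -> ChipLayout:
    rows, cols = cfg.frame_grid
    h, w = cfg.frame_size
    frames: dict = {}
    for r in range(rows):
        for c in range(cols):
            nominal = np.array([c * (w - cfg.overlap), r * (h - cfg.overlap)])
            if (r, c) == (0, 0):
                frames[(r, c)] = np.zeros(2)
            else:
                frames[(r, c)] = nominal + rng.uniform(
                    -cfg.offset_jitter, cfg.offset_jitter, 2
                )
    gw = cols * w - (cols - 1) * cfg.overlap
    gh = rows * h - (rows - 1) * cfg.overlap
    margin = 6.0
    cell = cfg.min_separation * 1.6
    nx = int((gw - 2 * margin) // cell)
    ny = int((gh - 2 * margin) // cell)
    n = len(read_ids)
    if n > nx * ny:
        raise ValueError(
            f"chip too small: {n} clusters but only {nx * ny} sites at "
            f"min_separation {cfg.min_separation}"
        )
    cells = rng.choice(nx * ny, size=n, replace=False)
    cx = cells % nx
    cy = cells // nx
    jitter = rng.uniform(-0.2, 0.2, (n, 2)) * cell
    pixel = np.column_stack(
        [margin + (cx + 0.5) * cell, margin + (cy + 0.5) * cell]
    ) + jitter
    stage = cfg.transform(pixel)
    return ChipLayout(
        list(read_ids), pixel, stage, frames, cfg.frame_size, cfg.overlap,
        cfg.transform, cfg.spot_sigma,
    )


def render_frames(
    layout: ChipLayout, noise_sd: float = 0.0, amplitude: float = 1000.0, seed: int = 0
) -> dict:
    """Grayscale tile images with a Gaussian spot at each cluster position.

    Spot centroids in tile-local coordinates equal the cluster's global pixel
    position minus the frame's true float offset.
    """
    rng = np.random.default_rng(seed)
    h, w = layout.frame_size
    sigma = layout.spot_sigma
    rad = int(math.ceil(4 * sigma))
    out = {}
    for frame_id in layout.frames:
        img = np.zeros((h, w), dtype=np.float64)
        _, local = layout.local_spots(frame_id)
        for x0, y0 in local:
            c0, c1 = int(np.floor(x0)) - rad, int(np.floor(x0)) + rad + 1
            r0, r1 = int(np.floor(y0)) - rad, int(np.floor(y0)) + rad + 1
            c0, c1 = max(0, c0), min(w, c1)
            r0, r1 = max(0, r0), min(h, r1)
            if c0 >= c1 or r0 >= r1:
                continue
            yy, xx = np.mgrid[r0:r1, c0:c1]
            img[r0:r1, c0:c1] += amplitude * np.exp(
                -((xx - x0) ** 2 + (yy - y0) ** 2) / (2 * sigma * sigma)
            )
        if noise_sd > 0:
            img = img + rng.normal(0, noise_sd, img.shape)
        out[frame_id] = img.astype(np.float32)
    return out


# ---------------------------------------------------------------------------
# sequencing


@dataclass
class SimulatedRun:
    """Reads plus exhaustive ground truth for every discrepancy."""

    reads: list[Read]
    truth: list[tuple[Edit, ...]]
    molecule_index: np.ndarray
    pool: MoleculePool
    layout: ChipLayout | None
    seed: int
    seq_model: SeqErrorModel

    @property
    def reference(self) -> str:
        return self.pool.templates.reference

    def molecule_edits(self, read_idx: int) -> tuple[Edit, ...]:
        """Edits physically present in the read's DNA clone (everything but
        sequencer miscalls)."""
        return tuple(e for e in self.truth[read_idx] if e.origin != ORIGIN_SEQ)

    def truth_table(self) -> pd.DataFrame:
        rows = []
        for read, edits in zip(self.reads, self.truth):
            for e in edits:
                rows.append(
                    {
                        "read_id": read.read_id, "pos": e.pos, "kind": e.kind,
                        "ref": e.ref, "alt": e.alt, "origin": e.origin,
                    }
                )
        return pd.DataFrame(
            rows, columns=["read_id", "pos", "kind", "ref", "alt", "origin"]
        )

    def counts_by_origin(self) -> dict:
        out: dict = {}
        for edits in self.truth:
            for e in edits:
                out[e.origin] = out.get(e.origin, 0) + 1
        return out


def simulate_sequencing(
    pool: MoleculePool,
    model: SeqErrorModel,
    n_reads: int,
    seed: int,
    layout: ChipLayoutConfig | None = None,
    read_sampling: str | None = None,
) -> SimulatedRun:
    """Sample reads from the molecule pool and inject sequencer errors.

    Each read is one molecule re-read by the instrument: sequencer-injected
    errors (origin ``sequencer_error``) are laid on top of the molecule's own
    edits, per-base Phred scores are emitted from the realized error
    probabilities, and every read is assigned a unique cluster on the chip
    when a layout configuration is given.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    if len(pool) == 0:
        raise ValueError("empty molecule pool")
    rng = np.random.default_rng(seed)
    templates = pool.templates
    ref = templates.reference
    L = len(ref)
    hp_runs = homopolymer_lengths(ref)

    # each cluster on the chip is a distinct physical molecule, so reads
    # sample the pool without replacement whenever it is large enough
    sampling = read_sampling or pool.composition
    if sampling == "multinomial":
        if len(pool) >= n_reads:
            mol_idx = rng.choice(len(pool), n_reads, replace=False)
        else:
            mol_idx = rng.integers(0, len(pool), n_reads)
    else:
        counts = _template_counts(rng, templates.fractions(), n_reads, sampling)
        parts = []
        for t, k in enumerate(counts):
            pool_t = pool.indices_for_template(t)
            if len(pool_t) == 0 and k > 0:
                raise ValueError(f"no molecules of template {t} in the pool")
            if k > 0:
                if len(pool_t) >= k:
                    parts.append(rng.choice(pool_t, k, replace=False))
                else:
                    parts.append(pool_t[rng.integers(0, len(pool_t), k)])
        mol_idx = rng.permutation(np.concatenate(parts)) if parts else np.array([], int)

    sub_p, indel_p = model.position_rates(ref)
    p_tot = sub_p + indel_p
    total_p = float(p_tot.sum())
    if total_p > 0:
        cdf = np.cumsum(p_tot) / total_p
        sub_frac = sub_p / np.maximum(p_tot, 1e-300)
    else:
        cdf = None

    if model.read_rate_sigma > 0:
        s = model.read_rate_sigma
        r_mult = np.exp(rng.normal(-0.5 * s * s, s, n_reads))
    else:
        r_mult = np.ones(n_reads)
    n_err = rng.poisson(total_p * r_mult) if total_p > 0 else np.zeros(n_reads, int)

    uniform_q = model.read_rate_sigma == 0 and model.q_jitter_sd == 0
    if uniform_q:
        shared_q = model.q_from_p(np.maximum(p_tot, 1e-6))
        shared_q.flags.writeable = False

    seq_cache: dict = {}  # molecule index -> (sequence, quals) for clean reads
    reads: list[Read] = []
    truth: list[tuple[Edit, ...]] = []
    width = max(6, len(str(n_reads)))
    for i in range(n_reads):
        mi = int(mol_idx[i])
        mol_edits = pool.molecule_edits(mi)
        read_id = f"r{i:0{width}d}"
        if uniform_q:
            base_q = shared_q
        else:
            base_q = model.q_from_p(np.maximum(p_tot * r_mult[i], 1e-6), rng=rng)

        seq_edits: list[Edit] = []
        if n_err[i] > 0 and cdf is not None:
            taken = [e.pos for e in mol_edits]
            for _ in range(int(n_err[i])):
                e = _draw_edit(
                    rng, ref, cdf, np.arange(L), lambda p: sub_frac[p], hp_runs,
                    taken, ORIGIN_SEQ, hp_duplication=model.hp_duplication,
                )
                if e is not None:
                    seq_edits.append(e)

        all_edits = tuple(sorted(mol_edits + tuple(seq_edits), key=lambda e: e.sort_key))
        if not all_edits:
            cached = seq_cache.get(mi) if uniform_q else None
            if cached is None:
                seq, quals = ref, base_q
                if uniform_q:
                    seq_cache[mi] = (seq, quals)
            else:
                seq, quals = cached
        elif not seq_edits and uniform_q:
            cached = seq_cache.get(mi)
            if cached is None:
                seq, quals = materialize(ref, all_edits, base_q)
                quals.flags.writeable = False
                seq_cache[mi] = (seq, quals)
            else:
                seq, quals = cached
        else:
            seq, quals = materialize(ref, all_edits, base_q)
        reads.append(Read(read_id, seq, quals, cluster_ref=read_id))
        truth.append(all_edits)

    chip = None
    if layout is not None:
        chip = build_chip_layout(layout, [r.read_id for r in reads], rng)
    return SimulatedRun(reads, truth, mol_idx, pool, chip, seed, model)


# ---------------------------------------------------------------------------
# validation re-sequencing


def simulate_validation(
    reference: str,
    molecule_edits: Sequence[Edit],
    n_reads: int,
    val_error_rate: float,
    seed: int,
    damage_rate: float = 0.0,
    clone_id: str = "",
) -> ValidationPileup:
    """Re-read a retrieved clone's physical molecule ``n_reads`` times.

    The input is the *molecule* (template plus PCR mutations) - sequencer
    miscalls from the original run do not replicate, which is the entire point
    of the method.  Each validation read carries independent errors at
    ``val_error_rate`` (substitution-style noise).  With probability
    ``damage_rate``, the molecule acquires one extra mutation *before*
    re-reading (damage, degradation or PCR error on the substrate during the
    validation process), labelled ``validation_artifact``.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    rng = np.random.default_rng(seed)
    edits = sorted(molecule_edits, key=lambda e: e.sort_key)
    damage: tuple[Edit, ...] = ()
    if damage_rate > 0 and rng.random() < damage_rate:
        taken = [e.pos for e in edits]
        free = [
            p for p in range(len(reference))
            if all(abs(p - t) > EDIT_GUARD for t in taken)
        ]
        pos = int(rng.choice(free))
        others = [b for b in BASES if b != reference[pos]]
        dmg = Edit(pos, SUB, reference[pos], others[rng.integers(3)], ORIGIN_VALIDATION)
        edits = sorted(edits + [dmg], key=lambda e: e.sort_key)
        damage = (dmg,)

    L = len(reference)
    major = np.array([_AIDX_REF[b] for b in reference], dtype=np.int64)
    ins_events: list[tuple[int, str]] = []
    for e in edits:
        if e.kind == SUB:
            major[e.pos] = ALLELES.index(e.alt)
        elif e.kind == DEL:
            for k in range(len(e.ref)):
                major[e.pos + k] = 4  # gap
        else:
            ins_events.append((e.pos, e.alt))

    counts = np.zeros((L, 5), dtype=np.int64)
    if val_error_rate > 0:
        k = rng.binomial(n_reads, val_error_rate, L)
    else:
        k = np.zeros(L, dtype=np.int64)
    counts[np.arange(L), major] = n_reads - k
    for pos in np.nonzero(k)[0]:
        others = [a for a in range(5) if a != major[pos] and a != 4]  # base miscalls
        split = rng.multinomial(int(k[pos]), np.ones(len(others)) / len(others))
        for a, n in zip(others, split):
            counts[pos, a] += int(n)

    ins_counts: dict[tuple[int, str], int] = {}
    for pos, alt in ins_events:
        miss = int(rng.binomial(n_reads, val_error_rate)) if val_error_rate > 0 else 0
        ins_counts[(pos, alt)] = n_reads - miss
    return ValidationPileup(clone_id, reference, counts, ins_counts, damage)


_AIDX_REF = {b: i for i, b in enumerate(ALLELES)}
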