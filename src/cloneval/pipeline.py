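"""End-to-end orchestration: simulate -> select -> register -> validate -> stats.

Each enabled stage consumes the previous stage's products, writes its
artifacts under the output directory, and contributes a summary block to the
:class:`RunReport`.  Identical configuration (including seeds) produces
byte-identical TSV/JSON outputs; every reported fraction is recomputable from
the reported counts.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as cio
from .config import RunConfig
from .edits import ORIGIN_SEQ, mask_to_bool
from .registration import fit_similarity_lsq, map_and_plan
from .select import (
    ALL_VARIANT_READS,
    CoordinateIndex,
    VariantCall,
    align_and_call,
    build_coordinate_index,
    select_targets,
)
from .simulate import (
    ChipLayoutConfig,
    PcrModel,
    SeqErrorModel,
    SimilarityTransform,
    SimulatedRun,
    TemplateSet,
    default_reference,
    make_spikein_templates,
    simulate_pcr,
    simulate_sequencing,
    simulate_validation,
)
from .stats import (
    BudgetModel,
    budget_crossover,
    count_true_variant_bases,
    pcr_error_rate,
    qc_loss_analysis,
)
from .validation import (
    Verdict,
    classify_variant,
    recompute_vf,
    summarize_validation,
)

log = logging.getLogger("cloneval")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class RunReport:
    config_hash: str
    seed: int | None
    stages: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {"config_hash": self.config_hash, "seed": self.seed, "stages": self.stages},
            sort_keys=True,
            indent=2,
            default=_jsonable,
        )


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    raise TypeError(f"not JSON serializable: {type(x)}")


def _stage_seed(base: int, k: int) -> int:
    return int(np.random.SeedSequence((base, k)).generate_state(1)[0] % (2**31))


def build_templates(config: RunConfig) -> TemplateSet:
    rc = config.reference
    if rc.sequence is not None:
        reference = rc.sequence
        primer = tuple(tuple(x) for x in (rc.primer_mask or ()))
    else:
        reference, primer = default_reference(rc.length, rc.primer_len, seed=rc.seed)
        if rc.primer_mask is not None:
            primer = tuple(tuple(x) for x in rc.primer_mask)
    specs = [t.variants for t in config.templates]
    fractions = [t.fraction for t in config.templates]
    labels = [
        t.label or (f"template_{i}" if t.variants else "wild_type")
        for i, t in enumerate(config.templates)
    ]
    return make_spikein_templates(reference, specs, fractions, labels, primer)


def run_pipeline(config: RunConfig, outdir) -> RunReport:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config.config_hash(), config.seed)
    state: dict = {}

    for stage in config.stages:
        log.info("stage %s starting", stage)
        try:
            _STAGES[stage](config, state, report, out)
        except Exception as err:  # name the failing stage, keep partial outputs
            (out / "report.json").write_text(report.to_json() + "\n")
            raise PipelineError(stage, err) from err
        log.info("stage %s done: %s", stage, report.stages.get(stage))
    (out / "report.json").write_text(report.to_json() + "\n")
    return report


def _stage_simulate(config: RunConfig, state, report, out: Path) -> None:
    templates = build_templates(config)
    pcr = PcrModel(
        config.pcr.doublings, config.pcr.sub_rate, config.pcr.indel_rate,
        config.pcr.mode,
    )
    pool = simulate_pcr(
        templates, pcr, config.pcr.n_molecules, _stage_seed(config.seed, 0),
        composition=config.pcr.composition,
    )
    sc = config.sequencer
    seq_model = SeqErrorModel.from_aggregate(
        templates.reference, sc.sub_rate, sc.indel_rate,
        hp_multipliers=sc.hp_multipliers, positional_gain=tuple(sc.positional_gain),
        read_rate_sigma=sc.read_rate_sigma, q_jitter_sd=sc.q_jitter_sd,
    )
    layout_cfg = None
    if config.layout is not None:
        lc = config.layout
        layout_cfg = ChipLayoutConfig(
            tuple(lc.frame_grid), tuple(lc.frame_size), lc.overlap,
            lc.offset_jitter, lc.min_separation, lc.spot_sigma,
            SimilarityTransform(*lc.transform),
        )
    run = simulate_sequencing(
        pool, seq_model, config.run.n_reads, _stage_seed(config.seed, 1),
        layout=layout_cfg,
    )
    state["templates"] = templates
    state["run"] = run
    state["reads"] = run.reads
    state["reference"] = templates.reference
    state["primer_mask"] = templates.primer_mask
    cio.write_fastq(run.reads, out / "reads.fastq")
    run.truth_table().to_csv(out / "truth.tsv", sep="\t", index=False)
    if run.layout is not None:
        run.layout.table().to_csv(out / "layout.tsv", sep="\t", index=False)
    report.stages["simulate"] = {
        "n_reads": len(run.reads),
        "n_molecules": len(pool),
        "truth_by_origin": run.counts_by_origin(),
        "pcr_doublings": pcr.doublings,
        "sequencer_aggregate_rate": seq_model.aggregate_rate(templates.reference),
    }


def _stage_select(config: RunConfig, state, report, out: Path) -> None:
    if "run" not in state and config.input is not None:
        if config.input.reference_fasta:
            ref = next(iter(cio.read_fasta(config.input.reference_fasta).values()))
            state["reference"] = ref
            state["primer_mask"] = ()
        if config.input.fastq:
            state["reads"] = cio.read_fastq(config.input.fastq)
        elif config.input.sam:
            pairs = cio.read_sam_alignments(config.input.sam, state["reference"])
            state["reads"] = [r for r, _ in pairs]
            state["sam_alignments"] = {a.read_id: a for _, a in pairs}
    reads = state["reads"]
    reference = state["reference"]
    primer_mask = state.get("primer_mask", ())

    if "sam_alignments" in state:
        from .select import calls_from_cigar

        calls: list[VariantCall] = []
        for read in reads:
            aln = state["sam_alignments"][read.read_id]
            sub_ref = reference[aln.ref_start : aln.ref_end]
            for e in calls_from_cigar(aln.cigar, read.sequence, sub_ref):
                calls.append(
                    VariantCall(read.read_id, e.pos + aln.ref_start, e.kind, e.ref,
                                e.alt)
                )
        excluded: list = []
        n_aligned = len(reads)
    else:
        calls, alignments, excluded = align_and_call(
            reads, reference, primer_mask, band_width=config.selection.band_width
        )
        n_aligned = len(alignments)
    selected = select_targets(
        calls, config.selection.mode, config.selection.positions
    )
    state["calls"] = calls
    state["selected"] = selected
    state["n_aligned"] = n_aligned
    cio.write_calls_tsv(calls, out / "calls.tsv")
    cio.write_vcf(calls, reference, out / "calls.vcf")
    (out / "selected_reads.txt").write_text("\n".join(selected) + "\n")
    report.stages["select"] = {
        "n_reads_in": len(reads),
        "n_aligned": n_aligned,
        "n_unalignable": len(excluded),
        "n_calls": len(calls),
        "n_selected_reads": len(selected),
        "mode": config.selection.mode,
    }


def _stage_register(config: RunConfig, state, report, out: Path) -> None:
    run: SimulatedRun | None = state.get("run")
    rc = config.registration
    if run is not None and run.layout is not None:
        layout = run.layout
        table = layout.table()
    elif config.input is not None and config.input.layout_tsv:
        layout = None
        table = cio.read_layout_tsv(config.input.layout_tsv)
    else:
        raise ValueError("register stage needs a simulated layout or a layout_tsv")
    index = build_coordinate_index(state["selected"], table)

    stitch_error = None
    if layout is not None:
        # exercise the imaging path: render the frames, detect spots, stitch,
        # and report how far the recovered frame offsets sit from the truth
        if len(layout.frames) > 1 and len(layout.read_ids) <= 20_000:
            from .registration import detect_spots, stitch_frames
            from .simulate import render_frames

            frames = render_frames(layout, noise_sd=rc.render_noise_sd,
                                   seed=_stage_seed(config.seed or 0, 3))
            cio.write_frames_tiff(frames, out / "frames")
            spots = {
                fid: detect_spots(img, rc.min_intensity,
                                  min_separation=layout.overlap / 16)
                for fid, img in frames.items()
            }
            stitched = stitch_frames(spots, layout.frame_adjacency(),
                                     layout.overlap)
            stitch_error = float(
                np.mean(
                    [
                        np.linalg.norm(stitched.offsets[f] - layout.frames[f])
                        for f in layout.frames
                    ]
                )
            )
        # calibrate pixel -> stage on a deterministic fiducial subset
        n = len(layout.read_ids)
        fid = np.unique(np.linspace(0, n - 1, min(50, n)).round().astype(int))
        transform, rms = fit_similarity_lsq(layout.pixel[fid], layout.stage[fid])
    else:
        if not {"stage_x", "stage_y"} <= set(table.columns):
            raise ValueError("layout table without stage columns cannot be calibrated")
        pts = table[["pixel_x", "pixel_y"]].to_numpy()
        stg = table[["stage_x", "stage_y"]].to_numpy()
        transform, rms = fit_similarity_lsq(pts, stg)
    plan = map_and_plan(
        index, transform, plate_format=rc.plate_format,
        laser_radius=rc.laser_radius, skip_collisions=rc.skip_collisions,
    )
    state["plan"] = plan
    plan.to_tsv(out / "retrieval_plan.tsv")
    plan.plate_map().to_csv(out / "plate_map.csv", index=False)
    report.stages["register"] = {
        "n_planned": len(plan),
        "n_collision_flagged": int(plan.table["collision"].sum()),
        "calibration_rms": rms,
        "stitch_error_px": stitch_error,
        "transform": {
            "scale": transform.scale, "rotation": transform.rotation,
            "tx": transform.tx, "ty": transform.ty,
        },
        "plate_format": rc.plate_format,
    }


def _stage_validate(config: RunConfig, state, report, out: Path) -> None:
    run: SimulatedRun | None = state.get("run")
    if run is None:
        raise ValueError(
            "validate stage needs simulated clones; for real data build pileups "
            "with validation.pileup_from_sam and classify_variant directly"
        )
    vc = config.validation
    selected = set(state["selected"])
    calls_by_read: dict[str, list[VariantCall]] = {}
    for c in state["calls"]:
        calls_by_read.setdefault(c.read_id, []).append(c)
    idx_of = {r.read_id: i for i, r in enumerate(run.reads)}

    verdicts: list[Verdict] = []
    cache: dict = {}
    deterministic = vc.error_rate == 0 and vc.damage_rate == 0
    base_seed = _stage_seed(config.seed, 2)
    for k, read_id in enumerate(sorted(selected)):
        mol_edits = run.molecule_edits(idx_of[read_id])
        key = tuple((e.pos, e.kind, e.ref, e.alt) for e in mol_edits)
        pileup = cache.get(key) if deterministic else None
        if pileup is None:
            pileup = simulate_validation(
                run.reference, mol_edits, vc.depth, vc.error_rate,
                seed=(base_seed + k) % (2**31), damage_rate=vc.damage_rate,
                clone_id=read_id,
            )
            if deterministic:
                cache[key] = pileup
        for call in calls_by_read.get(read_id, ()):
            verdicts.append(
                classify_variant(call, pileup, vc.consensus_threshold,
                                 vc.min_depth_fraction)
            )
    state["verdicts"] = verdicts
    cio.write_verdicts_tsv(verdicts, out / "verdicts.tsv")
    cio.write_vcf(
        state["calls"], run.reference, out / "validated.vcf", verdicts=verdicts
    )
    summary = summarize_validation(verdicts) if verdicts else None
    vf = recompute_vf(state["calls"], state["n_aligned"], verdicts)
    vf.to_csv(out / "vf_table.tsv", sep="\t", index=False)
    state["vf_table"] = vf
    report.stages["validate"] = {
        "n_clones": len(selected),
        "n_verdicts": len(verdicts),
        "consensus_threshold": vc.consensus_threshold,
        "depth": vc.depth,
        "counts": summary.counts if summary else {},
        "artifact_fraction": summary.artifact_fraction if summary else None,
        "true_fraction": summary.true_fraction if summary else None,
    }


def _stage_stats(config: RunConfig, state, report, out: Path) -> None:
    run: SimulatedRun | None = state.get("run")
    verdicts = state.get("verdicts", [])
    reference = state["reference"]
    primer_mask = state.get("primer_mask", ())
    nonprimer = int((~mask_to_bool(primer_mask, len(reference))).sum())
    block: dict = {}

    if verdicts:
        # designed spike-in alleles are known template variants, not PCR
        # errors; exclude them from the fidelity estimate
        designed = set()
        templates = state.get("templates")
        if templates is not None:
            designed = {
                (e.pos, e.kind, e.ref, e.alt)
                for t in templates.templates
                for e in t.edits
            }
        pcr_verdicts = [
            v for v in verdicts
            if (v.variant.pos, v.variant.kind, v.variant.ref, v.variant.alt)
            not in designed
        ]
        tv_bases = count_true_variant_bases(pcr_verdicts)
        assayed = state["n_aligned"] * nonprimer
        doublings = config.pcr.doublings
        est = pcr_error_rate(tv_bases, assayed, doublings)
        block["pcr_error_rate"] = {
            "true_variant_bases": est.true_variant_bases,
            "assayed_bases": est.assayed_bases,
            "doublings": est.doublings,
            "rate": est.rate,
            "ci": [est.ci_low, est.ci_high],
        }
        curve = qc_loss_analysis(
            state["reads"], state["calls"], verdicts,
            config.stats.q_thresholds, config.stats.quality_mode,
            config.stats.p_fraction,
        )
        curve.table.to_csv(out / "qc_loss.tsv", sep="\t", index=False)
        block["qc_loss"] = curve.table.to_dict(orient="list")

    budget = budget_crossover(BudgetModel())
    block["budget"] = {
        "reads_barcoding": budget.reads_barcoding,
        "reads_validation": budget.reads_validation,
        "crossover_sites": budget.crossover_sites,
        "equations": budget.equations,
    }
    if run is not None:
        block["truth_by_origin"] = run.counts_by_origin()
    report.stages["stats"] = block


_STAGES = {
    "simulate": _stage_simulate,
    "select": _stage_select,
    "register": _stage_register,
    "validate": _stage_validate,
    "stats": _stage_stats,
}


def demo_config(n_reads: int = 4000, seed: int = 7) -> RunConfig:
    """A small, fully simulated end-to-end experiment: a spike-in ladder on a
    2x2-frame chip, PCR at the study rate, and error-free validation."""
    from .config import (
        LayoutSection,
        PcrConfig,
        RunConfig,
        SequencerConfig,
        SequencingRunConfig,
        TemplateConfig,
    )

    reference, _ = default_reference()
    # designed spike-in weights 90% .. 0.01%; the mixture normalizes to 1,
    # the majority template playing the role of the main (wild-type) sequence
    ladder = [0.90, 0.10, 0.01, 1e-3, 1e-4]
    positions = [40, 75, 120, 155, 205]
    templates = [
        TemplateConfig(
            variants=[(p, "substitution", reference[p], _other(reference[p]))]
            if f < max(ladder) else None,
            fraction=f,
            label=f"spike_{f:g}" if f < max(ladder) else "majority",
        )
        for p, f in zip(positions, ladder)
    ]
    return RunConfig(
        seed=seed,
        templates=templates,
        pcr=PcrConfig(n_molecules=20000, composition="expected"),
        sequencer=SequencerConfig(sub_rate=0.0015, indel_rate=0.0015),
        run=SequencingRunConfig(n_reads=n_reads),
        layout=LayoutSection(),
    )


def _other(base: str) -> str:
    return {"A": "G", "C": "T", "G": "A", "T": "C"}[base]
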