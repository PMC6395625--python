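"""Benchmark experiments at the study's conditions.

Each function runs the full method - generate, select, validate, estimate -
at the conditions of the corresponding wet-lab experiment and returns the
measured quantities.  They are used by the acceptance tests and the
``scripts/acceptance.py`` reproduction script.
"""
from __future__ import annotations

import numpy as np
from scipy.stats import binomtest

from .edits import SUB
from .select import ALL_VARIANT_READS, POSITIONAL, align_and_call, select_targets
from .simulate import (
    DEFAULT_PRIMER_MASK,
    DEFAULT_REFERENCE,
    PcrModel,
    SeqErrorModel,
    make_spikein_templates,
    simulate_pcr,
    simulate_sequencing,
    simulate_validation,
)
from .stats import count_true_variant_bases, pcr_error_rate
from .validation import ARTIFACT, TRUE_VARIANT, classify_variant, recompute_vf

#: aggregate sequencer error split used throughout: ~0.147% indel + ~0.148%
#: substitution per base, the error signature of the pyrosequencing run
SEQ_SUB_RATE = 0.00148
SEQ_INDEL_RATE = 0.00147

PCR_RATE = 2.5e-6
DOUBLINGS = 43.0


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in
            np.random.SeedSequence(seed).generate_state(n) % (2 ** 31)]


def _validate_all(run, calls, selected, depth=20, seed=0):
    """Error-free validation of every selected clone; verdicts for each of
    its calls.  Identical molecules validate identically, so pileups are
    cached per distinct molecule."""
    idx_of = {r.read_id: i for i, r in enumerate(run.reads)}
    calls_by_read: dict[str, list] = {}
    for c in calls:
        calls_by_read.setdefault(c.read_id, []).append(c)
    cache: dict = {}
    verdicts = []
    for rid in selected:
        mol = run.molecule_edits(idx_of[rid])
        key = tuple((e.pos, e.kind, e.ref, e.alt) for e in mol)
        pileup = cache.get(key)
        if pileup is None:
            pileup = simulate_validation(run.reference, mol, depth, 0.0, seed=seed,
                                         clone_id=rid)
            cache[key] = pileup
        for c in calls_by_read.get(rid, ()):
            verdicts.append(classify_variant(c, pileup))
    return verdicts


def pcr_rate_replicate(seed: int, n_reads: int = 10_000):
    """One full pipeline pass at the PCR-fidelity experiment's conditions:
    43 doublings at 2.5e-6 per base per doubling, ~2.2e6 assayed non-primer
    bases, pyrosequencing-type errors on top, error-free validation."""
    templates = make_spikein_templates(
        DEFAULT_REFERENCE, [None], [1.0], primer_mask=DEFAULT_PRIMER_MASK
    )
    s_pool, s_run, s_val = _child_seeds(seed, 3)
    pool = simulate_pcr(
        templates, PcrModel(DOUBLINGS, PCR_RATE), n_molecules=20 * n_reads,
        seed=s_pool,
    )
    model = SeqErrorModel.from_aggregate(
        DEFAULT_REFERENCE, SEQ_SUB_RATE, SEQ_INDEL_RATE
    )
    run = simulate_sequencing(pool, model, n_reads, seed=s_run)
    calls, alignments, _ = align_and_call(
        run.reads, DEFAULT_REFERENCE, DEFAULT_PRIMER_MASK
    )
    selected = select_targets(calls, ALL_VARIANT_READS)
    verdicts = _validate_all(run, calls, selected, seed=s_val)
    tv_bases = count_true_variant_bases(verdicts)
    assayed = len(alignments) * 221  # non-primer bases per end-to-end read
    return pcr_error_rate(tv_bases, assayed, DOUBLINGS)


def pcr_rate_experiment(seed: int, n_replicates: int = 50, n_reads: int = 10_000):
    """Replicated recovery of the PCR-induced error rate.

    Returns the per-replicate estimates, their mean, and the fraction of
    replicates whose 95% Poisson CI covers the configured rate."""
    estimates = []
    covered = 0
    for s in _child_seeds(seed * 2 + 1, n_replicates):
        est = pcr_rate_replicate(s, n_reads)
        estimates.append(est.rate)
        covered += est.ci_low <= PCR_RATE <= est.ci_high
    return {
        "rates": estimates,
        "mean_rate": float(np.mean(estimates)),
        "ci_coverage": covered / n_replicates,
        "true_rate": PCR_RATE,
        "n_replicates": n_replicates,
    }


def sensitivity_floor_experiment(seed: int, n_reads: int = 164_332,
                                 spike_fraction: float = 3e-5):
    """Detection of a spike-in at 0.003% variant frequency.

    The dilution is composed deterministically (the sample contains the
    expected number of variant molecules - a pipetted spike-in), the
    sequencer injects ~0.3%/base errors, every flagged read at the site is
    validated error-free, and the post-validation VF is measured."""
    pos = 120
    ref = DEFAULT_REFERENCE
    alt = "A" if ref[pos] != "A" else "G"
    templates = make_spikein_templates(
        ref,
        [None, (pos, SUB, ref[pos], alt)],
        [1 - spike_fraction, spike_fraction],
        primer_mask=DEFAULT_PRIMER_MASK,
    )
    s_pool, s_run, s_val = _child_seeds(seed * 2 + 2, 3)
    pool = simulate_pcr(
        templates, PcrModel(DOUBLINGS, 0.0), n_molecules=n_reads, seed=s_pool,
        composition="expected",
    )
    model = SeqErrorModel.from_aggregate(ref, SEQ_SUB_RATE, SEQ_INDEL_RATE)
    run = simulate_sequencing(pool, model, n_reads, seed=s_run)
    calls, alignments, _ = align_and_call(run.reads, ref, DEFAULT_PRIMER_MASK)
    site_calls = [c for c in calls if c.pos == pos]
    selected = select_targets(calls, POSITIONAL, [pos])
    verdicts = _validate_all(run, site_calls, selected, seed=s_val)

    vf = recompute_vf(site_calls, len(alignments), verdicts)
    row = vf[
        (vf["pos"] == pos) & (vf["kind"] == SUB) & (vf["alt"] == alt)
    ].iloc[0]
    n_true = int(row["n_true"])
    ci = binomtest(n_true, len(alignments)).proportion_ci(0.95)
    idx_of = {r.read_id: i for i, r in enumerate(run.reads)}
    seq_only = [
        v for v in verdicts
        if not any(e.pos == pos for e in run.molecule_edits(idx_of[v.variant.read_id]))
    ]
    return {
        "vf_after": float(row["vf_after"]),
        "vf_after_percent": float(row["vf_after"]) * 100,
        "vf_before_percent": float(row["vf_before"]) * 100,
        "n_true": n_true,
        "n_flagged_at_site": len(selected),
        "designed_percent": spike_fraction * 100,
        "ci_contains_design": bool(ci.low <= spike_fraction <= ci.high),
        "all_sequencer_calls_artifact": all(
            v.category == ARTIFACT for v in seq_only
        ),
    }


LADDER = (0.90, 0.10, 0.01, 1e-3, 1e-4)
LADDER_POSITIONS = (40, 75, 120, 155, 205)


def _ladder_replicate(seed: int, n_reads: int):
    ref = DEFAULT_REFERENCE
    specs, alts = [], {}
    for i, (p, f) in enumerate(zip(LADDER_POSITIONS, LADDER)):
        if f == max(LADDER):
            specs.append(None)  # the majority template is the base sequence
        else:
            alt = "A" if ref[p] != "A" else "G"
            specs.append((p, SUB, ref[p], alt))
            alts[p] = (alt, f / sum(LADDER))
    templates = make_spikein_templates(
        ref, specs, list(LADDER), primer_mask=DEFAULT_PRIMER_MASK
    )
    s_pool, s_run, s_val = _child_seeds(seed, 3)
    pool = simulate_pcr(
        templates, PcrModel(DOUBLINGS, 0.0), n_molecules=n_reads, seed=s_pool,
        composition="expected",
    )
    model = SeqErrorModel.from_aggregate(ref, SEQ_SUB_RATE, SEQ_INDEL_RATE)
    run = simulate_sequencing(pool, model, n_reads, seed=s_run)
    calls, alignments, _ = align_and_call(run.reads, ref, DEFAULT_PRIMER_MASK)
    positions = list(alts)
    site_calls = [c for c in calls if c.pos in alts]
    selected = select_targets(calls, POSITIONAL, positions)
    verdicts = _validate_all(run, site_calls, selected, seed=s_val)
    vf = recompute_vf(site_calls, len(alignments), verdicts)

    design, before, after = [], [], []
    for p, (alt, frac) in alts.items():
        row = vf[(vf["pos"] == p) & (vf["kind"] == SUB) & (vf["alt"] == alt)]
        if len(row) == 0:
            return None  # designed variant entirely unobserved: degenerate
        design.append(frac)
        before.append(max(float(row["vf_before"].iloc[0]), 1e-7))
        after.append(max(float(row["vf_after"].iloc[0]), 1e-7))

    def r2(obs):
        x = np.log10(design)
        y = np.log10(obs)
        return float(np.corrcoef(x, y)[0, 1] ** 2)

    return r2(before), r2(after)


def ladder_r2_experiment(seed: int, n_seeds: int = 50, n_reads: int = 20_000):
    """Log-log agreement between observed and designed VF on the sub-1%
    rungs of the dilution ladder, before vs after validation."""
    wins = 0
    r2b, r2a = [], []
    for s in _child_seeds(seed * 2 + 3, n_seeds):
        result = _ladder_replicate(s, n_reads)
        if result is None:
            continue
        b, a = result
        r2b.append(b)
        r2a.append(a)
        wins += a > b
    return {
        "n_seeds": n_seeds,
        "wins_after_over_before": wins,
        "mean_r2_before": float(np.mean(r2b)),
        "mean_r2_after": float(np.mean(r2a)),
    }


def stitching_chain_experiment(seed: int, n_seeds: int = 25, n_frames: int = 200,
                               noise: float = 0.3, k_shared: int = 60):
    """Float vs integer-rounded stitching over a long one-axis frame chain.

    Each adjacent frame pair shares ``k_shared`` spots observed with
    independent Gaussian centroid noise on both sides; pairwise offsets are
    reconciled globally and the terminal frame's position error is compared
    between the float pipeline and the integer-rounded baseline."""
    from .registration import stitch_frames

    wins = 0
    errs_f, errs_i = [], []
    step = 80.0
    for s in _child_seeds(seed * 2 + 4, n_seeds):
        rng = np.random.default_rng(s)
        rel = rng.uniform([step - 2, -2], [step + 2, 2], (n_frames - 1, 2))
        true = np.vstack([[0.0, 0.0], np.cumsum(rel, axis=0)])
        sets = {f: [] for f in range(n_frames)}
        adj = []
        for f in range(n_frames - 1):
            d = true[f + 1] - true[f]
            shared = rng.uniform([step + 5, 5], [step + 25, 95], (k_shared, 2))
            sets[f].append(shared + rng.normal(0, noise, shared.shape))
            sets[f + 1].append(shared - d + rng.normal(0, noise, shared.shape))
            adj.append((f, f + 1, np.round(d)))
        spot_sets = {f: np.vstack(p) for f, p in sets.items()}
        res_f = stitch_frames(spot_sets, adj, 20.0, search_radius=3.0)
        res_i = stitch_frames(spot_sets, adj, 20.0, search_radius=3.0,
                              integer_offsets=True)
        err_f = float(np.linalg.norm(res_f.offsets[n_frames - 1] - true[-1]))
        err_i = float(np.linalg.norm(res_i.offsets[n_frames - 1] - true[-1]))
        errs_f.append(err_f)
        errs_i.append(err_i)
        wins += err_f < err_i
    return {
        "n_seeds": n_seeds,
        "float_wins": wins,
        "mean_terminal_error_float": float(np.mean(errs_f)),
        "mean_terminal_error_integer": float(np.mean(errs_i)),
    }
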