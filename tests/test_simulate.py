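"""Generator correctness: designed mixtures, PCR statistics, sequencer error
structure, chip geometry, conservation of origin labels, determinism."""
import numpy as np
import pytest

from cloneval.edits import ORIGIN_PCR, ORIGIN_SEQ, ORIGIN_TEMPLATE, SUB
from cloneval.simulate import (
    ChipLayoutConfig,
    PcrModel,
    SeqErrorModel,
    build_chip_layout,
    make_spikein_templates,
    render_frames,
    simulate_pcr,
    simulate_sequencing,
    simulate_validation,
)


def _sub_at(reference, pos):
    alt = "A" if reference[pos] != "A" else "G"
    return (pos, SUB, reference[pos], alt)


LADDER = [1e-4, 1e-3, 1e-2, 0.10, 0.90]  # the 0.01% .. 90% dilution series


class TestSpikeinTemplates:
    def test_ladder_fractions_normalized(self, reference, primer_mask):
        specs = [_sub_at(reference, p) for p in (40, 75, 120, 155, 205)]
        ts = make_spikein_templates(reference, specs, LADDER, primer_mask=primer_mask)
        assert ts.fractions() == pytest.approx(np.array(LADDER) / sum(LADDER))
        for i, (pos, _, _, alt) in enumerate(specs):
            assert ts.sequence(i)[pos] == alt

    def test_single_wild_type_equals_reference(self, reference):
        ts = make_spikein_templates(reference, [None], [1.0])
        assert ts.sequence(0) == reference

    def test_fractions_one_one_normalize_to_halves(self, reference):
        ts = make_spikein_templates(
            reference, [None, _sub_at(reference, 50)], [1, 1]
        )
        assert ts.fractions() == pytest.approx([0.5, 0.5])

    def test_overlapping_variant_positions_rejected(self, reference):
        with pytest.raises(ValueError, match="distinguishable"):
            make_spikein_templates(
                reference,
                [_sub_at(reference, 50), (50, SUB, reference[50], "C")],
                [0.5, 0.5],
            )


class TestPcr:
    def test_poisson_mean_matches_closed_form(self, wt_templates):
        model = PcrModel(doublings=43, sub_rate=2.5e-6)
        n = 10_000
        pool = simulate_pcr(wt_templates, model, n, seed=5)
        n_mut = sum(len(v) for v in pool.extra_edits.values())
        expected = 221 * 43 * 2.5e-6 * n  # L_eff x rate x d x molecules
        se = np.sqrt(expected)
        assert abs(n_mut - expected) < 3 * se

    def test_zero_rate_zero_mutations(self, wt_templates):
        pool = simulate_pcr(wt_templates, PcrModel(43, 0.0), 500, seed=1)
        assert pool.extra_edits == {}

    def test_mutations_only_at_non_primer_positions(self, wt_templates):
        pool = simulate_pcr(
            wt_templates, PcrModel(doublings=43, sub_rate=5e-4), 2000, seed=2
        )
        nonprimer = set(wt_templates.nonprimer_positions().tolist())
        for edits in pool.extra_edits.values():
            for e in edits:
                assert e.origin == ORIGIN_PCR
                # canonical position may shift left of a run but stays off-primer
                assert e.pos in nonprimer or (e.pos + len(e.ref)) in nonprimer

    def test_lineage_tree_single_doubling_binomial(self, wt_templates):
        """d=1 from one founder: each of the two molecules carries
        Binomial(L_eff, rate) fresh mutations."""
        rate = 2e-3
        counts = []
        for seed in range(300):
            pool = simulate_pcr(
                wt_templates,
                PcrModel(1, rate, mode="lineage_tree"),
                2,
                seed=seed,
                n_initial=1,
            )
            counts.append(sum(len(v) for v in pool.extra_edits.values()) / 2)
        mean = np.mean(counts)
        expected = 221 * rate
        se = np.sqrt(expected / (2 * 300))
        assert abs(mean - expected) < 3.5 * se

    def test_poisson_and_lineage_agree_for_small_doublings(self, wt_templates):
        rate, d, n = 1e-3, 6, 4000
        pools = {
            mode: simulate_pcr(
                wt_templates, PcrModel(d, rate, mode=mode), n, seed=77, n_initial=8
            )
            for mode in ("poisson_approx", "lineage_tree")
        }
        means = {
            mode: sum(len(v) for v in p.extra_edits.values()) / n
            for mode, p in pools.items()
        }
        expected = 221 * rate * d
        se = np.sqrt(expected / n)
        assert abs(means["poisson_approx"] - means["lineage_tree"]) < 3 * se * 2

    def test_invalid_doublings_rejected(self):
        with pytest.raises(ValueError):
            PcrModel(doublings=0, sub_rate=1e-6)


class TestSequencing:
    def test_injected_error_rate_near_configured_aggregate(self, wt_templates):
        model = SeqErrorModel.from_aggregate(wt_templates.reference, 0.0015, 0.0015)
        run = simulate_sequencing(
            simulate_pcr(wt_templates, PcrModel(43, 0.0), 1000, seed=1),
            model, 2000, seed=3,
        )
        n_bases = sum(len(r.sequence) for r in run.reads)
        n_err = sum(1 for t in run.truth for e in t if e.origin == ORIGIN_SEQ)
        assert n_bases >= 1e5
        agg = model.aggregate_rate(wt_templates.reference)
        assert abs(n_err / n_bases - agg) < 0.2 * agg

    def test_zero_error_model_reads_equal_molecules(self, wt_templates):
        pool = simulate_pcr(wt_templates, PcrModel(43, 0.0), 100, seed=1)
        run = simulate_sequencing(pool, SeqErrorModel.flat(0.0), 300, seed=4)
        for read, truth in zip(run.reads, run.truth):
            assert read.sequence == wt_templates.reference
            assert truth == ()

    def test_homopolymer_indels_enriched_tenfold(self, wt_templates):
        ref = wt_templates.reference
        model = SeqErrorModel.from_aggregate(
            ref, sub_rate=0.0, indel_rate=2e-3,
            hp_multipliers={1: 1.0, 2: 1.0, 3: 10.0},
            positional_gain=(1.0, 1.0),
        )
        pool = simulate_pcr(wt_templates, PcrModel(43, 0.0), 10, seed=1)
        run = simulate_sequencing(pool, model, 20_000, seed=6)
        from cloneval.edits import homopolymer_lengths

        runs = homopolymer_lengths(ref)
        hp_sites = int((runs >= 3).sum())
        other_sites = len(ref) - hp_sites
        hp_hits = other_hits = 0
        for t in run.truth:
            for e in t:
                if e.kind == SUB:
                    continue
                # attribute to the run the canonical position belongs to
                if runs[e.pos] >= 3 or (e.pos + 1 < len(ref) and runs[e.pos + 1] >= 3):
                    hp_hits += 1
                else:
                    other_hits += 1
        ratio = (hp_hits / hp_sites) / (other_hits / other_sites)
        assert 6 < ratio < 16  # configured 10x enrichment, binomial scatter

    def test_every_discrepancy_labelled_once_and_counts_conserved(self, small_run):
        total = 0
        for read, truth in zip(small_run.reads, small_run.truth):
            positions = [e.pos for e in truth]
            assert len(positions) == len(set(positions))
            total += len(truth)
        by_origin = small_run.counts_by_origin()
        assert sum(by_origin.values()) == total
        assert set(by_origin) <= {ORIGIN_TEMPLATE, ORIGIN_PCR, ORIGIN_SEQ}

    def test_identical_seed_reproduces_run_byte_identically(self, wt_templates):
        def make():
            pool = simulate_pcr(
                wt_templates, PcrModel(43, 2.5e-6), 500, seed=9
            )
            model = SeqErrorModel.from_aggregate(wt_templates.reference, 1e-3, 1e-3)
            return simulate_sequencing(pool, model, 500, seed=10)

        a, b = make(), make()
        assert [r.sequence for r in a.reads] == [r.sequence for r in b.reads]
        assert all((x.quals == y.quals).all() for x, y in zip(a.reads, b.reads))
        assert a.truth == b.truth

    def test_realized_fractions_concentrate_around_design(self, reference, primer_mask):
        specs = [None, _sub_at(reference, 120)]
        ts = make_spikein_templates(reference, specs, [0.9, 0.1], primer_mask=primer_mask)
        pool = simulate_pcr(ts, PcrModel(43, 0.0), 20_000, seed=3)
        frac = (pool.template_idx == 1).mean()
        assert abs(frac - 0.1) < 3 * np.sqrt(0.1 * 0.9 / 20_000)
        # expected-count composition realizes the design exactly
        pool_e = simulate_pcr(ts, PcrModel(43, 0.0), 20_000, seed=3, composition="expected")
        assert (pool_e.template_idx == 1).sum() == 2000

    def test_emitted_q_within_phred_bounds(self, small_run):
        for read in small_run.reads[:200]:
            assert read.quals.min() >= 2 and read.quals.max() <= 41

    def test_empty_pool_rejected(self, wt_templates):
        pool = simulate_pcr(wt_templates, PcrModel(43, 0.0), 1, seed=1)
        pool.template_idx = pool.template_idx[:0]
        with pytest.raises(ValueError, match="empty"):
            simulate_sequencing(pool, SeqErrorModel.flat(0.0), 10, seed=1)


class TestChip:
    def test_layout_invariants(self, rng):
        cfg = ChipLayoutConfig(frame_grid=(2, 3), frame_size=(128, 128), overlap=24.0)
        layout = build_chip_layout(cfg, [f"r{i}" for i in range(80)], rng)
        assert len(set(layout.read_ids)) == 80
        assert np.allclose(layout.stage, layout.truth_transform(layout.pixel))
        assert layout.frames[(0, 0)] == pytest.approx([0.0, 0.0])

    def test_render_centroid_matches_truth(self):
        from cloneval.registration import detect_spots
        from cloneval.simulate import ChipLayout
        from cloneval.registration import SimilarityTransform

        t = SimilarityTransform()
        pix = np.array([[10.3, 20.7]])
        layout = ChipLayout(["a"], pix, t(pix).reshape(1, 2), {(0, 0): np.zeros(2)},
                            (64, 64), 8.0, t)
        img = render_frames(layout)[(0, 0)]
        spots = detect_spots(img, 50.0, 4.0)
        assert np.abs(spots.xy - pix).max() < 0.05

    def test_zero_spots_blank_tile(self):
        from cloneval.simulate import ChipLayout
        from cloneval.registration import SimilarityTransform

        t = SimilarityTransform()
        layout = ChipLayout(["a"], np.array([[500.0, 500.0]]),
                            t(np.array([[500.0, 500.0]])).reshape(1, 2),
                            {(0, 0): np.zeros(2)}, (64, 64), 8.0, t)
        img = render_frames(layout)[(0, 0)]
        assert img.max() == 0

    def test_nonpositive_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            ChipLayoutConfig(overlap=0.0)


class TestValidationReads:
    def test_true_variant_fully_supported_at_zero_error(self, reference):
        from cloneval.edits import Edit

        mol = (Edit(100, SUB, reference[100], "A" if reference[100] != "A" else "C",
                    ORIGIN_PCR),)
        p = simulate_validation(reference, mol, 100, 0.0, seed=1)
        frac = p.base_counts[100] / p.depth[100]
        assert frac.max() == 1.0
        assert p.base_counts[100].argmax() == "ACGT-".index(mol[0].alt)

    def test_reference_molecule_fully_reference(self, reference):
        p = simulate_validation(reference, (), 100, 0.0, seed=1)
        for pos in (0, 50, 260):
            assert p.base_counts[pos].argmax() == "ACGT-".index(reference[pos])
            assert p.base_counts[pos].max() == 100

    def test_error_rate_realized_in_pileup(self, reference):
        p = simulate_validation(reference, (), 1000, 1e-3, seed=2)
        depth = p.depth.sum()
        non_consensus = depth - sum(
            p.base_counts[i].max() for i in range(len(reference))
        )
        rate = non_consensus / depth
        assert abs(rate - 1e-3) < 3 * np.sqrt(1e-3 / depth)  # binomial tolerance

    def test_damage_event_recorded(self, reference):
        p = simulate_validation(reference, (), 50, 0.0, seed=3, damage_rate=1.0)
        assert len(p.damage_edits) == 1
        dmg = p.damage_edits[0]
        assert p.base_counts[dmg.pos].argmax() == "ACGT-".index(dmg.alt)
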