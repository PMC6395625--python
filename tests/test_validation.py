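"""Verdict logic: consensus calling, classification thresholds, summaries,
and variant-frequency recomputation."""
import numpy as np
import pytest

from cloneval.edits import ORIGIN_PCR, SUB, Edit
from cloneval.select import VariantCall
from cloneval.simulate import simulate_validation
from cloneval.validation import (
    ARTIFACT,
    INDETERMINATE,
    TRUE_VARIANT,
    VALIDATION_ARTIFACT,
    ValidationPileup,
    classify_variant,
    clone_consensus_variants,
    consensus_call,
    recompute_vf,
    summarize_validation,
)

REF = "ACGTACGTAC"


def _pileup(counts_at, depth=100, positions=None):
    """Uniform-depth pileup with overrides at given positions."""
    counts = np.zeros((len(REF), 5), dtype=int)
    for i, b in enumerate(REF):
        counts[i, "ACGT-".index(b)] = depth
    for pos, row in (counts_at or {}).items():
        counts[pos] = row
    return ValidationPileup("clone", REF, counts)


class TestConsensus:
    def test_unanimous_alt(self):
        p = _pileup({3: [100, 0, 0, 0, 0]})  # ref T, all A
        assert consensus_call(p, 3) == ("A", 1.0, True)

    def test_majority_ref_with_minor_alt(self):
        p = _pileup({2: [5, 0, 95, 0, 0]})  # ref G
        allele, frac, usable = consensus_call(p, 2)
        assert (allele, usable) == ("G", True)
        assert frac == pytest.approx(0.95)

    def test_low_depth_position_unusable(self):
        # mean depth ~500; a position at depth 8 (< 2% of mean) is excluded
        p = _pileup({5: [8, 0, 0, 0, 0]}, depth=500)
        assert consensus_call(p, 5) == ("", 0.0, False)

    def test_position_outside_span(self):
        with pytest.raises(IndexError):
            consensus_call(_pileup({}), 99)


class TestClassify:
    CALL = VariantCall("r1", 3, SUB, "T", "A")

    def test_sequencer_miscall_is_artifact(self):
        # clone molecule = reference: clean reference pileup at the site
        v = classify_variant(self.CALL, _pileup({}))
        assert v.category == ARTIFACT
        assert v.consensus_fraction == 0.0

    def test_true_variant_duplicates_in_validation(self):
        v = classify_variant(self.CALL, _pileup({3: [98, 0, 0, 2, 0]}))
        assert v.category == TRUE_VARIANT
        assert v.consensus_fraction == pytest.approx(0.98)

    def test_third_allele_is_validation_artifact(self):
        # damage during validation: consensus is C, neither ref T nor alt A
        v = classify_variant(self.CALL, _pileup({3: [0, 97, 3, 0, 0]}))
        assert v.category == VALIDATION_ARTIFACT

    def test_mixed_pileup_indeterminate(self):
        v = classify_variant(self.CALL, _pileup({3: [60, 0, 0, 40, 0]}))
        assert v.category == INDETERMINATE

    def test_low_depth_indeterminate(self):
        p = _pileup({3: [4, 0, 0, 0, 0]}, depth=500)
        v = classify_variant(self.CALL, p)
        assert v.category == INDETERMINATE and not v.usable

    def test_deletion_call_against_gap_consensus(self):
        call = VariantCall("r1", 2, "deletion", "G", "")
        v = classify_variant(call, _pileup({2: [0, 0, 10, 0, 90]}))
        assert v.category == TRUE_VARIANT

    def test_insertion_call_consensus(self):
        call = VariantCall("r1", 4, "insertion", "", "G")
        p = _pileup({})
        p.ins_counts[(4, "G")] = 95
        assert classify_variant(call, p).category == TRUE_VARIANT
        assert classify_variant(call, _pileup({})).category == ARTIFACT

    def test_threshold_outside_documented_range_rejected(self):
        with pytest.raises(ValueError):
            classify_variant(self.CALL, _pileup({}), consensus_threshold=0.5)

    def test_position_outside_pileup_errors(self):
        with pytest.raises(IndexError):
            classify_variant(VariantCall("r", 50, SUB, "A", "C"), _pileup({}))

    @pytest.mark.parametrize("counts", [[85, 0, 0, 15, 0], [15, 0, 0, 85, 0],
                                        [0, 85, 0, 15, 0], [50, 0, 0, 50, 0]])
    def test_raising_threshold_only_moves_verdicts_to_indeterminate(self, counts):
        low = classify_variant(self.CALL, _pileup({3: counts}), 0.80)
        high = classify_variant(self.CALL, _pileup({3: counts}), 0.95)
        if high.category != INDETERMINATE:
            assert high.category == low.category
        if low.category == INDETERMINATE:
            assert high.category == INDETERMINATE


class TestSummary:
    def test_study_scale_artifact_fractions(self):
        verdicts = []
        for i in range(1879):
            verdicts.append(
                classify_variant(VariantCall(f"a{i}", 3, SUB, "T", "A"), _pileup({}))
            )
        for i in range(10):
            verdicts.append(
                classify_variant(
                    VariantCall(f"t{i}", 3, SUB, "T", "A"),
                    _pileup({3: [100, 0, 0, 0, 0]}),
                )
            )
        s = summarize_validation(verdicts)
        assert s.total == 1889
        assert s.artifact_fraction == pytest.approx(0.9947, abs=5e-5)
        assert s.true_fraction == pytest.approx(0.0053, abs=5e-5)

    def test_all_artifacts(self):
        verdicts = [
            classify_variant(VariantCall("a", 3, SUB, "T", "A"), _pileup({}))
        ]
        s = summarize_validation(verdicts)
        assert (s.artifact_fraction, s.true_fraction) == (1.0, 0.0)

    def test_indel_split_reported(self):
        verdicts = [
            classify_variant(VariantCall(f"d{i}", 2, "deletion", "G", ""), _pileup({}))
            for i in range(816)
        ] + [
            classify_variant(
                VariantCall("d816", 2, "deletion", "G", ""),
                _pileup({2: [0, 0, 0, 0, 100]}),
            )
        ]
        s = summarize_validation(verdicts)
        assert s.counts_by_kind["deletion"][ARTIFACT] == 816
        assert s.counts_by_kind["deletion"][TRUE_VARIANT] == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_validation([])


class TestVfTable:
    def _verdicts(self, calls, categories):
        out = []
        for c, cat in zip(calls, categories):
            if cat == TRUE_VARIANT:
                p = _pileup({c.pos: [0, 0, 0, 0, 0]})
                p.base_counts[c.pos, "ACGT-".index(c.alt)] = 100
            else:
                p = _pileup({})
            out.append(classify_variant(c, p))
        return out

    def test_all_artifacts_vf_after_zero(self):
        calls = [VariantCall(f"r{i}", 3, SUB, "T", "A") for i in range(10)]
        verdicts = self._verdicts(calls, [ARTIFACT] * 10)
        vf = recompute_vf(calls, 100_000, verdicts)
        assert vf.loc[0, "vf_before"] == pytest.approx(1e-4)
        assert vf.loc[0, "vf_after"] == 0.0

    def test_rare_true_variant_survives(self):
        calls = [VariantCall(f"r{i}", 3, SUB, "T", "A") for i in range(5)]
        verdicts = self._verdicts(calls, [TRUE_VARIANT] * 5)
        vf = recompute_vf(calls, 164_332, verdicts)
        assert vf.loc[0, "vf_after"] == pytest.approx(5 / 164_332)
        assert vf.loc[0, "vf_after"] == pytest.approx(3.04e-5, rel=0.01)

    def test_vf_after_never_exceeds_before(self, small_run):
        from cloneval.select import align_and_call

        calls, alns, _ = align_and_call(small_run.reads, small_run.reference)
        idx_of = {r.read_id: i for i, r in enumerate(small_run.reads)}
        verdicts = []
        for c in calls:
            mol = small_run.molecule_edits(idx_of[c.read_id])
            p = simulate_validation(small_run.reference, mol, 20, 0.0, seed=9)
            verdicts.append(classify_variant(c, p))
        vf = recompute_vf(calls, len(alns), verdicts)
        assert (vf["vf_after"] <= vf["vf_before"]).all()
        # equality exactly where everything validated true
        eq = vf["vf_after"] == vf["vf_before"]
        all_true = vf["n_true"] == vf["n_before"]
        assert (eq == all_true).all()


class TestNoiselessOracle:
    def test_classification_matches_truth_exactly(self, small_run):
        """With error-free validation at depth >= 10, verdicts equal the
        simulator's origin labels: sensitivity = specificity = 1."""
        from cloneval.select import align_and_call

        calls, _, _ = align_and_call(small_run.reads, small_run.reference)
        idx_of = {r.read_id: i for i, r in enumerate(small_run.reads)}
        for c in calls:
            mol = small_run.molecule_edits(idx_of[c.read_id])
            p = simulate_validation(small_run.reference, mol, 10, 0.0, seed=3)
            v = classify_variant(c, p)
            # ground truth lives at the molecule level: a call is a true
            # variant iff the clone's DNA actually carries that allele
            mol_alleles = {(e.pos, e.kind, e.ref, e.alt) for e in mol}
            mol_positions = {e.pos for e in mol}
            if (c.pos, c.kind, c.ref, c.alt) in mol_alleles:
                assert v.category == TRUE_VARIANT
            elif c.pos not in mol_positions:
                assert v.category == ARTIFACT
            else:  # molecule carries a different allele at the called site
                assert v.category != TRUE_VARIANT

    def test_error_free_clones_yield_no_variants(self, small_run):
        """Clones of reads with zero discrepancies validate clean: the
        consensus equals the reference everywhere."""
        clean = [
            i for i, t in enumerate(small_run.truth) if not t
        ][:700]
        assert len(clean) == 700
        seen = {}
        for i in clean:
            mol = small_run.molecule_edits(i)
            key = tuple((e.pos, e.ref, e.alt) for e in mol)
            if key in seen:  # identical molecules validate identically
                continue
            p = simulate_validation(small_run.reference, mol, 10, 0.0, seed=4)
            seen[key] = clone_consensus_variants(p)
            assert seen[key] == []
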