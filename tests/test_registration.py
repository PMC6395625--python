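"""Registration chain: similarity transforms, sub-pixel stitching,
invariant point-pattern matching, and the retrieval plan."""
import numpy as np
import pytest

from cloneval.registration import (
    NoMatchError,
    SimilarityTransform,
    SpotSet,
    detect_spots,
    fit_similarity_lsq,
    map_and_plan,
    match_point_patterns,
    stitch_frames,
)
from cloneval.select import build_coordinate_index


class TestTransform:
    def test_round_trip_random_transforms(self, rng):
        for _ in range(200):
            t = SimilarityTransform(
                scale=float(rng.uniform(0.5, 3.0)),
                rotation=float(rng.uniform(-np.pi, np.pi)),
                tx=float(rng.uniform(-1e3, 1e3)),
                ty=float(rng.uniform(-1e3, 1e3)),
            )
            pts = rng.uniform(-500, 500, (7, 2))
            back = t.inverse()(t(pts))
            assert np.abs(back - pts).max() < 1e-9

    def test_compose_is_associative(self, rng):
        ts = [
            SimilarityTransform(float(rng.uniform(0.5, 2)), float(rng.uniform(-3, 3)),
                                float(rng.uniform(-10, 10)), float(rng.uniform(-10, 10)))
            for _ in range(3)
        ]
        a = ts[0].compose(ts[1]).compose(ts[2])
        b = ts[0].compose(ts[1].compose(ts[2]))
        assert np.allclose(a.matrix, b.matrix, atol=1e-9)

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValueError):
            SimilarityTransform(scale=0.0)


class TestFit:
    def test_exact_recovery_three_points(self):
        t = SimilarityTransform(1.5, np.pi / 4, 10.0, 10.0)
        src = np.array([[0.0, 0.0], [5.0, 1.0], [2.0, 7.0]])
        fit, rms = fit_similarity_lsq(src, t(src))
        assert fit.scale == pytest.approx(1.5, abs=1e-9)
        assert fit.rotation == pytest.approx(np.pi / 4, abs=1e-9)
        assert (fit.tx, fit.ty) == (pytest.approx(10, abs=1e-9),) * 2
        assert rms < 1e-9

    def test_identity_data(self):
        src = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        fit, _ = fit_similarity_lsq(src, src)
        assert fit.scale == pytest.approx(1.0)
        assert fit.rotation == pytest.approx(0.0)
        assert (fit.tx, fit.ty) == (pytest.approx(0.0), pytest.approx(0.0))

    def test_noisy_fit_residual_matches_noise(self, rng):
        """Residual RMS tracks the injected noise and recovered parameters
        stay within Monte-Carlo scatter of the truth."""
        t = SimilarityTransform(2.0, 0.3, -50.0, 20.0)
        src = rng.uniform(0, 200, (200, 2))
        sigma = 0.5
        scales, rots, rmss = [], [], []
        for _ in range(30):
            dst = t(src) + rng.normal(0, sigma, src.shape)
            fit, rms = fit_similarity_lsq(src, dst)
            scales.append(fit.scale)
            rots.append(fit.rotation)
            rmss.append(rms)
        assert np.mean(rmss) == pytest.approx(sigma * np.sqrt(2), rel=0.15)
        assert np.mean(scales) == pytest.approx(2.0, abs=0.01)
        assert np.mean(rots) == pytest.approx(0.3, abs=0.01)

    def test_coincident_points_rejected(self):
        src = np.zeros((4, 2))
        with pytest.raises(ValueError, match="degenerate"):
            fit_similarity_lsq(src, src + 1.0)

    def test_exact_recovery_over_random_transform_family(self, rng):
        for _ in range(50):
            t = SimilarityTransform(
                float(rng.uniform(0.5, 3)), float(rng.uniform(-np.pi, np.pi)),
                float(rng.uniform(-1e3, 1e3)), float(rng.uniform(-1e3, 1e3)),
            )
            src = rng.uniform(-100, 100, (3, 2))
            if np.linalg.matrix_rank(src - src.mean(0)) < 1:
                continue
            fit, _ = fit_similarity_lsq(src, t(src))
            assert fit.scale == pytest.approx(t.scale, rel=1e-6)
            assert np.abs(np.angle(np.exp(1j * (fit.rotation - t.rotation)))) < 1e-6
            assert fit.tx == pytest.approx(t.tx, abs=1e-5)


class TestDetect:
    def test_blank_image_empty_set(self):
        assert len(detect_spots(np.zeros((32, 32)), 10.0)) == 0

    def test_close_pair_dropped_and_flagged(self):
        img = np.zeros((40, 40))
        for cx in (18.0, 21.0):  # two spots 3 px apart, min_separation 4
            yy, xx = np.mgrid[0:40, 0:40]
            img += 100 * np.exp(-((xx - cx) ** 2 + (yy - 20.0) ** 2) / (2 * 1.2 ** 2))
        spots = detect_spots(img, 10.0, min_separation=4.0)
        assert len(spots) == 0
        assert spots.n_dropped >= 1


class TestStitch:
    @staticmethod
    def _two_frames(rng, true_offset=(100.37, 0.21), n=9):
        """Frame B offset by true_offset; shared spots visible in both."""
        shared = rng.uniform([110, 10], [190, 90], (n, 2))
        a_only = rng.uniform([5, 5], [95, 95], (5, 2))
        b_only = rng.uniform([120, 10], [190, 90], (5, 2)) - true_offset
        xa = np.vstack([shared, a_only])
        xb = np.vstack([shared - true_offset, b_only])
        return {"A": xa, "B": xb}

    def test_two_frame_offset_recovered_subpixel(self, rng):
        true = np.array([100.37, 0.21])
        sets = self._two_frames(rng, true)
        res = stitch_frames(sets, [("A", "B", np.array([100.0, 0.0]))], 40.0)
        assert np.abs(res.offsets["B"] - true).max() < 0.02
        assert res.offsets["A"] == pytest.approx([0.0, 0.0])

    def test_single_frame_zero_offset(self, rng):
        res = stitch_frames({"A": rng.uniform(0, 100, (5, 2))}, [], 10.0)
        assert res.offsets["A"] == pytest.approx([0.0, 0.0])

    def test_disconnected_frame_dead_reckons_with_warning(self, rng):
        sets = {"A": rng.uniform(0, 50, (4, 2)), "B": rng.uniform(0, 50, (4, 2))}
        with pytest.warns(UserWarning, match="dead reckoning"):
            res = stitch_frames(sets, [("A", "B", np.array([500.0, 0.0]))], 10.0)
        assert ("A", "B") in res.dead_reckoned
        assert res.offsets["B"] == pytest.approx([500.0, 0.0])

    @staticmethod
    def _chain(rng, n_frames, noise, k_shared=60, step=80.0):
        """A 1xN chain of frames; each neighbor pair shares ``k_shared`` spots
        observed with independent centroid noise on both sides (cluster
        density in a real overlap strip is of this order).  Returns spot
        sets, adjacency with nominal integer offsets, and true offsets."""
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
        return (
            {f: np.vstack(p) for f, p in sets.items()},
            adj,
            true,
        )

    def test_long_chain_float_beats_integer_rounding(self):
        """Over a 200-frame chain with 0.3 px centroid noise the float
        pipeline's terminal error stays ~sqrt(N) while integer rounding of
        the pairwise offsets adds quantization error on top of it."""
        wins = 0
        n_seeds = 25
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            sets, adj, true = self._chain(rng, 200, noise=0.3)
            res_f = stitch_frames(sets, adj, 20.0, search_radius=3.0)
            res_i = stitch_frames(sets, adj, 20.0, search_radius=3.0,
                                  integer_offsets=True)
            err_f = np.linalg.norm(res_f.offsets[199] - true[199])
            err_i = np.linalg.norm(res_i.offsets[199] - true[199])
            if err_f < err_i:
                wins += 1
            assert err_f < 0.3 * np.sqrt(200) * 3  # ~sqrt(N) growth, generous cap
        assert wins >= 0.95 * n_seeds


class TestMatch:
    def test_identity_correspondence(self, rng):
        pts = rng.uniform(0, 100, (12, 2))
        pairs, frac, _ = match_point_patterns(pts, pts)
        assert frac == 1.0
        assert all(i == j for i, j in pairs)

    def test_full_correspondence_under_similarity(self, rng):
        exp = rng.uniform(0, 100, (20, 2))
        t = SimilarityTransform(2.0, np.deg2rad(30), 50.0, -20.0)
        obs = t.inverse()(exp)
        pairs, frac, fit = match_point_patterns(obs, exp)
        assert frac == 1.0
        assert all(i == j for i, j in pairs)
        assert fit.scale == pytest.approx(2.0, rel=1e-6)

    def test_decoys_excluded(self, rng):
        exp_true = rng.uniform(0, 100, (20, 2))
        t = SimilarityTransform(1.3, 0.4, 10.0, 5.0)
        obs = np.vstack([t.inverse()(exp_true), rng.uniform(200, 300, (10, 2))])
        exp = np.vstack([exp_true, rng.uniform(-300, -200, (10, 2))])
        pairs, frac, _ = match_point_patterns(obs, exp, min_inlier_fraction=0.5)
        true_pairs = [(i, j) for i, j in pairs if i < 20 and j < 20]
        assert len(true_pairs) >= 19
        assert all(i == j for i, j in true_pairs)

    def test_invariant_to_pre_transform_of_observed(self, rng):
        exp = rng.uniform(0, 100, (15, 2))
        base = match_point_patterns(exp, exp)[0]
        for t in (
            SimilarityTransform(0.7, 1.2, 300.0, -40.0),
            SimilarityTransform(2.5, -2.0, -5.0, 8.0),
        ):
            pairs, frac, _ = match_point_patterns(t(exp), exp)
            assert frac == 1.0
            assert pairs == base

    def test_wrong_region_raises(self, rng):
        obs = rng.uniform(0, 100, (10, 2))
        exp = rng.uniform(0, 100, (10, 2))  # unrelated pattern
        with pytest.raises((NoMatchError,)):
            match_point_patterns(obs, exp, min_inlier_fraction=0.9,
                                 descriptor_tol=1e-4, match_tol=0.05)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            match_point_patterns(np.zeros((2, 2)), np.zeros((5, 2)))


class TestPlan:
    def test_96_targets_fill_plate_in_order(self):
        xy = {f"r{i:02d}": (float(i), 0.0) for i in range(96)}
        idx = build_coordinate_index(sorted(xy), xy)
        plan = map_and_plan(idx, SimilarityTransform(), laser_radius=0.5)
        wells = list(plan.table["well"])
        assert wells[:13] == ["A1", "A2", "A3", "A4", "A5", "A6", "A7", "A8",
                              "A9", "A10", "A11", "A12", "B1"]
        assert wells[-1] == "H12"
        assert plan.table["well"].is_unique

    def test_collision_pair_flagged(self):
        xy = {"a": (0.0, 0.0), "b": (1.0, 0.0), "c": (50.0, 50.0)}
        idx = build_coordinate_index(["a", "b", "c"], xy)
        plan = map_and_plan(idx, SimilarityTransform(), laser_radius=3.0)
        flags = dict(zip(plan.table["read_id"], plan.table["collision"]))
        assert flags["a"] and flags["b"] and not flags["c"]

    def test_capacity_spills_to_next_plate(self):
        xy = {f"r{i:03d}": (float(i), float(i % 7)) for i in range(100)}
        idx = build_coordinate_index(sorted(xy), xy)
        plan = map_and_plan(idx, SimilarityTransform(), laser_radius=0.1)
        assert set(plan.table["plate"]) == {1, 2}
        assert (plan.table["plate"] == 2).sum() == 4

    def test_planned_stage_positions_match_simulator_truth(self, rng):
        """End to end: stitched pixels + fitted transform reproduce the
        layout's true stage coordinates."""
        from cloneval.simulate import ChipLayoutConfig, build_chip_layout

        cfg = ChipLayoutConfig(frame_grid=(1, 1), frame_size=(400, 400),
                               overlap=30.0, min_separation=8.0)
        layout = build_chip_layout(cfg, [f"r{i:03d}" for i in range(60)], rng)
        idx = build_coordinate_index(
            layout.read_ids,
            {rid: tuple(p) for rid, p in zip(layout.read_ids, layout.pixel)},
        )
        fit, _ = fit_similarity_lsq(layout.pixel[:30], layout.stage[:30])
        plan = map_and_plan(idx, fit, laser_radius=2.0)
        truth = {rid: s for rid, s in zip(layout.read_ids, layout.stage)}
        for row in plan.table.itertuples():
            assert np.hypot(
                row.stage_x - truth[row.read_id][0],
                row.stage_y - truth[row.read_id][1],
            ) < 1e-6
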