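"""Constrained landmark search: windows, iteration behaviour and archives."""

import numpy as np
import pytest

from cephaloc.clm import (StageConfig, TwoStageModel, clm_iterate,
                          compute_vote_grids, constrained_fit, load_model,
                          save_model, search, search_range, train_stage)
from cephaloc.presets import compact, train_system
from cephaloc.shape import fit_params, similarity_fit
from cephaloc.synth import SyntheticSpec, sample_case

from conftest import frame_errors

MICRO = StageConfig(frame_width=50, ps=10, tr=6.0, sr_a=1.0, sr_c=6.0,
                    n_features=60, n_trees=6, samples_per_image=10)


class TestSearchRange:
    @pytest.mark.parametrize("pr,a,c,expected", [
        (0.0, 0.3, 7.0, 7.0),     # improved refinement setting
        (10.0, 0.3, 7.0, 10.0),
        (10.0, 1.0, 15.0, 25.0),  # original bone-contour setting
    ])
    def test_published_coefficients(self, pr, a, c, expected):
        assert search_range(pr, a, c) == pytest.approx(expected)

    def test_negative_position_range_rejected(self):
        with pytest.raises(ValueError):
            search_range(-1.0, 0.3, 7.0)


class TestTraining:
    def test_zero_training_range_makes_position_stampers(self, train_cases):
        cases = train_cases[:6]
        cfg = StageConfig(frame_width=50, ps=10, tr=0.0, sr_a=1.0, sr_c=5.0,
                          n_features=40, n_trees=4, samples_per_image=8)
        model = train_stage([c.image for c in cases],
                            [c.truth.points for c in cases], cfg, rng_seed=3)
        for forest in model.forests:
            for tree in forest.trees:
                assert np.max(np.abs(tree.values)) < 1e-9

    def test_too_few_images_rejected(self, train_cases):
        with pytest.raises(ValueError):
            train_stage([train_cases[0].image], [train_cases[0].truth.points],
                        MICRO, rng_seed=0)

    def test_position_ranges_are_positive_and_finite(self, trained_system):
        _, ts = trained_system
        for model in (ts.coarse, ts.fine):
            assert np.all(model.pr >= 0)
            assert np.all(np.isfinite(model.pr))
            assert np.all(model.sr > 0)


class TestIteration:
    def test_truth_is_a_near_fixed_point_on_training_images(self, trained_system,
                                                            train_cases):
        _, ts = trained_system
        case = train_cases[0]
        out, _ = clm_iterate(ts.fine, case.image, case.truth.points)
        fit = similarity_fit(ts.fine.shape_model.mean, case.truth.points)
        rms = np.sqrt(((out - case.truth.points) ** 2).sum(axis=1).mean()) / fit.scale
        assert rms < 2.0

    def test_displaced_start_improves_in_most_cases(self, trained_system,
                                                    test_cases):
        _, ts = trained_system
        rng = np.random.default_rng(0)
        improved = 0
        for case in test_cases[:10]:
            fit = similarity_fit(ts.coarse.shape_model.mean, case.truth.points)
            phi = rng.uniform(0, 2 * np.pi)
            offset = 5.0 * fit.scale * np.array([np.cos(phi), np.sin(phi)])
            start = case.truth.points + offset
            out, _ = clm_iterate(ts.coarse, case.image, start)
            rms0 = np.sqrt(((start - case.truth.points) ** 2).sum(axis=1).mean())
            rms1 = np.sqrt(((out - case.truth.points) ** 2).sum(axis=1).mean())
            improved += rms1 < rms0
        assert improved >= 9

    def test_rigid_template_matches_pose_grid_oracle(self):
        # a zero-variance shape model (all training shapes identical up to
        # similarity) reduces the constrained fit to rigid template
        # placement, which a brute-force search over a coarse pose grid must
        # reproduce on a tiny instance
        spec = SyntheticSpec(n=12, seed=21, mode_sds=(0.0, 0.0, 0.0), n_clutter=0)
        cases = [sample_case(spec, i) for i in range(12)]
        model = train_stage([c.image for c in cases[:10]],
                            [c.truth.points for c in cases[:10]], MICRO, rng_seed=5)
        assert model.shape_model.n_modes == 0
        case = cases[11]
        fit = similarity_fit(model.shape_model.mean, case.truth.points)
        start = case.truth.points + 2.5 * fit.scale * np.array([0.8, -0.6])
        pose, cur_f, grids, _ = compute_vote_grids(model, case.image, start)
        out = constrained_fit(model, pose, grids, cur_f)

        smoothed = [g.smoothed(model.config.smooth) if g is not None else None
                    for g in grids]

        def objective(points_f):
            total = 0.0
            for l, g in enumerate(grids):
                if g is None:
                    continue
                cx = int(round(points_f[l, 0] - g.offset[0]))
                cy = int(round(points_f[l, 1] - g.offset[1]))
                if 0 <= cy < smoothed[l].shape[0] and 0 <= cx < smoothed[l].shape[1]:
                    total += smoothed[l][cy, cx]
            return total

        mean_f = model.shape_model.mean + model.pad
        best_val, best_pts = -1.0, None
        for dx in np.arange(-6, 6.01, 0.5):
            for dy in np.arange(-6, 6.01, 0.5):
                for s in (0.97, 1.0, 1.03):
                    cand = (mean_f - mean_f.mean(axis=0)) * s \
                        + mean_f.mean(axis=0) + [dx, dy]
                    val = objective(cand)
                    if val > best_val:
                        best_val, best_pts = val, cand
        out_f = pose.to_frame(out) + model.pad
        # the alternating fit should reach (essentially) the brute-force
        # optimum of the vote-maximisation objective
        assert objective(out_f) >= 0.9 * best_val
        assert np.mean(np.hypot(*(out_f - best_pts).T)) <= 2.0

    def test_output_satisfies_shape_constraint(self, trained_system,
                                               search_results):
        _, ts = trained_system
        lim = 3.0 * np.sqrt(ts.fine.shape_model.variances)
        for res in search_results:
            fit = fit_params(ts.fine.shape_model, res.points)
            assert np.all(np.abs(fit.b) <= lim + 1e-9)

    def test_iteration_is_deterministic(self, trained_system, test_cases):
        _, ts = trained_system
        case = test_cases[0]
        a, sa = clm_iterate(ts.fine, case.image, case.truth.points)
        b, sb = clm_iterate(ts.fine, case.image, case.truth.points)
        assert np.array_equal(a, b) and np.array_equal(sa, sb)


class TestSearch:
    def test_result_structure(self, trained_system, search_results):
        _, ts = trained_system
        for res in search_results:
            assert res.points.shape == (19, 2)
            assert res.spreads.shape == (19,)
            assert np.all(res.spreads >= 0)
            assert dict(res.stages).keys() == {"coarse", "fine"}

    def test_landmark_count_mismatch_rejected(self, trained_system, train_cases):
        det, ts = trained_system
        cases = train_cases[:6]
        ten_point = [c.truth.points[:10] for c in cases]
        other = train_stage([c.image for c in cases], ten_point,
                            MICRO, rng_seed=2)
        broken = TwoStageModel(coarse=ts.coarse, fine=other)
        with pytest.raises(ValueError):
            search(broken, det, cases[0].image)

    def test_more_training_data_does_not_hurt(self, synth_spec, test_cases):
        # paired comparison: same held-out cases, training set doubled
        cases = [sample_case(synth_spec, i) for i in range(32)]
        errs = {}
        for n in (16, 32):
            cfg = compact()
            cfg.coarse = StageConfig(frame_width=50, ps=10, tr=7.5, sr_a=1.0,
                                     sr_c=7.5, n_features=80, n_trees=8,
                                     samples_per_image=10)
            cfg.fine = StageConfig(frame_width=120, ps=7, tr=7.2, sr_a=0.3,
                                   sr_c=1.7, n_features=80, n_trees=8,
                                   samples_per_image=10)
            det, ts = train_system([c.image for c in cases[:n]],
                                   [c.truth.points for c in cases[:n]],
                                   cfg, seed=7)
            per_case = []
            for case in test_cases[:8]:
                res = search(ts, det, case.image)
                per_case.append(frame_errors(ts, case, res.points).mean())
            errs[n] = float(np.mean(per_case))
        assert errs[32] <= errs[16] * 1.35 + 0.5


class TestArchive:
    def test_save_load_round_trip_and_byte_identity(self, trained_system,
                                                    test_cases, tmp_path):
        det, ts = trained_system
        p1, p2 = tmp_path / "m1.bin", tmp_path / "m2.bin"
        save_model(p1, det, ts, seed=1)
        det2, ts2, manifest = load_model(p1)
        assert manifest["n_landmarks"] == 19
        save_model(p2, det2, ts2, seed=1)
        assert p1.read_bytes() == p2.read_bytes()
        case = test_cases[0]
        r1 = search(ts, det, case.image)
        r2 = search(ts2, det2, case.image)
        assert np.array_equal(r1.points, r2.points)
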