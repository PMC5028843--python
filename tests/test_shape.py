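"""Procrustes alignment, the PCA shape model and constrained fitting."""

import numpy as np
import pytest

from cephaloc.imaging import Pose
from cephaloc.shape import (ShapeParams, align_shapes, build_model, fit_params,
                            shape_from_params, similarity_fit)


def random_similarity(rng):
    return Pose(centre=tuple(rng.uniform(-50, 50, 2)),
                scale=float(rng.uniform(0.5, 2.0)),
                angle=float(rng.uniform(-np.pi, np.pi)),
                ref=(0.0, 0.0))


@pytest.fixture(scope="module")
def base_shape():
    rng = np.random.default_rng(42)
    return rng.random((19, 2)) * 100


@pytest.fixture(scope="module")
def shape_model(base_shape):
    rng = np.random.default_rng(43)
    shapes = [base_shape + rng.normal(0, 2, base_shape.shape) for _ in range(25)]
    aligned, _ = align_shapes(shapes)
    return build_model(aligned, var_kept=0.98, frame_width=200)


class TestAlignment:
    def test_identical_shapes_align_exactly(self, base_shape):
        aligned, mean = align_shapes([base_shape, base_shape.copy()])
        assert np.allclose(aligned[0], aligned[1], atol=1e-10)
        assert np.allclose(aligned[0], mean, atol=1e-8)

    def test_similarity_copies_coincide_after_alignment(self, base_shape):
        rng = np.random.default_rng(0)
        moved = random_similarity(rng).to_image(base_shape)
        aligned, _ = align_shapes([base_shape, moved])
        assert np.max(np.abs(aligned[0] - aligned[1])) < 1e-8

    def test_alignment_invariant_to_input_similarity(self, base_shape):
        rng = np.random.default_rng(1)
        shapes = [base_shape + rng.normal(0, 3, base_shape.shape) for _ in range(20)]
        moved = [random_similarity(rng).to_image(s) for s in shapes]
        _, mean_a = align_shapes(shapes)
        _, mean_b = align_shapes(moved)
        # means agree up to a residual similarity; align the two means
        fit = similarity_fit(mean_b, mean_a)
        assert np.max(np.abs(fit.to_image(mean_b) - mean_a)) < 1e-6

    def test_degenerate_shape_rejected(self):
        with pytest.raises(ValueError):
            align_shapes([np.zeros((5, 2)), np.ones((5, 2))])


class TestModelBuilding:
    def test_single_known_mode_recovered(self, base_shape):
        rng = np.random.default_rng(2)
        mode = rng.normal(size=base_shape.size)
        mode -= mode.mean()
        mode /= np.linalg.norm(mode)
        shapes = [base_shape + (rng.normal(0, 4) * mode).reshape(-1, 2)
                  for _ in range(40)]
        aligned, _ = align_shapes(shapes)
        model = build_model(aligned, var_kept=0.95, frame_width=100)
        assert model.n_modes >= 1
        # dominant retained mode should be (anti)parallel to the injected one
        # in the aligned-normalised space; compare directions via cosine
        lead = model.modes[:, 0]
        # re-express the injected mode in aligned space by projecting the
        # aligned data itself: leading mode of the data is the oracle here
        data = np.stack([s.ravel() for s in aligned])
        data -= data.mean(axis=0)
        _, _, vt = np.linalg.svd(data, full_matrices=False)
        cos = abs(float(lead @ vt[0]))
        assert cos > 0.999

    def test_identical_shapes_give_zero_modes(self, base_shape):
        aligned, _ = align_shapes([base_shape.copy() for _ in range(5)])
        model = build_model(aligned, var_kept=0.98, frame_width=100)
        assert model.n_modes == 0

    def test_full_variance_reconstructs_training_shapes(self, base_shape):
        rng = np.random.default_rng(3)
        shapes = [base_shape + rng.normal(0, 2, base_shape.shape) for _ in range(8)]
        aligned, _ = align_shapes(shapes)
        model = build_model(aligned, var_kept=1.0, frame_width=150)
        assert model.n_modes <= len(shapes) - 1
        for s in aligned:
            params = fit_params(model, s)
            rec = shape_from_params(model, ShapeParams(b=params.b, pose=params.pose))
            assert np.max(np.abs(rec - s)) < 1e-6

    def test_modes_are_orthonormal(self, shape_model):
        P = shape_model.modes
        assert np.allclose(P.T @ P, np.eye(shape_model.n_modes), atol=1e-10)


class TestParamFitting:
    def test_mean_shape_under_identity_gives_zero_b(self, shape_model):
        params = fit_params(shape_model, shape_model.mean)
        assert np.max(np.abs(params.b)) < 1e-8
        assert params.pose.scale == pytest.approx(1.0, abs=1e-9)

    def test_generation_recovery(self, shape_model):
        rng = np.random.default_rng(4)
        b = rng.uniform(-1, 1, shape_model.n_modes) * np.sqrt(shape_model.variances)
        pose = Pose(centre=(321.0, 222.0), scale=2.3, angle=0.4,
                    ref=shape_model.frame_centre)
        target = shape_from_params(shape_model, ShapeParams(b=b, pose=pose))
        fit = fit_params(shape_model, target)
        assert np.max(np.abs(fit.b - b)) < 1e-6
        assert abs(fit.pose.scale - pose.scale) < 1e-6
        assert abs(fit.pose.angle - pose.angle) < 1e-6
        assert np.max(np.abs(np.asarray(fit.pose.centre) - pose.centre)) < 1e-6
        assert np.max(np.abs(fit.residuals)) < 1e-6

    def test_clamp_engages_exactly_at_three_sd(self, shape_model):
        b = np.zeros(shape_model.n_modes)
        b[0] = 10.0 * np.sqrt(shape_model.variances[0])
        pose = Pose(centre=(50.0, 60.0), scale=1.5, angle=-0.2,
                    ref=shape_model.frame_centre)
        target = shape_from_params(shape_model, ShapeParams(b=b, pose=pose))
        fit = fit_params(shape_model, target)
        assert fit.b[0] == 3.0 * np.sqrt(shape_model.variances[0])

    def test_fit_invariant_to_target_similarity(self, shape_model):
        rng = np.random.default_rng(5)
        b = 0.5 * np.sqrt(shape_model.variances)
        pose = Pose(centre=(10.0, 20.0), scale=1.2, angle=0.1,
                    ref=shape_model.frame_centre)
        target = shape_from_params(shape_model, ShapeParams(b=b, pose=pose))
        extra = random_similarity(rng)
        fit2 = fit_params(shape_model, extra.to_image(target))
        assert np.max(np.abs(fit2.b - b)) < 1e-6

    def test_shape_from_params_matches_independent_chain(self, shape_model):
        rng = np.random.default_rng(6)
        b = rng.normal(0, 1, shape_model.n_modes) * np.sqrt(shape_model.variances)
        r = rng.normal(0, 0.5, shape_model.mean.shape)
        pose = Pose(centre=(5.0, -3.0), scale=0.8, angle=1.1,
                    ref=shape_model.frame_centre)
        out = shape_from_params(shape_model, ShapeParams(b=b, pose=pose, residuals=r))
        # independently coded transform chain
        pts = shape_model.mean + (shape_model.modes @ b).reshape(-1, 2) + r
        c, s = np.cos(pose.angle), np.sin(pose.angle)
        R = pose.scale * np.array([[c, -s], [s, c]])
        expected = (pts - shape_model.frame_centre) @ R.T + np.array(pose.centre)
        assert np.allclose(out, expected, atol=1e-10)

    def test_all_zero_weights_rejected(self, shape_model):
        with pytest.raises(ValueError):
            fit_params(shape_model, shape_model.mean,
                       weights=np.zeros(shape_model.n_points))
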