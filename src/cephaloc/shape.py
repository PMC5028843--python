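"""Statistical shape modelling for landmark configurations.

A shape is an ordered ``(k, 2)`` array of ``(x, y)`` points.  Shapes are
aligned by generalized Procrustes analysis (similarity transforms), a linear
point-distribution model is built by PCA of the aligned shapes, and new point
configurations are expressed as

    x_l = T_theta( mean_l + (P b)_l + r_l )

where ``b`` weights the deformation modes ``P``, ``r_l`` are small per-point
residuals and ``T_theta`` is a global similarity transform.  Mode weights are
hard-clamped to three standard deviations per mode, the usual constrained
local model regularisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .imaging import Pose

__all__ = [
    "ShapeModel",
    "ShapeParams",
    "align_shapes",
    "build_model",
    "shape_from_params",
    "fit_params",
    "similarity_fit",
]

CLAMP_SD = 3.0


def _as_shape(s: np.ndarray) -> np.ndarray:
    a = np.asarray(s, dtype=np.float64)
    if a.ndim != 2 or a.shape[1] != 2 or a.shape[0] < 2:
        raise ValueError("a shape must be a (k, 2) array with k >= 2")
    return a


def similarity_fit(src: np.ndarray, dst: np.ndarray,
                   weights: np.ndarray | None = None) -> Pose:
    """Weighted least-squares similarity transform mapping ``src`` onto ``dst``.

    Returns a :class:`Pose` whose ``ref`` is the weighted centroid of ``src``.
    """
    src = _as_shape(src)
    dst = _as_shape(dst)
    if weights is None:
        w = np.ones(len(src))
    else:
        w = np.asarray(weights, dtype=np.float64)
        if np.any(w < 0) or not np.any(w > 0):
            raise ValueError("weights must be non-negative and not all zero")
    wsum = w.sum()
    c_src = (src * w[:, None]).sum(axis=0) / wsum
    c_dst = (dst * w[:, None]).sum(axis=0) / wsum
    X = src - c_src
    Y = dst - c_dst
    denom = (w * (X ** 2).sum(axis=1)).sum()
    if denom <= 0:
        raise ValueError("degenerate source shape (all points coincident)")
    a = (w * (X * Y).sum(axis=1)).sum() / denom
    b = (w * (X[:, 0] * Y[:, 1] - X[:, 1] * Y[:, 0])).sum() / denom
    scale = float(np.hypot(a, b))
    if scale <= 0:
        raise ValueError("degenerate similarity fit (zero scale)")
    angle = float(np.arctan2(b, a))
    return Pose(centre=tuple(c_dst), scale=scale, angle=angle, ref=tuple(c_src))


def _normalise(shape: np.ndarray) -> np.ndarray:
    """Centre a shape and scale it to unit RMS point distance."""
    c = shape.mean(axis=0)
    centred = shape - c
    rms = np.sqrt((centred ** 2).sum(axis=1).mean())
    if rms <= 0:
        raise ValueError("degenerate shape (all points coincident)")
    return centred / rms


def align_shapes(shapes: list[np.ndarray], tol: float = 1e-10,
                 max_iter: int = 50) -> tuple[list[np.ndarray], np.ndarray]:
    """Generalized Procrustes alignment of a set of shapes.

    Each shape is similarity-transformed to minimise its summed squared
    distance to the evolving mean; the mean is renormalised to centroid zero
    and unit RMS size every round.  Returns the aligned shapes and the mean.
    """
    if len(shapes) < 2:
        raise ValueError("need at least two shapes to align")
    arrs = [_as_shape(s) for s in shapes]
    k = arrs[0].shape[0]
    if any(a.shape[0] != k for a in arrs):
        raise ValueError("all shapes must have the same point count")
    mean = _normalise(arrs[0])
    for _ in range(max_iter):
        aligned = [similarity_fit(a, mean).to_image(a) for a in arrs]
        new_mean = _normalise(np.mean(aligned, axis=0))
        done = np.max(np.abs(new_mean - mean)) < tol
        mean = new_mean
        if done:
            break
    aligned = [similarity_fit(a, mean).to_image(a) for a in arrs]
    return aligned, mean


@dataclass
class ShapeModel:
    """Linear point-distribution model in a standardised reference frame.

    ``mean`` is the mean shape in frame pixels; ``modes`` has orthonormal
    columns (one per mode, length 2k, xy-interleaved); ``variances`` are the
    per-mode eigenvalues in frame px².  ``frame_scale`` is the factor from
    normalised Procrustes units to frame pixels, used to relate frames of
    different resolution.
    """

    mean: np.ndarray
    modes: np.ndarray
    variances: np.ndarray
    frame_width: int
    frame_height: int
    frame_scale: float

    @property
    def n_points(self) -> int:
        return self.mean.shape[0]

    @property
    def n_modes(self) -> int:
        return self.modes.shape[1]

    @property
    def frame_centre(self) -> tuple[float, float]:
        return (self.frame_width / 2.0, self.frame_height / 2.0)

    def clamp(self, b: np.ndarray) -> np.ndarray:
        lim = CLAMP_SD * np.sqrt(self.variances)
        return np.clip(b, -lim, lim)

    def pose_for(self, image_points: np.ndarray,
                 weights: np.ndarray | None = None) -> Pose:
        """Similarity pose mapping the mean shape onto image points, anchored
        at the frame centre."""
        fit = similarity_fit(self.mean, _as_shape(image_points), weights)
        centre = fit.to_image(np.asarray(self.frame_centre))
        return Pose(centre=tuple(centre), scale=fit.scale, angle=fit.angle,
                    ref=self.frame_centre)

    def to_arrays(self) -> dict[str, np.ndarray]:
        return {
            "mean": self.mean,
            "modes": self.modes,
            "variances": self.variances,
            "dims": np.array([self.frame_width, self.frame_height], dtype=np.int64),
            "frame_scale": np.array([self.frame_scale]),
        }

    @classmethod
    def from_arrays(cls, a: dict[str, np.ndarray]) -> "ShapeModel":
        return cls(mean=a["mean"], modes=a["modes"], variances=a["variances"],
                   frame_width=int(a["dims"][0]), frame_height=int(a["dims"][1]),
                   frame_scale=float(a["frame_scale"][0]))


@dataclass
class ShapeParams:
    """Parameters of a shape instance: mode weights, pose and residuals."""

    b: np.ndarray
    pose: Pose
    residuals: np.ndarray = field(default=None)  # type: ignore[assignment]


BOX_FILL = 0.75  # fraction of frame width occupied by the mean-shape bounding box


def build_model(aligned: list[np.ndarray], var_kept: float = 0.98,
                frame_width: int = 500) -> ShapeModel:
    """PCA point-distribution model from Procrustes-aligned shapes.

    The number of modes is the smallest count capturing ``var_kept`` of total
    variance.  The mean shape is scaled so its bounding box spans
    ``BOX_FILL * frame_width`` horizontally and centred in a frame whose
    height keeps the same absolute margins.
    """
    if len(aligned) < 3:
        raise ValueError("need at least three shapes to build a model")
    data = np.stack([_as_shape(s).ravel() for s in aligned])
    mean_n = data.mean(axis=0)
    centred = data - mean_n
    # eigen-decomposition of the shape covariance via SVD of the data matrix
    _, svals, vt = np.linalg.svd(centred, full_matrices=False)
    var = svals ** 2 / (len(aligned) - 1)
    total = var.sum()
    if total <= 1e-24:
        t = 0
    else:
        frac = np.cumsum(var) / total
        t = int(np.searchsorted(frac, var_kept - 1e-12) + 1)
        t = min(t, int((var > total * 1e-12).sum()), data.shape[1] - 1)
    modes_n = vt[:t].T
    var_n = var[:t]

    mean_pts = mean_n.reshape(-1, 2)
    lo = mean_pts.min(axis=0)
    hi = mean_pts.max(axis=0)
    bbox = hi - lo
    frame_scale = BOX_FILL * frame_width / bbox[0]
    margin = (1.0 - BOX_FILL) * frame_width / 2.0
    frame_height = int(np.ceil(bbox[1] * frame_scale + 2 * margin))
    centre_n = (lo + hi) / 2.0
    mean_f = (mean_pts - centre_n) * frame_scale + \
        np.array([frame_width / 2.0, frame_height / 2.0])
    return ShapeModel(mean=mean_f, modes=modes_n, variances=var_n * frame_scale ** 2,
                      frame_width=int(frame_width), frame_height=frame_height,
                      frame_scale=float(frame_scale))


def shape_from_params(model: ShapeModel, params: ShapeParams) -> np.ndarray:
    """Instantiate image-space points from model parameters (modes, then
    residuals, then the global similarity)."""
    b = np.asarray(params.b, dtype=np.float64)
    if b.shape != (model.n_modes,):
        raise ValueError(f"b must have length {model.n_modes}")
    pts = model.mean + (model.modes @ b).reshape(-1, 2)
    if params.residuals is not None:
        pts = pts + np.asarray(params.residuals, dtype=np.float64)
    return params.pose.to_image(pts)


def fit_params(model: ShapeModel, target: np.ndarray,
               weights: np.ndarray | None = None,
               tol: float = 1e-9, max_iter: int = 50) -> ShapeParams:
    """Fit pose and clamped mode weights to image-space target points.

    Weighted alternating least squares: solve for ``b`` at fixed pose, clamp
    each mode weight to ±3 sd, re-fit the similarity pose to the current model
    points, and iterate until the model points move less than ``tol`` frame px.
    Residuals are the frame-space discrepancy left after the clamped fit.
    """
    target = _as_shape(target)
    if target.shape[0] != model.n_points:
        raise ValueError("target point count does not match the model")
    if weights is None:
        w = np.ones(model.n_points)
    else:
        w = np.asarray(weights, dtype=np.float64)
        if np.any(w < 0) or not np.any(w > 0):
            raise ValueError("weights must be non-negative and not all zero")
    pose = model.pose_for(target, w)
    b = np.zeros(model.n_modes)
    model_pts = model.mean.copy()
    w2 = np.repeat(w, 2)
    P = model.modes
    for _ in range(max_iter):
        tgt_f = pose.to_frame(target)
        d = (tgt_f - model.mean).ravel()
        if model.n_modes:
            M = P.T @ (P * w2[:, None])
            b = np.linalg.solve(M, P.T @ (w2 * d))
            b = model.clamp(b)
        new_pts = model.mean + (P @ b).reshape(-1, 2)
        fit = similarity_fit(new_pts, target, w)
        centre = fit.to_image(np.asarray(model.frame_centre))
        pose = Pose(centre=tuple(centre), scale=fit.scale, angle=fit.angle,
                    ref=model.frame_centre)
        move = np.max(np.abs(new_pts - model_pts)) if model_pts is not None else np.inf
        model_pts = new_pts
        if move < tol:
            break
    residuals = pose.to_frame(target) - model_pts
    return ShapeParams(b=b, pose=pose, residuals=residuals)
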