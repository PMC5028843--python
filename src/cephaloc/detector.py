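"""Global object detection by Random-Forest regression voting.

A single *pseudo* landmark — the centre of a reference frame that encompasses
all 19 landmarks — is predicted by a regression forest from patches sampled
across the frame.  At detection time the forest is slid over the image at a
grid of scales and orientations; every tree at every window position casts a
vote for the frame centre into an accumulator array per (scale, angle).
Smoothed voting peaks are candidates for the object's pose, and the stored
mean shape mapped through the top candidate's pose initialises the landmark
search.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .imaging import FeaturePool, Image, Pose, integral_image, resample_to_frame
from .forest import LandmarkForest, sample_training_set, train_forest, cast_votes
from .shape import align_shapes, build_model

__all__ = ["DetectorConfig", "DetectorModel", "DetectionCandidate",
           "train_detector", "detect", "init_landmarks"]

log = logging.getLogger(__name__)


@dataclass
class DetectorConfig:
    frame_width: int = 100
    ps: int = 20
    n_features: int = 200
    n_trees: int = 10
    samples_per_image: int = 60
    scan_step: int = 2
    # scale grid: multiples of the median training scale, x1.25 steps over [0.7, 1.4]
    scale_factors: tuple[float, ...] = (0.7, 0.875, 1.094, 1.367)
    scan_angles: tuple[float, ...] = (-np.deg2rad(15.0), 0.0, np.deg2rad(15.0))
    smooth: int = 3
    min_samples_leaf: int = 10


@dataclass
class DetectionCandidate:
    pose: Pose
    score: float


@dataclass
class DetectorModel:
    """Trained global detector: pseudo-landmark forest + mean shape + scan grid."""

    forest: LandmarkForest
    frame_width: int
    frame_height: int
    mean_shape: np.ndarray          # frame coords
    base_scale: float               # median training pose scale (image px / frame px)
    scale_factors: tuple[float, ...]
    scan_angles: tuple[float, ...]
    scan_step: int
    smooth: int

    @property
    def frame_centre(self) -> np.ndarray:
        return np.array([self.frame_width / 2.0, self.frame_height / 2.0])

    def to_arrays(self) -> dict[str, np.ndarray]:
        out = {f"forest_{k}": v for k, v in self.forest.to_arrays().items()}
        out["mean_shape"] = self.mean_shape
        out["scalars"] = np.array([self.frame_width, self.frame_height,
                                   self.scan_step, self.smooth], dtype=np.int64)
        out["base_scale"] = np.array([self.base_scale])
        out["scale_factors"] = np.asarray(self.scale_factors, dtype=np.float64)
        out["scan_angles"] = np.asarray(self.scan_angles, dtype=np.float64)
        return out

    @classmethod
    def from_arrays(cls, a: dict[str, np.ndarray]) -> "DetectorModel":
        forest = LandmarkForest.from_arrays(
            {k[len("forest_"):]: v for k, v in a.items() if k.startswith("forest_")})
        fw, fh, step, smooth = (int(v) for v in a["scalars"])
        return cls(forest=forest, frame_width=fw, frame_height=fh,
                   mean_shape=a["mean_shape"], base_scale=float(a["base_scale"][0]),
                   scale_factors=tuple(float(v) for v in a["scale_factors"]),
                   scan_angles=tuple(float(v) for v in a["scan_angles"]),
                   scan_step=step, smooth=smooth)


def train_detector(images: list[Image], annotations: list[np.ndarray],
                   cfg: DetectorConfig = DetectorConfig(),
                   rng_seed: int = 0) -> DetectorModel:
    """Train the global detector from annotated images.

    Per image the reference pose is derived from the annotation (similarity
    fit of the mean shape); the forest learns to predict the displacement
    from a patch centre to the frame centre from patches sampled across the
    whole frame.
    """
    if len(images) < 5:
        raise ValueError("need at least 5 annotated images to train a detector")
    k = np.asarray(annotations[0]).shape[0]
    if any(np.asarray(a).shape != (k, 2) for a in annotations):
        raise ValueError("inconsistent landmark counts across annotations")
    aligned, _ = align_shapes([np.asarray(a) for a in annotations])
    model = build_model(aligned, var_kept=0.98, frame_width=cfg.frame_width)
    fw, fh = model.frame_width, model.frame_height
    centre = np.array([fw / 2.0, fh / 2.0])
    pad = cfg.ps  # allow patches centred anywhere in the frame box
    rng = np.random.default_rng(rng_seed)
    X, Y, scales = [], [], []
    for img, ann in zip(images, annotations):
        pose = model.pose_for(np.asarray(ann))
        scales.append(pose.scale)
        frame = resample_to_frame(img, pose, fw, fh, pad=pad)
        f, d = sample_training_set(
            frame, (centre[0] + pad, centre[1] + pad),
            _pool_for(cfg, rng_seed), tr=max(fw, fh) / 2.0,
            n=cfg.samples_per_image, rng=rng)
        X.append(f)
        Y.append(d)
    pool = _pool_for(cfg, rng_seed)
    forest = train_forest(np.vstack(X), np.vstack(Y), pool, tr=max(fw, fh) / 2.0,
                          n_trees=cfg.n_trees, rng_seed=rng_seed + 1,
                          min_samples_leaf=cfg.min_samples_leaf)
    return DetectorModel(
        forest=forest, frame_width=fw, frame_height=fh, mean_shape=model.mean,
        base_scale=float(np.median(scales)),
        scale_factors=cfg.scale_factors, scan_angles=cfg.scan_angles,
        scan_step=cfg.scan_step, smooth=cfg.smooth)


_POOL_CACHE: dict[tuple, FeaturePool] = {}


def _pool_for(cfg: DetectorConfig, seed: int) -> FeaturePool:
    key = (cfg.ps, cfg.n_features, seed)
    if key not in _POOL_CACHE:
        _POOL_CACHE[key] = FeaturePool.sample(
            cfg.ps, cfg.n_features, np.random.default_rng(seed ^ 0x5EED))
    return _POOL_CACHE[key]


def detect(det: DetectorModel, img: Image, max_candidates: int = 5) -> list[DetectionCandidate]:
    """Scan ``img`` over the detector's scale/angle grid and return pose
    candidates sorted by accumulated vote mass (descending)."""
    ps = det.forest.patch_size
    step = det.scan_step
    results: list[DetectionCandidate] = []
    any_grid = False
    for f in det.scale_factors:
        s = det.base_scale * f
        for ang in det.scan_angles:
            # resample the whole image into scan space: image px = s R(ang) p
            pose = Pose(centre=(0.0, 0.0), scale=s, angle=ang, ref=(0.0, 0.0))
            corners = np.array([[0, 0], [img.width - 1, 0],
                                [0, img.height - 1], [img.width - 1, img.height - 1]])
            cf = pose.to_frame(corners)
            lo = cf.min(axis=0)
            hi = cf.max(axis=0)
            shift = Pose(centre=tuple(pose.to_image(lo)), scale=s, angle=ang,
                         ref=(0.0, 0.0))
            w = int(np.floor(hi[0] - lo[0])) + 1
            h = int(np.floor(hi[1] - lo[1])) + 1
            if w < ps + 2 * step or h < ps + 2 * step:
                continue
            scan = resample_to_frame(img, shift, w, h, pad=0)
            ii = integral_image(scan)
            half = ps // 2
            x0, y0 = half, half
            x1 = w - 1 - half - (ps - 2 * half)
            y1 = h - 1 - half - (ps - 2 * half)
            if x1 <= x0 or y1 <= y0:
                continue
            any_grid = True
            vg = cast_votes(det.forest, ii, (x0, y0, x1, y1), step=step, cell=step)
            sm = vg.smoothed(det.smooth)
            local_max = (sm == ndimage.maximum_filter(sm, size=3)) & (sm > 0)
            ys, xs = np.nonzero(local_max)
            order = np.argsort(-sm[ys, xs], kind="stable")
            for i in order[: max_candidates]:
                # sub-cell refinement: vote-mass centroid around the peak
                r = 2
                yy0, yy1 = max(0, ys[i] - r), min(sm.shape[0], ys[i] + r + 1)
                xx0, xx1 = max(0, xs[i] - r), min(sm.shape[1], xs[i] + r + 1)
                win = sm[yy0:yy1, xx0:xx1]
                gy, gx = np.mgrid[yy0:yy1, xx0:xx1]
                px = (gx * win).sum() / win.sum()
                py = (gy * win).sum() / win.sum()
                cx = vg.offset[0] + px * vg.cell
                cy = vg.offset[1] + py * vg.cell
                centre_img = shift.to_image(np.array([cx, cy], dtype=np.float64))
                cand_pose = Pose(centre=tuple(centre_img), scale=s, angle=ang,
                                 ref=tuple(det.frame_centre))
                results.append(DetectionCandidate(pose=cand_pose,
                                                  score=float(sm[ys[i], xs[i]])))
    if not any_grid:
        raise ValueError("image too small for the detector scan grid")
    results.sort(key=lambda c: (-c.score, c.pose.centre[1], c.pose.centre[0]))
    return results[:max_candidates]


def init_landmarks(det: DetectorModel, pose: Pose) -> np.ndarray:
    """First estimate of all landmark points: the mean shape mapped through
    the detected pose."""
    return pose.to_image(det.mean_shape)
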