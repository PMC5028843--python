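"""RFRV-CLM landmark search: per-landmark regression-voting constrained by a
statistical shape model, applied coarse-to-fine.

Training builds, per stage, a shape model and one displacement-voting forest
per landmark from patches sampled within ``±tr`` of the true position in the
reference frame.  At search time the image is resampled into the frame at the
current pose estimate, each landmark's forest casts votes over a square
window of half-width ``sr`` around the current position, and the shape model
is fitted to the vote peaks (weighted by vote mass) under the ±3 sd mode
clamp.  The search window half-width is tied to the landmark's positional
variability across the aligned training data, ``sr = a * pr + c``; the
refinement stage uses the decreased-search-range setting ``(a, c) = (0.3, 7)``
(with ``ps`` 30 and ``tr`` ±30), the coarse stage the original
``(1.0, 15)`` setting.

A runtime early-stop rule terminates the iteration loop once every landmark's
votes agree to within a threshold: the mean distance of a landmark's votes
from their centroid, expressed in refinement-frame pixels, must be at most 4.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np

from .imaging import FeaturePool, Image, Pose, integral_image, resample_to_frame
from .forest import LandmarkForest, VoteGrid, cast_votes, sample_training_set, train_forest
from .shape import ShapeModel, align_shapes, build_model, fit_params
from .detector import DetectorModel, detect, init_landmarks

__all__ = [
    "StageConfig", "RfrvClmModel", "TwoStageModel", "SearchResult",
    "search_range", "train_stage", "clm_iterate", "search",
    "compute_vote_grids", "constrained_fit", "save_model", "load_model",
    "FINE_STAGE", "COARSE_STAGE", "ORIGINAL_FINE_STAGE",
]

log = logging.getLogger(__name__)


def search_range(pr: float, a: float, c: float) -> float:
    """Search-window half-width ``a * pr + c`` (frame px) for a landmark whose
    position varies over a range ``pr`` across the aligned training data."""
    if pr < 0:
        raise ValueError("position range pr must be non-negative")
    return a * pr + c


@dataclass
class StageConfig:
    """Training/search configuration of one RFRV-CLM resolution stage."""

    frame_width: int = 500
    ps: int = 30            # sampled patch size, frame px
    tr: float = 30.0        # training displacement range, frame px
    sr_a: float = 0.3       # search range = sr_a * pr + sr_c
    sr_c: float = 7.0
    n_features: int = 400
    n_trees: int = 10
    samples_per_image: int = 40
    min_samples_leaf: int = 10
    var_kept: float = 0.98
    smooth: int = 3
    residual_limit: float = 3.0  # max per-point deviation from the model, frame px


# the refinement-stage settings found best for isolated cephalometric
# landmarks, and the original bone-contour settings for comparison
FINE_STAGE = StageConfig(frame_width=500, ps=30, tr=30.0, sr_a=0.3, sr_c=7.0)
ORIGINAL_FINE_STAGE = StageConfig(frame_width=500, ps=20, tr=15.0, sr_a=1.0, sr_c=15.0)
COARSE_STAGE = StageConfig(frame_width=100, ps=20, tr=15.0, sr_a=1.0, sr_c=15.0)


@dataclass
class RfrvClmModel:
    """One trained stage: shape model + per-landmark voting forests."""

    shape_model: ShapeModel
    forests: list[LandmarkForest]
    pr: np.ndarray                  # per-landmark position range, frame px
    config: StageConfig
    pad: int

    @property
    def n_landmarks(self) -> int:
        return len(self.forests)

    @property
    def sr(self) -> np.ndarray:
        return self.config.sr_a * self.pr + self.config.sr_c

    def to_arrays(self) -> dict[str, np.ndarray]:
        out = {f"shape_{k}": v for k, v in self.shape_model.to_arrays().items()}
        for l, f in enumerate(self.forests):
            for k, v in f.to_arrays().items():
                out[f"f{l:02d}_{k}"] = v
        out["pr"] = self.pr
        out["pad"] = np.array([self.pad], dtype=np.int64)
        cfg = self.config
        out["cfg"] = np.array([cfg.frame_width, cfg.ps, cfg.tr, cfg.sr_a, cfg.sr_c,
                               cfg.n_features, cfg.n_trees, cfg.samples_per_image,
                               cfg.min_samples_leaf, cfg.var_kept, cfg.smooth,
                               cfg.residual_limit], dtype=np.float64)
        return out

    @classmethod
    def from_arrays(cls, a: dict[str, np.ndarray]) -> "RfrvClmModel":
        sm = ShapeModel.from_arrays(
            {k[len("shape_"):]: v for k, v in a.items() if k.startswith("shape_")})
        c = a["cfg"]
        cfg = StageConfig(frame_width=int(c[0]), ps=int(c[1]), tr=float(c[2]),
                          sr_a=float(c[3]), sr_c=float(c[4]), n_features=int(c[5]),
                          n_trees=int(c[6]), samples_per_image=int(c[7]),
                          min_samples_leaf=int(c[8]), var_kept=float(c[9]),
                          smooth=int(c[10]), residual_limit=float(c[11]))
        forests = []
        l = 0
        while f"f{l:02d}_n_trees" in a:
            prefix = f"f{l:02d}_"
            forests.append(LandmarkForest.from_arrays(
                {k[len(prefix):]: v for k, v in a.items() if k.startswith(prefix)}))
            l += 1
        return cls(shape_model=sm, forests=forests, pr=a["pr"], config=cfg,
                   pad=int(a["pad"][0]))


def _frame_pad(cfg: StageConfig, sr_max: float) -> int:
    reach = max(cfg.tr, sr_max)
    return int(np.ceil(cfg.ps / 2 * 1.1 * np.sqrt(2) + 1 + reach + 2))


def train_stage(images: list[Image], annotations: list[np.ndarray],
                cfg: StageConfig, rng_seed: int = 0) -> RfrvClmModel:
    """Train one RFRV-CLM stage from annotated images."""
    if len(images) < 5:
        raise ValueError("need at least 5 annotated images")
    shapes = [np.asarray(a, dtype=np.float64) for a in annotations]
    aligned, mean_n = align_shapes(shapes)
    model = build_model(aligned, var_kept=cfg.var_kept, frame_width=cfg.frame_width)
    fs = model.frame_scale
    # aligned training shapes expressed in frame px
    aligned_f = [model.mean + (a - mean_n) * fs for a in aligned]
    stack = np.stack(aligned_f)
    ranges = stack.max(axis=0) - stack.min(axis=0)   # (k, 2)
    pr = ranges.max(axis=1)
    sr = cfg.sr_a * pr + cfg.sr_c
    pad = _frame_pad(cfg, float(sr.max()))
    k = model.n_points
    rng = np.random.default_rng(rng_seed)
    pools = [FeaturePool.sample(cfg.ps, cfg.n_features,
                                np.random.default_rng((rng_seed + 1) * 1000 + l))
             for l in range(k)]
    feats: list[list[np.ndarray]] = [[] for _ in range(k)]
    disps: list[list[np.ndarray]] = [[] for _ in range(k)]
    for img, ann in zip(images, shapes):
        pose = model.pose_for(ann)
        frame = resample_to_frame(img, pose, model.frame_width,
                                  model.frame_height, pad=pad)
        true_f = pose.to_frame(ann) + pad
        for l in range(k):
            f, d = sample_training_set(frame, tuple(true_f[l]), pools[l],
                                       cfg.tr, cfg.samples_per_image, rng)
            feats[l].append(f)
            disps[l].append(d)
    forests = []
    for l in range(k):
        forests.append(train_forest(
            np.vstack(feats[l]), np.vstack(disps[l]), pools[l], cfg.tr,
            n_trees=cfg.n_trees, rng_seed=rng_seed * 100 + l,
            min_samples_leaf=cfg.min_samples_leaf))
    return RfrvClmModel(shape_model=model, forests=forests, pr=pr,
                        config=cfg, pad=pad)


def _clip_region(cx: float, cy: float, half: float, ps: int,
                 width: int, height: int) -> tuple[int, int, int, int] | None:
    """Intersect a window around (cx, cy) with the patch-feasible raster area."""
    lo = ps // 2
    hi_x = width - 1 - (ps - ps // 2)
    hi_y = height - 1 - (ps - ps // 2)
    x0 = max(int(np.floor(cx - half)), lo)
    x1 = min(int(np.ceil(cx + half)), hi_x)
    y0 = max(int(np.floor(cy - half)), lo)
    y1 = min(int(np.ceil(cy + half)), hi_y)
    if x1 < x0 or y1 < y0:
        return None
    return x0, y0, x1, y1


def _argmax_in_box(sm: np.ndarray, vg: VoteGrid, centre: np.ndarray,
                   half: float) -> tuple[float, float, float]:
    """Peak of the smoothed grid restricted to a box around ``centre``
    (frame coords); ties break at the smallest y then x."""
    ox, oy = vg.offset
    gh, gw = sm.shape
    x0 = max(int(np.floor(centre[0] - half)) - ox, 0)
    x1 = min(int(np.ceil(centre[0] + half)) - ox, gw - 1)
    y0 = max(int(np.floor(centre[1] - half)) - oy, 0)
    y1 = min(int(np.ceil(centre[1] + half)) - oy, gh - 1)
    if x1 < x0 or y1 < y0:
        return float(centre[0]), float(centre[1]), 0.0
    sub = sm[y0:y1 + 1, x0:x1 + 1]
    iy, ix = np.unravel_index(int(np.argmax(sub)), sub.shape)
    return float(ox + x0 + ix), float(oy + y0 + iy), float(sub[iy, ix])


def compute_vote_grids(model: RfrvClmModel, img: Image, current: np.ndarray
                       ) -> tuple[Pose, np.ndarray, list[VoteGrid | None], np.ndarray]:
    """Resample the image at the pose fitted to ``current`` and cast votes
    per landmark over a window of half-width ``sr_l`` around its current
    position.

    Returns the frame pose, the current points in frame raster coordinates,
    the per-landmark vote grids (``None`` where the window left the frame)
    and the per-landmark vote spreads (frame px).
    """
    sm_model = model.shape_model
    current = np.asarray(current, dtype=np.float64)
    pose = fit_params(sm_model, current).pose
    frame = resample_to_frame(img, pose, sm_model.frame_width,
                              sm_model.frame_height, pad=model.pad)
    ii = integral_image(frame)
    h, w = frame.pixels.shape
    cur_f = pose.to_frame(current) + model.pad    # raster coords
    sr = model.sr
    grids: list[VoteGrid | None] = []
    spreads = np.zeros(model.n_landmarks)
    for l in range(model.n_landmarks):
        region = _clip_region(cur_f[l, 0], cur_f[l, 1], sr[l], model.config.ps, w, h)
        if region is None:
            grids.append(None)
            continue
        vg = cast_votes(model.forests[l], ii, region, step=1)
        grids.append(vg)
        spreads[l] = vg.spread()
    return pose, cur_f, grids, spreads


def constrained_fit(model: RfrvClmModel, pose: Pose, grids: list[VoteGrid | None],
                    cur_f: np.ndarray, inner_rounds: int = 5,
                    move_tol: float = 0.5) -> np.ndarray:
    """Alternating vote-peak selection and weighted constrained shape fit.

    Each round picks, per landmark, the peak of the box-smoothed vote grid
    within a box of half-width ``sr_l`` around the current estimate, then
    fits pose and clamped mode weights with the vote mass as weights, until
    the model points move less than ``move_tol`` frame px.  Bounded per-point
    residuals toward the vote peaks are applied at the end.  Returns the
    updated points in image coordinates.
    """
    sm_model = model.shape_model
    cfg = model.config
    smoothed = [g.smoothed(cfg.smooth) if g is not None else None for g in grids]
    sr = model.sr
    est_f = cur_f.copy()
    cand_f = cur_f.copy()
    for _ in range(inner_rounds):
        weights = np.zeros(model.n_landmarks)
        for l in range(model.n_landmarks):
            if grids[l] is None:
                cand_f[l] = est_f[l]
                continue
            x, y, mass = _argmax_in_box(smoothed[l], grids[l], est_f[l], sr[l])
            cand_f[l] = (x, y)
            weights[l] = mass
        if not np.any(weights > 0):
            weights[:] = 1.0
        cand_img = pose.to_image(cand_f - model.pad)
        fit = fit_params(sm_model, cand_img, weights)
        fitted = sm_model.mean + (sm_model.modes @ fit.b).reshape(-1, 2)
        fitted_img = fit.pose.to_image(fitted)
        new_est = pose.to_frame(fitted_img) + model.pad
        move = float(np.max(np.abs(new_est - est_f)))
        est_f = new_est
        if move < move_tol:
            break
    # allow bounded per-point deviations from the model toward the vote peaks
    resid = cand_f - est_f
    norms = np.hypot(resid[:, 0], resid[:, 1])
    lim = cfg.residual_limit
    scale = np.where(norms > lim, lim / np.maximum(norms, 1e-12), 1.0)
    out_f = est_f + resid * scale[:, None]
    return pose.to_image(out_f - model.pad)


def clm_iterate(model: RfrvClmModel, img: Image, current: np.ndarray,
                inner_rounds: int = 5, move_tol: float = 0.5,
                ) -> tuple[np.ndarray, np.ndarray]:
    """One constrained search iteration: cast votes around the current
    points, then fit the shape model to the vote peaks.  Returns the updated
    image-space points and the per-landmark vote spread (frame px)."""
    pose, cur_f, grids, spreads = compute_vote_grids(model, img, current)
    out_img = constrained_fit(model, pose, grids, cur_f,
                              inner_rounds=inner_rounds, move_tol=move_tol)
    return out_img, spreads


@dataclass
class SearchResult:
    """Final landmark points with per-landmark vote spread (refinement-frame
    px) and a record of the iterations run per stage."""

    points: np.ndarray
    spreads: np.ndarray
    stages: list[tuple[str, int]]
    pose_score: float = 0.0


@dataclass
class TwoStageModel:
    """Coarse-to-fine RFRV-CLM pair with iteration counts and early stop."""

    coarse: RfrvClmModel
    fine: RfrvClmModel
    n_coarse_iterations: int = 10
    n_fine_iterations: int = 1
    early_stop_threshold: float = 4.0   # refinement-frame px

    def to_arrays(self) -> dict[str, np.ndarray]:
        out = {f"coarse_{k}": v for k, v in self.coarse.to_arrays().items()}
        out.update({f"fine_{k}": v for k, v in self.fine.to_arrays().items()})
        out["iters"] = np.array([self.n_coarse_iterations, self.n_fine_iterations],
                                dtype=np.int64)
        out["early_stop_threshold"] = np.array([self.early_stop_threshold])
        return out

    @classmethod
    def from_arrays(cls, a: dict[str, np.ndarray]) -> "TwoStageModel":
        return cls(
            coarse=RfrvClmModel.from_arrays(
                {k[len("coarse_"):]: v for k, v in a.items() if k.startswith("coarse_")}),
            fine=RfrvClmModel.from_arrays(
                {k[len("fine_"):]: v for k, v in a.items() if k.startswith("fine_")}),
            n_coarse_iterations=int(a["iters"][0]),
            n_fine_iterations=int(a["iters"][1]),
            early_stop_threshold=float(a["early_stop_threshold"][0]))


ARCHIVE_VERSION = 1


def save_model(path, det: DetectorModel, two_stage: TwoStageModel,
               seed: int | None = None, landmark_names: list[str] | None = None
               ) -> None:
    """Bundle detector + both CLM stages into a single canonical archive."""
    from .ceph import LANDMARK_NAMES
    from .io import save_archive

    arrays = {f"det_{k}": v for k, v in det.to_arrays().items()}
    arrays.update({f"ts_{k}": v for k, v in two_stage.to_arrays().items()})
    manifest = {
        "format_version": ARCHIVE_VERSION,
        "n_landmarks": two_stage.fine.n_landmarks,
        "landmark_names": list(landmark_names or LANDMARK_NAMES),
        "training_seed": seed,
        "stages": {
            "coarse": asdict(two_stage.coarse.config),
            "fine": asdict(two_stage.fine.config),
        },
        "n_coarse_iterations": two_stage.n_coarse_iterations,
        "n_fine_iterations": two_stage.n_fine_iterations,
        "early_stop_threshold": two_stage.early_stop_threshold,
    }
    save_archive(path, manifest, arrays)


def load_model(path) -> tuple[DetectorModel, TwoStageModel, dict]:
    from .io import load_archive

    manifest, arrays = load_archive(path)
    if manifest.get("format_version") != ARCHIVE_VERSION:
        raise ValueError("unsupported model archive version")
    det = DetectorModel.from_arrays(
        {k[len("det_"):]: v for k, v in arrays.items() if k.startswith("det_")})
    ts = TwoStageModel.from_arrays(
        {k[len("ts_"):]: v for k, v in arrays.items() if k.startswith("ts_")})
    return det, ts, manifest


def search(two_stage: TwoStageModel, det: DetectorModel, img: Image,
           early_stop: bool = True) -> SearchResult:
    """Full landmark search: detection, coarse iterations, fine refinement.

    With ``early_stop`` the iteration loop of each stage exits as soon as
    every landmark's vote spread, converted to refinement-frame px, is at or
    below the threshold (checked after each iteration's vote casting).
    """
    if two_stage.coarse.n_landmarks != two_stage.fine.n_landmarks:
        raise ValueError("coarse and fine stages disagree on landmark count")
    cands = detect(det, img)
    if not cands:
        raise ValueError("detection produced no candidates")
    pts = init_landmarks(det, cands[0].pose)
    thr = two_stage.early_stop_threshold
    fine_fs = two_stage.fine.shape_model.frame_scale
    stages: list[tuple[str, int]] = []
    spreads = np.zeros(two_stage.fine.n_landmarks)
    for name, model, n_iter in (("coarse", two_stage.coarse, two_stage.n_coarse_iterations),
                                ("fine", two_stage.fine, two_stage.n_fine_iterations)):
        conv = fine_fs / model.shape_model.frame_scale
        done = 0
        for _ in range(n_iter):
            pts, raw = clm_iterate(model, img, pts)
            spreads = raw * conv
            done += 1
            if early_stop and np.all(spreads <= thr):
                break
        stages.append((name, done))
    return SearchResult(points=pts, spreads=spreads, stages=stages,
                        pose_score=float(cands[0].score))
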