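"""Random-Forest regression voting for landmark position prediction.

For one landmark, patches are sampled around the true position in the
reference frame at random displacements; a regression forest learns to map
Haar-feature vectors of a patch to the displacement from the patch centre to
the landmark.  At search time every tree casts one unit vote at its predicted
landmark position for every evaluated patch position, accumulating a 2D vote
histogram ``V_l`` whose peaks indicate likely landmark positions.

Tree training is delegated to scikit-learn's regression trees (bootstrap
resampling, per-node random feature subsets, variance-reduction splits,
leaf means); trained trees are flattened to plain arrays for fast vectorised
voting and for canonical serialisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.ensemble import RandomForestRegressor

from .imaging import FeaturePool, Image, IntegralImage

__all__ = [
    "LandmarkForest",
    "VoteGrid",
    "sample_training_set",
    "train_forest",
    "cast_votes",
]

# appearance perturbation ranges applied to training patches
SCALE_JITTER = 0.10
ANGLE_JITTER = np.deg2rad(6.0)


def sample_training_set(frame: Image, true_pos: tuple[float, float], pool: FeaturePool,
                        tr: float, n: int, rng: np.random.Generator,
                        scale_jitter: float = SCALE_JITTER,
                        angle_jitter: float = ANGLE_JITTER,
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Sample ``n`` training patches around ``true_pos`` in a frame image.

    Displacements are uniform in ``[-tr, +tr]²`` (frame px); each patch is
    additionally perturbed by a random scale in ``[1-scale_jitter,
    1+scale_jitter]`` and rotation in ``±angle_jitter`` for robustness, which
    affects appearance only, not the displacement label.  Patches that do not
    fit inside the frame are skipped; if more than half are skipped an error
    is raised.  Returns ``(features, displacements)`` with displacement =
    true position minus patch centre.
    """
    ps = pool.patch_size
    px = frame.pixels
    h, w = px.shape
    tx, ty = float(true_pos[0]), float(true_pos[1])
    disp = rng.uniform(-tr, tr, size=(n, 2))
    scales = rng.uniform(1.0 - scale_jitter, 1.0 + scale_jitter, size=n)
    angles = rng.uniform(-angle_jitter, angle_jitter, size=n)
    centres = np.array([tx, ty]) + disp
    # conservative in-bounds radius for a rotated, scaled patch
    radius = (ps / 2.0) * (1.0 + scale_jitter) * np.sqrt(2.0) + 1.0
    ok = (
        (centres[:, 0] >= radius) & (centres[:, 0] <= w - 1 - radius)
        & (centres[:, 1] >= radius) & (centres[:, 1] <= h - 1 - radius)
    )
    if ok.sum() < n / 2.0:
        raise ValueError("more than half of the sampled patches fall outside the frame")
    centres, scales, angles = centres[ok], scales[ok], angles[ok]
    m = len(centres)
    u = np.arange(ps, dtype=np.float64) - ps // 2
    uu, vv = np.meshgrid(u, u)  # patch-local x (cols), y (rows)
    cos, sin = np.cos(angles), np.sin(angles)
    # frame coords of every patch pixel: centre + s * R(angle) @ (u, v)
    gx = centres[:, 0, None, None] + scales[:, None, None] * (
        cos[:, None, None] * uu[None] - sin[:, None, None] * vv[None])
    gy = centres[:, 1, None, None] + scales[:, None, None] * (
        sin[:, None, None] * uu[None] + cos[:, None, None] * vv[None])
    patches = ndimage.map_coordinates(
        px, np.stack([gy.ravel(), gx.ravel()]), order=1, mode="nearest"
    ).reshape(m, ps, ps)
    feats = pool.extract_patches(patches)
    labels = np.array([tx, ty]) - centres
    return feats, labels


@dataclass
class _TreeArrays:
    children_left: np.ndarray
    children_right: np.ndarray
    feature: np.ndarray
    threshold: np.ndarray
    values: np.ndarray  # (n_nodes, 2) leaf mean displacement

    def predict(self, X: np.ndarray) -> np.ndarray:
        idx = np.zeros(X.shape[0], dtype=np.int64)
        active = self.children_left[idx] >= 0
        while active.any():
            ai = np.flatnonzero(active)
            node = idx[ai]
            left = X[ai, self.feature[node]] <= self.threshold[node]
            idx[ai] = np.where(left, self.children_left[node], self.children_right[node])
            active = self.children_left[idx] >= 0
        return self.values[idx]


@dataclass
class LandmarkForest:
    """Per-landmark ensemble of displacement-regression trees plus its
    Haar-feature pool and sampling parameters."""

    trees: list[_TreeArrays]
    pool: FeaturePool
    tr: float

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    @property
    def patch_size(self) -> int:
        return self.pool.patch_size

    def predict_per_tree(self, X: np.ndarray) -> np.ndarray:
        """Displacement votes, shape (n_trees, n_samples, 2)."""
        return np.stack([t.predict(X) for t in self.trees])

    def predict_mean(self, X: np.ndarray) -> np.ndarray:
        return self.predict_per_tree(X).mean(axis=0)

    def to_arrays(self) -> dict[str, np.ndarray]:
        out = {"n_trees": np.array([self.n_trees], dtype=np.int64),
               "tr": np.array([self.tr])}
        for k, v in self.pool.to_arrays().items():
            out[f"pool_{k}"] = v
        for i, t in enumerate(self.trees):
            out[f"t{i}_left"] = t.children_left
            out[f"t{i}_right"] = t.children_right
            out[f"t{i}_feat"] = t.feature
            out[f"t{i}_thresh"] = t.threshold
            out[f"t{i}_values"] = t.values
        return out

    @classmethod
    def from_arrays(cls, a: dict[str, np.ndarray]) -> "LandmarkForest":
        pool = FeaturePool.from_arrays(
            {k[len("pool_"):]: v for k, v in a.items() if k.startswith("pool_")})
        trees = []
        for i in range(int(a["n_trees"][0])):
            trees.append(_TreeArrays(
                children_left=a[f"t{i}_left"], children_right=a[f"t{i}_right"],
                feature=a[f"t{i}_feat"], threshold=a[f"t{i}_thresh"],
                values=a[f"t{i}_values"]))
        return cls(trees=trees, pool=pool, tr=float(a["tr"][0]))


def train_forest(features: np.ndarray, displacements: np.ndarray, pool: FeaturePool,
                 tr: float, n_trees: int = 10, rng_seed: int = 0,
                 min_samples_leaf: int = 10) -> LandmarkForest:
    """Train a displacement-voting forest.

    Each tree sees a bootstrap of the samples; node splits are chosen among a
    random sqrt-sized feature subset to minimise the summed displacement
    variance of the children; leaves store the mean displacement.
    """
    X = np.asarray(features, dtype=np.float64)
    Y = np.asarray(displacements, dtype=np.float64)
    if X.shape[0] < 20:
        raise ValueError("need at least 20 training samples")
    rf = RandomForestRegressor(
        n_estimators=n_trees, criterion="squared_error", max_features="sqrt",
        min_samples_leaf=min_samples_leaf, bootstrap=True,
        random_state=int(rng_seed) % (2 ** 31), n_jobs=1)
    rf.fit(X, Y)
    trees = []
    for est in rf.estimators_:
        t = est.tree_
        trees.append(_TreeArrays(
            children_left=t.children_left.astype(np.int64),
            children_right=t.children_right.astype(np.int64),
            feature=t.feature.astype(np.int64),
            threshold=t.threshold.astype(np.float64),
            values=t.value.reshape(t.node_count, -1).astype(np.float64)))
    return LandmarkForest(trees=trees, pool=pool, tr=float(tr))


@dataclass
class VoteGrid:
    """2D accumulator of landmark-position votes in frame raster coordinates.

    ``offset`` is the frame coordinate of cell ``grid[0, 0]``; ``cell`` is
    the cell size in frame px.  ``dropped`` counts votes that landed outside
    the grid.
    """

    grid: np.ndarray
    offset: tuple[int, int]
    cell: int = 1
    dropped: int = 0

    @property
    def total_mass(self) -> float:
        return float(self.grid.sum())

    def smoothed(self, size: int = 3) -> np.ndarray:
        return ndimage.uniform_filter(self.grid, size=size, mode="constant") * size * size

    def argmax_position(self, smooth: int = 3) -> tuple[float, float]:
        """Frame coordinates of the (box-smoothed) maximum cell; ties break
        at the smallest y then x (row-major first occurrence)."""
        sm = self.smoothed(smooth) if smooth else self.grid
        idx = int(np.argmax(sm))
        cy, cx = np.unravel_index(idx, sm.shape)
        return (self.offset[0] + cx * self.cell, self.offset[1] + cy * self.cell)

    def mass_at(self, pos: tuple[float, float], smooth: int = 3) -> float:
        sm = self.smoothed(smooth) if smooth else self.grid
        cx = int(round((pos[0] - self.offset[0]) / self.cell))
        cy = int(round((pos[1] - self.offset[1]) / self.cell))
        if 0 <= cy < sm.shape[0] and 0 <= cx < sm.shape[1]:
            return float(sm[cy, cx])
        return 0.0

    def spread(self) -> float:
        """Mean distance of vote mass from its centroid (frame px); 0 for an
        empty grid."""
        m = self.grid.sum()
        if m <= 0:
            return 0.0
        h, w = self.grid.shape
        ys, xs = np.mgrid[0:h, 0:w]
        cx = (xs * self.grid).sum() / m
        cy = (ys * self.grid).sum() / m
        d = np.hypot(xs - cx, ys - cy)
        return float((d * self.grid).sum() / m) * self.cell


def cast_votes(forest: LandmarkForest, ii: IntegralImage,
               region: tuple[int, int, int, int], step: int = 1,
               cell: int = 1) -> VoteGrid:
    """Scan ``region`` (x0, y0, x1, y1 inclusive, frame raster coords) with
    stride ``step``; every tree casts one unit vote at its predicted landmark
    position.  Votes landing outside the region grid are dropped (counted)."""
    x0, y0, x1, y1 = (int(v) for v in region)
    if x1 < x0 or y1 < y0:
        raise ValueError("empty vote region")
    ps = forest.patch_size
    half = ps // 2
    nx = (x1 - x0) // step + 1
    ny = (y1 - y0) // step + 1
    feats = forest.pool.extract_grid(ii, x0 - half, y0 - half, nx, ny, step=step)
    xs = x0 + step * np.tile(np.arange(nx), ny)
    ys = y0 + step * np.repeat(np.arange(ny), nx)
    gw = (x1 - x0) // cell + 1
    gh = (y1 - y0) // cell + 1
    grid = np.zeros((gh, gw), dtype=np.float64)
    dropped = 0
    preds = forest.predict_per_tree(feats)
    for t in range(forest.n_trees):
        vx = np.rint((xs + preds[t, :, 0] - x0) / cell).astype(np.int64)
        vy = np.rint((ys + preds[t, :, 1] - y0) / cell).astype(np.int64)
        ok = (vx >= 0) & (vx < gw) & (vy >= 0) & (vy < gh)
        dropped += int((~ok).sum())
        np.add.at(grid, (vy[ok], vx[ok]), 1.0)
    return VoteGrid(grid=grid, offset=(x0, y0), cell=cell, dropped=dropped)
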