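"""Pixel-grid handling: integral images, Haar-like features and reference-frame resampling.

Coordinate convention (used throughout the package): 0-based pixel indices,
origin at the centre of the top-left pixel, ``x`` increases rightward (columns),
``y`` increases downward (rows).  A point is an ``(x, y)`` pair; arrays are
indexed ``pixels[y, x]``.

A *reference frame* is a pose-normalised coordinate system into which the
image region around the object of interest is resampled, so that local
appearance models can be trained and evaluated independently of where and at
what scale/orientation the object appears in the image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "Image",
    "IntegralImage",
    "HaarFeatureSpec",
    "FeaturePool",
    "Pose",
    "integral_image",
    "haar_value",
    "resample_to_frame",
    "frame_to_image",
    "image_to_frame",
]

HAAR_KINDS = (
    "two-rect-horizontal",
    "two-rect-vertical",
    "three-rect",
    "four-rect-checker",
    "single-rect-vs-mean",
)


@dataclass
class Image:
    """A grayscale raster with physical pixel spacing.

    Parameters
    ----------
    pixels : ndarray, shape (height, width)
        Intensity values (float).
    spacing : float
        Physical size of one pixel in mm (isotropic).
    """

    pixels: np.ndarray
    spacing: float = 0.1

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("image must be a non-empty 2D array")
        if not self.spacing > 0:
            raise ValueError("pixel spacing must be positive")

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def height(self) -> int:
        return self.pixels.shape[0]


@dataclass
class IntegralImage:
    """Cumulative-sum table with a one-pixel zero border.

    ``sums[r, c]`` is the sum of all source pixels with row < r and col < c,
    so any axis-aligned rectangle sum costs four lookups.  ``abs_sums`` is the
    same table over ``|pixels|`` and is used to normalise Haar responses by
    the local mean absolute intensity.
    """

    sums: np.ndarray
    abs_sums: np.ndarray

    @property
    def height(self) -> int:
        return self.sums.shape[0] - 1

    @property
    def width(self) -> int:
        return self.sums.shape[1] - 1

    def rect_sum(self, x0: int, y0: int, w: int, h: int) -> float:
        s = self.sums
        return float(s[y0 + h, x0 + w] - s[y0, x0 + w] - s[y0 + h, x0] + s[y0, x0])


def integral_image(img: Image | np.ndarray) -> IntegralImage:
    """Build the integral image (summed-area table) of ``img``."""
    px = img.pixels if isinstance(img, Image) else np.asarray(img, dtype=np.float64)
    if px.ndim != 2 or px.size == 0:
        raise ValueError("cannot build an integral image from an empty image")
    h, w = px.shape
    sums = np.zeros((h + 1, w + 1), dtype=np.float64)
    np.cumsum(np.cumsum(px, axis=0), axis=1, out=sums[1:, 1:])
    abs_sums = np.zeros_like(sums)
    np.cumsum(np.cumsum(np.abs(px), axis=0), axis=1, out=abs_sums[1:, 1:])
    return IntegralImage(sums=sums, abs_sums=abs_sums)


@dataclass(frozen=True)
class HaarFeatureSpec:
    """One Haar-like feature: a signed combination of rectangle sums.

    ``rect = (x0, y0, w, h)`` in patch-local pixels; the rectangle (and its
    sub-rectangles, depending on ``kind``) must lie inside the ``[0, ps)²``
    patch.  ``polarity`` flips the sign of the response.
    """

    kind: str
    rect: tuple[int, int, int, int]
    polarity: int = 1
    patch_size: int = 0

    def rects_weights(self) -> list[tuple[int, int, int, int, float]]:
        """Decompose the feature into weighted axis-aligned rectangles."""
        x0, y0, w, h = self.rect
        p = float(self.polarity)
        if self.kind == "two-rect-horizontal":
            hw = w // 2
            return [(x0, y0, hw, h, p), (x0 + hw, y0, w - hw, h, -p)]
        if self.kind == "two-rect-vertical":
            hh = h // 2
            return [(x0, y0, w, hh, p), (x0, y0 + hh, w, h - hh, -p)]
        if self.kind == "three-rect":
            tw = w // 3
            return [
                (x0, y0, tw, h, p),
                (x0 + tw, y0, w - 2 * tw, h, -2.0 * p),
                (x0 + w - tw, y0, tw, h, p),
            ]
        if self.kind == "four-rect-checker":
            hw, hh = w // 2, h // 2
            return [
                (x0, y0, hw, hh, p),
                (x0 + hw, y0 + hh, w - hw, h - hh, p),
                (x0 + hw, y0, w - hw, hh, -p),
                (x0, y0 + hh, hw, h - hh, -p),
            ]
        if self.kind == "single-rect-vs-mean":
            # rectangle sum minus the area-matched fraction of the whole patch
            ps = self.patch_size
            if ps <= 0:
                raise ValueError("single-rect-vs-mean requires patch_size")
            frac = (w * h) / float(ps * ps)
            return [(x0, y0, w, h, p), (0, 0, ps, ps, -p * frac)]
        raise ValueError(f"unknown Haar kind {self.kind!r}")


def haar_value(ii: IntegralImage, spec: HaarFeatureSpec, origin: tuple[int, int]) -> float:
    """Evaluate one Haar feature at ``origin`` (patch top-left) on ``ii``.

    Raises ``ValueError`` if any rectangle falls outside the image.
    """
    ox, oy = origin
    total = 0.0
    for x0, y0, w, h, wt in spec.rects_weights():
        x, y = x0 + ox, y0 + oy
        if x < 0 or y < 0 or x + w > ii.width or y + h > ii.height:
            raise ValueError("Haar rectangle out of image bounds")
        total += wt * ii.rect_sum(x, y, w, h)
    return total


class FeaturePool:
    """A fixed pool of Haar features over a ``ps``×``ps`` patch, with fast
    vectorised evaluation.

    Internally each feature is flattened to weighted integral-image corner
    lookups, so extracting the whole pool over a regular grid of patch
    positions is a handful of strided slice-adds per corner.

    Responses are optionally normalised by the patch mean absolute intensity
    (plus a small epsilon) for lighting robustness.
    """

    EPS = 1e-6

    def __init__(self, specs: list[HaarFeatureSpec], patch_size: int, normalise: bool = True):
        self.specs = specs
        self.patch_size = int(patch_size)
        self.normalise = bool(normalise)
        self._compile()

    def _compile(self) -> None:
        rows, cols, weights, fidx = [], [], [], []
        for i, spec in enumerate(self.specs):
            for x0, y0, w, h, wt in spec.rects_weights():
                for dy, dx, s in ((h, w, 1.0), (0, w, -1.0), (h, 0, -1.0), (0, 0, 1.0)):
                    rows.append(y0 + dy)
                    cols.append(x0 + dx)
                    weights.append(s * wt)
                    fidx.append(i)
        order = np.argsort(np.asarray(fidx), kind="stable")
        self._rows = np.asarray(rows)[order]
        self._cols = np.asarray(cols)[order]
        self._weights = np.asarray(weights, dtype=np.float64)[order]
        self._fidx = np.asarray(fidx)[order]
        # reduceat boundaries per feature (every feature has >= 4 corners)
        self._starts = np.searchsorted(self._fidx, np.arange(len(self.specs)))

    def __len__(self) -> int:
        return len(self.specs)

    @classmethod
    def sample(cls, patch_size: int, n_features: int, rng: np.random.Generator,
               normalise: bool = True, min_rect: int = 2) -> "FeaturePool":
        """Draw ``n_features`` random Haar specs inside a ``patch_size`` patch."""
        ps = int(patch_size)
        specs: list[HaarFeatureSpec] = []
        while len(specs) < n_features:
            kind = HAAR_KINDS[rng.integers(len(HAAR_KINDS))]
            if kind == "two-rect-horizontal":
                w = 2 * int(rng.integers(min_rect, max(min_rect + 1, ps // 2)))
                h = int(rng.integers(min_rect, ps))
            elif kind == "two-rect-vertical":
                w = int(rng.integers(min_rect, ps))
                h = 2 * int(rng.integers(min_rect, max(min_rect + 1, ps // 2)))
            elif kind == "three-rect":
                w = 3 * int(rng.integers(min_rect, max(min_rect + 1, ps // 3)))
                h = int(rng.integers(min_rect, ps))
            elif kind == "four-rect-checker":
                w = 2 * int(rng.integers(min_rect, max(min_rect + 1, ps // 2)))
                h = 2 * int(rng.integers(min_rect, max(min_rect + 1, ps // 2)))
            else:  # single-rect-vs-mean
                w = int(rng.integers(min_rect, ps))
                h = int(rng.integers(min_rect, ps))
            if w > ps or h > ps:
                continue
            x0 = int(rng.integers(0, ps - w + 1))
            y0 = int(rng.integers(0, ps - h + 1))
            pol = 1 if rng.random() < 0.5 else -1
            specs.append(HaarFeatureSpec(kind, (x0, y0, w, h), pol, patch_size=ps))
        return cls(specs, ps, normalise=normalise)

    def extract_patches(self, patches: np.ndarray) -> np.ndarray:
        """Features for a stack of patches, shape (n, ps, ps) -> (n, n_features)."""
        n = patches.shape[0]
        ps = self.patch_size
        ii = np.zeros((n, ps + 1, ps + 1), dtype=np.float64)
        np.cumsum(np.cumsum(patches, axis=1), axis=2, out=ii[:, 1:, 1:])
        vals = ii[:, self._rows, self._cols] * self._weights
        feats = np.add.reduceat(vals, self._starts, axis=1)
        if self.normalise:
            ii_abs = np.zeros_like(ii)
            np.cumsum(np.cumsum(np.abs(patches), axis=1), axis=2, out=ii_abs[:, 1:, 1:])
            mean_abs = ii_abs[:, ps, ps] / float(ps * ps)
            feats /= (mean_abs + self.EPS)[:, None]
        return feats

    def extract_grid(self, ii: IntegralImage, x0: int, y0: int,
                     nx: int, ny: int, step: int = 1) -> np.ndarray:
        """Features for patches whose top-left corners form a regular grid.

        Grid origins are ``(x0 + j*step, y0 + i*step)`` for ``i < ny``,
        ``j < nx``.  Returns an array of shape (ny*nx, n_features), rows in
        row-major (y, x) order.  All patches must lie inside the image.
        """
        ps = self.patch_size
        if x0 < 0 or y0 < 0 or x0 + (nx - 1) * step + ps > ii.width \
                or y0 + (ny - 1) * step + ps > ii.height:
            raise ValueError("patch grid out of image bounds")
        feats = np.zeros((len(self.specs), ny, nx), dtype=np.float64)
        s = ii.sums
        for r, c, wt, fi in zip(self._rows, self._cols, self._weights, self._fidx):
            block = s[y0 + r: y0 + r + ny * step: step, x0 + c: x0 + c + nx * step: step]
            feats[fi] += wt * block
        out = feats.reshape(len(self.specs), -1).T
        if self.normalise:
            a = ii.abs_sums
            patch_sum = (
                a[y0 + ps: y0 + ps + ny * step: step, x0 + ps: x0 + ps + nx * step: step]
                - a[y0: y0 + ny * step: step, x0 + ps: x0 + ps + nx * step: step]
                - a[y0 + ps: y0 + ps + ny * step: step, x0: x0 + nx * step: step]
                + a[y0: y0 + ny * step: step, x0: x0 + nx * step: step]
            )
            mean_abs = patch_sum.reshape(-1) / float(ps * ps)
            out = out / (mean_abs + self.EPS)[:, None]
        return out

    def to_arrays(self) -> dict[str, np.ndarray]:
        kinds = np.array([HAAR_KINDS.index(sp.kind) for sp in self.specs], dtype=np.int64)
        rects = np.array([sp.rect for sp in self.specs], dtype=np.int64)
        pols = np.array([sp.polarity for sp in self.specs], dtype=np.int64)
        meta = np.array([self.patch_size, int(self.normalise)], dtype=np.int64)
        return {"kinds": kinds, "rects": rects, "pols": pols, "meta": meta}

    @classmethod
    def from_arrays(cls, arrays: dict[str, np.ndarray]) -> "FeaturePool":
        ps, norm = (int(v) for v in arrays["meta"])
        specs = [
            HaarFeatureSpec(HAAR_KINDS[int(k)], tuple(int(v) for v in r), int(p), patch_size=ps)
            for k, r, p in zip(arrays["kinds"], arrays["rects"], arrays["pols"])
        ]
        return cls(specs, ps, normalise=bool(norm))


def _wrap_angle(a: float) -> float:
    return float((a + np.pi) % (2 * np.pi) - np.pi)


@dataclass
class Pose:
    """Similarity transform between reference-frame and image coordinates.

    Maps a frame point ``p`` to the image point
    ``centre + scale * R(angle) @ (p - ref)`` where ``ref`` is the frame
    anchor (usually the frame centre) and ``centre`` its image position.
    ``scale`` is in image px per frame px.
    """

    centre: tuple[float, float]
    scale: float
    angle: float
    ref: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise ValueError("pose scale must be positive")
        self.angle = _wrap_angle(self.angle)

    def matrix(self) -> np.ndarray:
        c, s = np.cos(self.angle), np.sin(self.angle)
        return self.scale * np.array([[c, -s], [s, c]])

    def to_image(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=np.float64))
        out = (p - np.asarray(self.ref)) @ self.matrix().T + np.asarray(self.centre)
        return out if np.asarray(points).ndim == 2 else out[0]

    def to_frame(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=np.float64))
        inv = np.linalg.inv(self.matrix())
        out = (p - np.asarray(self.centre)) @ inv.T + np.asarray(self.ref)
        return out if np.asarray(points).ndim == 2 else out[0]


def frame_to_image(point: np.ndarray, pose: Pose) -> np.ndarray:
    """Map reference-frame coordinates to image coordinates under ``pose``."""
    return pose.to_image(point)


def image_to_frame(point: np.ndarray, pose: Pose) -> np.ndarray:
    """Inverse of :func:`frame_to_image`."""
    return pose.to_frame(point)


def resample_to_frame(img: Image, pose: Pose, frame_width: int,
                      frame_height: int | None = None, pad: int = 0) -> Image:
    """Resample ``img`` into the reference frame defined by ``pose``.

    The output covers frame coordinates ``[-pad, frame_width + pad)`` ×
    ``[-pad, frame_height + pad)`` so that patches sampled near the frame
    boundary stay inside the raster; output array index = frame coord + pad.
    Bilinear interpolation, nearest-edge padding outside the image.
    """
    if frame_width < 8:
        raise ValueError("frame width must be at least 8 px")
    if frame_height is None:
        frame_height = int(round(frame_width * img.height / img.width))
    w = frame_width + 2 * pad
    h = frame_height + 2 * pad
    u = np.arange(w, dtype=np.float64) - pad
    v = np.arange(h, dtype=np.float64) - pad
    uu, vv = np.meshgrid(u, v)
    pts = np.stack([uu.ravel(), vv.ravel()], axis=1)
    xy = pose.to_image(pts)
    coords = np.stack([xy[:, 1].reshape(h, w), xy[:, 0].reshape(h, w)])
    out = ndimage.map_coordinates(img.pixels, coords, order=1, mode="nearest")
    return Image(pixels=out, spacing=img.spacing * pose.scale)


@dataclass
class Frame:
    """A resampled reference-frame raster together with its pose and padding."""

    image: Image
    pose: Pose
    pad: int
    ii: IntegralImage = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.ii is None:
            self.ii = integral_image(self.image)

    def to_index(self, frame_points: np.ndarray) -> np.ndarray:
        """Frame coordinates -> raster (x, y) indices (adds the pad offset)."""
        return np.asarray(frame_points, dtype=np.float64) + self.pad
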