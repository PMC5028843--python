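"""Synthetic cephalogram-like images with known ground-truth landmarks.

The generator deforms a fixed 19-point template by a small number of known
shape modes, poses it with a random similarity transform, and renders an
image by drawing smoothed intensity ridges along polylines connecting
landmark subsets (mimicking bone contours and the soft-tissue profile) plus
Gaussian blobs at isolated landmarks, with additive Gaussian noise.  Near the
gonion region a second, offset copy of the mandibular border is drawn to
emulate the duplicated/overlapping contours seen in real lateral cephalograms.

Every case is drawn from a counter-based RNG keyed by ``(seed, index)``, so a
case is bit-reproducible independently of generation order.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .ceph import LandmarkSet, N_LANDMARKS
from .imaging import Image, Pose

__all__ = [
    "SyntheticSpec",
    "SyntheticCase",
    "make_template",
    "make_modes",
    "sample_case",
    "generate_cases",
    "write_dataset",
]

log = logging.getLogger(__name__)

# 19-point template in "anatomical units" (approximately mm), tuned so that
# all eight clinical parameters fall in their normal (C1) class.
_TEMPLATE = np.array([
    (0.0, 0.0),      # L1  sella
    (65.9, 0.0),     # L2  nasion
    (53.3, 21.0),    # L3  orbitale
    (-7.2, 20.7),    # L4  porion
    (58.8, 45.9),    # L5  subspinale (A-point)
    (47.3, 80.1),    # L6  supramentale (B-point)
    (43.0, 94.5),    # L7  pogonion
    (35.5, 106.9),   # L8  menton
    (45.7, 108.5),   # L9  gnathion
    (-15.6, 74.5),   # L10 gonion
    (58.4, 69.0),    # L11 incision inferius
    (60.4, 66.4),    # L12 incision superius
    (77.0, 63.4),    # L13 upper lip
    (73.6, 75.0),    # L14 lower lip
    (75.0, 49.0),    # L15 subnasale
    (64.0, 101.2),   # L16 soft tissue pogonion
    (20.9, 43.2),    # L17 posterior nasal spine
    (67.0, 43.4),    # L18 anterior nasal spine
    (-4.5, 28.0),    # L19 articulare
])

# Rendered contours, as polylines of nodes; each node is an affine
# combination of landmark positions (weights sum to 1) so the drawn anatomy
# deforms consistently with the shape modes and pose.  Only anatomical
# structures are drawn: most landmarks have no distinctive blob at their
# position and are defined only by contour curvature and wider context,
# matching the locally-ambiguous character of real cephalometric landmarks.
Node = tuple[tuple[int, float], ...]

_CONTOURS: tuple[tuple[Node, ...], ...] = (
    # mandible: condyle -> gonion -> lower border -> chin -> alveolar ridge
    (((19, 1.0),), ((10, 1.0),), ((8, 1.0),), ((9, 1.0),), ((7, 1.0),),
     ((6, 1.0),), ((11, 1.0),)),
    # maxilla / palate: PNS -> ANS -> A-point -> upper incisor root region
    (((17, 1.0),), ((18, 1.0),), ((5, 1.0),), ((12, 1.0),)),
    # soft-tissue profile: forehead -> nasion -> subnasale -> lips -> chin
    (((2, 1.2), (15, -0.35), (1, 0.15)), ((2, 1.0),), ((15, 1.0),),
     ((13, 1.0),), ((14, 1.0),), ((16, 1.0),)),
    # orbit rim: lowest point at the orbitale
    (((3, 0.7), (2, 0.3)), ((3, 1.0),), ((3, 0.75), (17, 0.25))),
    # cranial-base ridge crossing the articulare
    (((1, 0.7), (4, 0.3)), ((19, 1.0),), ((19, 0.5), (10, 0.5))),
    # upper incisor axis (tip at L12)
    (((12, 1.0),), ((5, 0.7), (17, 0.3))),
    # lower incisor axis (tip at L11)
    (((11, 1.0),), ((6, 0.7), (10, 0.3))),
)
# second copy of the posterior mandible: the left and right outlines of a
# real skull are not perfectly superposed (head positioning, asymmetry), so
# the border appears duplicated at a patient-specific offset of a few mm
_DUP_CONTOUR = (19, 10, 8)

# genuinely isolated structures: sella (blob) and the ear canal below porion
_BLOB_LANDMARKS = (1,)
_PORION_OFFSET = 0.08  # ear-canal blob sits at L4 + offset * (L10 - L4)


def make_template() -> np.ndarray:
    """The fixed 19-point base shape (anatomical units, y downward)."""
    return _TEMPLATE.copy()


def make_modes(n_modes: int = 3) -> np.ndarray:
    """Fixed orthonormal deformation modes, shape (38, n_modes).

    Mode 1 rotates the mandible about the articulare (jaw opening), mode 2
    stretches the lower face vertically, mode 3 shifts the anterior
    maxillary/soft-tissue region horizontally (profile protrusion).
    """
    t = _TEMPLATE
    fields = []
    # jaw rotation about L19
    d = np.zeros_like(t)
    jaw = [6, 7, 8, 9, 10, 11, 14, 16]
    piv = t[18]
    for i in jaw:
        rel = t[i - 1] - piv
        d[i - 1] = (-rel[1], rel[0])
    fields.append(d.ravel())
    # lower-face vertical stretch about y = 45
    d = np.zeros_like(t)
    for i in range(N_LANDMARKS):
        if t[i, 1] > 45.0:
            d[i] = (0.0, t[i, 1] - 45.0)
    fields.append(d.ravel())
    # anterior protrusion
    d = np.zeros_like(t)
    for i in [5, 12, 13, 15, 18]:
        d[i - 1] = (1.0, 0.0)
    fields.append(d.ravel())
    # Gram-Schmidt orthonormalisation
    basis: list[np.ndarray] = []
    for f in fields[:n_modes]:
        for b in basis:
            f = f - (f @ b) * b
        basis.append(f / np.linalg.norm(f))
    return np.stack(basis, axis=1)


@dataclass
class SyntheticSpec:
    """Generation conditions for a synthetic dataset."""

    n: int = 70
    seed: int = 0
    image_size: tuple[int, int] = (340, 400)   # (width, height) px
    spacing: float = 0.4                       # mm per px
    render_scale: float = 2.4                  # px per anatomical unit
    translation: float = 10.0                  # px, uniform in ±translation
    scale_range: tuple[float, float] = (0.92, 1.08)
    angle_range: float = np.deg2rad(6.0)       # rad, uniform in ±angle_range
    noise_sd: float = 0.02                     # intensity units (image in [0, 1])
    edge_sigma: float = 1.4                    # ridge width, px
    blob_sigma: float = 2.5                    # landmark blob width, px
    ridge_contrast: float = 0.45
    blob_contrast: float = 0.30
    base_intensity: float = 0.10
    n_clutter: int = 3                         # overlapping-structure arcs per image
    clutter_contrast: tuple[float, float] = (0.3, 0.7)   # x ridge_contrast
    dup_offset_range: tuple[float, float] = (2.0, 9.0)   # anatomical units
    dup_contrast: tuple[float, float] = (0.4, 0.8)       # x ridge_contrast
    mode_sds: tuple[float, ...] = (2.2, 1.5, 1.0)  # anatomical units
    margin: float = 14.0                       # min truth distance to border, px

    def to_json(self) -> str:
        d = asdict(self)
        d["image_size"] = list(d["image_size"])
        d["scale_range"] = list(d["scale_range"])
        d["mode_sds"] = list(d["mode_sds"])
        return json.dumps(d, sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


@dataclass
class SyntheticCase:
    image: Image
    truth: LandmarkSet
    pose: Pose
    b: np.ndarray
    index: int = 0


def _splat_gaussian(img: np.ndarray, x: float, y: float, sigma: float, amp: float) -> None:
    h, w = img.shape
    r = int(np.ceil(3.5 * sigma))
    x0, x1 = max(0, int(x) - r), min(w, int(x) + r + 1)
    y0, y1 = max(0, int(y) - r), min(h, int(y) + r + 1)
    if x0 >= x1 or y0 >= y1:
        return
    xs = np.arange(x0, x1) - x
    ys = np.arange(y0, y1) - y
    g = np.exp(-(ys[:, None] ** 2 + xs[None, :] ** 2) / (2.0 * sigma ** 2))
    img[y0:y1, x0:x1] += amp * g


def _catmull_rom(pts: np.ndarray, samples_per_seg: int = 24) -> np.ndarray:
    """Smooth curve through control points (duplicated-endpoint Catmull-Rom).

    Real bone contours are smooth: landmarks on them sit at gentle curvature
    extrema rather than sharp corners, so their exact position is not
    locally obvious."""
    if len(pts) < 3:
        return pts
    ext = np.vstack([pts[0], pts, pts[-1]])
    out = []
    t = np.linspace(0.0, 1.0, samples_per_seg, endpoint=False)[:, None]
    for i in range(len(pts) - 1):
        p0, p1, p2, p3 = ext[i], ext[i + 1], ext[i + 2], ext[i + 3]
        out.append(
            0.5 * ((2 * p1) + (-p0 + p2) * t
                   + (2 * p0 - 5 * p1 + 4 * p2 - p3) * t ** 2
                   + (-p0 + 3 * p1 - 3 * p2 + p3) * t ** 3))
    out.append(pts[-1][None])
    return np.vstack(out)


def _draw_polyline(img: np.ndarray, pts: np.ndarray, sigma: float, amp: float) -> None:
    # splat Gaussians densely along the smoothed curve; per-splat amplitude
    # scaled by the sample step so brightness is independent of curve length
    step = 0.6
    curve = _catmull_rom(pts)
    for a, b in zip(curve[:-1], curve[1:]):
        length = float(np.linalg.norm(b - a))
        n = max(1, int(np.ceil(length / step)))
        for t in np.linspace(0.0, 1.0, n, endpoint=False):
            p = a + t * (b - a)
            _splat_gaussian(img, p[0], p[1], sigma, amp * (length / n) / sigma)


def _node_pos(shape_units: np.ndarray, node: Node) -> np.ndarray:
    return sum(w * shape_units[i - 1] for i, w in node)


def _render(spec: SyntheticSpec, shape_units: np.ndarray, pose: Pose,
            rng: np.random.Generator) -> np.ndarray:
    w, h = spec.image_size
    img = np.full((h, w), spec.base_intensity, dtype=np.float64)
    pts_img = pose.to_image(shape_units)
    for contour in _CONTOURS:
        poly = pose.to_image(np.stack([_node_pos(shape_units, n) for n in contour]))
        _draw_polyline(img, poly, spec.edge_sigma, spec.ridge_contrast)
    # duplicated mandibular border at a patient-specific offset
    mag = rng.uniform(*spec.dup_offset_range)
    phi = rng.uniform(0.0, 2.0 * np.pi)
    dup = shape_units[[i - 1 for i in _DUP_CONTOUR]] \
        + mag * np.array([np.cos(phi), np.sin(phi)])
    _draw_polyline(img, pose.to_image(dup), spec.edge_sigma,
                   rng.uniform(*spec.dup_contrast) * spec.ridge_contrast)
    # overlapping projected structures: a few smooth clutter arcs at random
    # positions and orientations over the object region
    lo = pts_img.min(axis=0) - 15.0
    hi = pts_img.max(axis=0) + 15.0
    for _ in range(spec.n_clutter):
        p0 = rng.uniform(lo, hi)
        d1 = rng.uniform(-45.0, 45.0, 2)
        d2 = rng.uniform(-45.0, 45.0, 2)
        arc = np.stack([p0, p0 + d1, p0 + d1 + d2])
        _draw_polyline(img, arc, spec.edge_sigma,
                       rng.uniform(*spec.clutter_contrast) * spec.ridge_contrast)
    for i in _BLOB_LANDMARKS:
        _splat_gaussian(img, pts_img[i - 1][0], pts_img[i - 1][1],
                        spec.blob_sigma, 1.6 * spec.blob_contrast)
    ear = shape_units[3] + _PORION_OFFSET * (shape_units[9] - shape_units[3])
    ear_img = pose.to_image(ear)
    _splat_gaussian(img, ear_img[0], ear_img[1], spec.blob_sigma, spec.blob_contrast)
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    return np.clip(img, 0.0, 1.0)


def _case_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.Generator(
        np.random.Philox(key=np.array([seed & 0xFFFFFFFFFFFFFFFF, index],
                                      dtype=np.uint64)))


def sample_case(spec: SyntheticSpec, index: int) -> SyntheticCase:
    """Draw case ``index`` of the dataset described by ``spec``.

    Deterministic in ``(spec.seed, index)``.  If the posed truth leaves the
    image margin the pose ranges are shrunk and the case redrawn (logged).
    """
    if not 0 <= index < spec.n:
        raise IndexError("case index out of range")
    rng = _case_rng(spec.seed, index)
    template = make_template()
    modes = make_modes(len(spec.mode_sds))
    centre_u = 0.5 * (template.min(axis=0) + template.max(axis=0))
    w, h = spec.image_size
    img_centre = np.array([w / 2.0, h / 2.0])
    shrink = 1.0
    for _attempt in range(8):
        b = rng.normal(0.0, 1.0, size=len(spec.mode_sds)) * np.asarray(spec.mode_sds)
        shape_units = template + (modes @ b).reshape(-1, 2)
        tx, ty = rng.uniform(-spec.translation * shrink, spec.translation * shrink, 2)
        s_lo, s_hi = spec.scale_range
        mid = 0.5 * (s_lo + s_hi)
        s = mid + (rng.uniform(s_lo, s_hi) - mid) * shrink
        ang = rng.uniform(-spec.angle_range, spec.angle_range) * shrink
        pose = Pose(centre=(img_centre[0] + tx, img_centre[1] + ty),
                    scale=spec.render_scale * s, angle=ang, ref=tuple(centre_u))
        truth = pose.to_image(shape_units)
        m = spec.margin
        if (truth[:, 0].min() >= m and truth[:, 0].max() <= w - 1 - m
                and truth[:, 1].min() >= m and truth[:, 1].max() <= h - 1 - m):
            break
        shrink *= 0.7
        log.warning("case %d: truth outside bounds, retrying with pose range x%.2f",
                    index, shrink)
    else:
        raise RuntimeError(f"could not place case {index} inside the image")
    pixels = _render(spec, shape_units, pose, rng)
    return SyntheticCase(
        image=Image(pixels=pixels, spacing=spec.spacing),
        truth=LandmarkSet(points=truth, spacing=spec.spacing),
        pose=pose, b=b, index=index)


def generate_cases(spec: SyntheticSpec, indices: range | None = None) -> list[SyntheticCase]:
    return [sample_case(spec, i) for i in (indices if indices is not None else range(spec.n))]


def write_dataset(spec: SyntheticSpec, out_dir: str | Path) -> dict:
    """Render the dataset to ``out_dir``: TIFF images, annotation text files
    and a JSON manifest recording the spec, its hash and per-case truth."""
    import tifffile

    from .io import write_annotation

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = []
    for i in range(spec.n):
        case = sample_case(spec, i)
        name = f"case{i:03d}"
        tifffile.imwrite(out / f"{name}.tif",
                         np.round(case.image.pixels * 65535).astype(np.uint16))
        write_annotation(case.truth, out / f"{name}.txt")
        records.append({
            "name": name,
            "pose": {"centre": list(case.pose.centre), "scale": case.pose.scale,
                     "angle": case.pose.angle, "ref": list(case.pose.ref)},
            "b": [float(v) for v in case.b],
        })
    manifest = {"spec": json.loads(spec.to_json()), "spec_hash": spec.digest(),
                "cases": records}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
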