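"""File formats: annotation text files, images, model archives, config.

Annotation dialect: one landmark per line, ``x,y`` in pixels (floats allowed),
lines ordered L1..L19; 0-based coordinates by default.  Extra trailing lines
are ignored with a warning.  Pixel spacing is configuration, not part of the
annotation file.

The model archive is a single zip file holding a JSON manifest plus raw
``.npy`` arrays, written canonically (sorted entries, fixed timestamps, no
compression) so that saving the same model always produces identical bytes.
"""

from __future__ import annotations

import io as _io
import json
import logging
import zipfile
from pathlib import Path

import numpy as np

from .ceph import LandmarkSet, N_LANDMARKS
from .imaging import Image

__all__ = [
    "read_annotation",
    "write_annotation",
    "read_image",
    "save_archive",
    "load_archive",
    "read_config",
]

log = logging.getLogger(__name__)


def read_annotation(path: str | Path, spacing: float = 0.1,
                    origin: int = 0) -> LandmarkSet:
    """Read a 19-landmark annotation file.

    ``origin`` subtracts 1 from both coordinates for 1-based files.  Raises a
    ``ValueError`` naming the offending line on short or unparseable files.
    """
    path = Path(path)
    lines = [ln.strip() for ln in path.read_text().splitlines()]
    pts = []
    for i, ln in enumerate(lines, start=1):
        if len(pts) == N_LANDMARKS:
            break
        if not ln:
            continue
        parts = ln.replace(";", ",").split(",")
        try:
            x, y = float(parts[0]), float(parts[1])
        except (ValueError, IndexError) as exc:
            raise ValueError(f"{path.name}: cannot parse line {i}: {ln!r}") from exc
        pts.append((x, y))
    if len(pts) < N_LANDMARKS:
        raise ValueError(
            f"{path.name}: expected {N_LANDMARKS} coordinate lines, "
            f"file ends at line {len(lines) + 1}")
    extra = sum(1 for ln in lines[len(pts):] if ln)
    if extra:
        log.warning("%s: %d trailing line(s) ignored", path.name, extra)
    points = np.asarray(pts, dtype=np.float64) - float(origin)
    return LandmarkSet(points=points, spacing=spacing)


def write_annotation(lm: LandmarkSet, path: str | Path) -> None:
    """Write a landmark set in the ``x,y`` dialect at 3-decimal precision."""
    lines = [f"{x:.3f},{y:.3f}" for x, y in lm.points]
    Path(path).write_text("\n".join(lines) + "\n")


def read_image(path: str | Path, spacing: float = 0.1) -> Image:
    """Read a grayscale TIFF or PNG as a float image scaled to [0, 1]."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile
        arr = tifffile.imread(path)
    else:
        from PIL import Image as PILImage
        arr = np.asarray(PILImage.open(path))
    if arr.ndim == 3:
        arr = arr[..., :3].mean(axis=2)
    orig = arr.dtype
    arr = arr.astype(np.float64)
    if orig.kind in "ui":
        arr /= float(np.iinfo(orig).max)
    elif arr.size and arr.max() > 1.0:
        arr /= arr.max()
    return Image(pixels=arr, spacing=spacing)


_FIXED_DATE = (1980, 1, 1, 0, 0, 0)


def save_archive(path: str | Path, manifest: dict,
                 arrays: dict[str, np.ndarray]) -> None:
    """Write a canonical zip archive: ``manifest.json`` + one ``.npy`` per
    array, entries sorted, fixed timestamps, stored uncompressed."""
    entries: dict[str, bytes] = {
        "manifest.json": json.dumps(manifest, indent=1, sort_keys=True).encode()}
    for name in sorted(arrays):
        buf = _io.BytesIO()
        np.lib.format.write_array(buf, np.ascontiguousarray(arrays[name]),
                                  version=(1, 0))
        entries[f"arrays/{name}.npy"] = buf.getvalue()
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_STORED) as zf:
        for name in sorted(entries):
            info = zipfile.ZipInfo(name, date_time=_FIXED_DATE)
            info.external_attr = 0o644 << 16
            zf.writestr(info, entries[name])


def load_archive(path: str | Path) -> tuple[dict, dict[str, np.ndarray]]:
    with zipfile.ZipFile(path) as zf:
        manifest = json.loads(zf.read("manifest.json"))
        arrays = {}
        for name in zf.namelist():
            if name.startswith("arrays/") and name.endswith(".npy"):
                buf = _io.BytesIO(zf.read(name))
                arrays[name[len("arrays/"):-len(".npy")]] = np.lib.format.read_array(buf)
    return manifest, arrays


def read_config(path: str | Path) -> dict[str, str]:
    """Parse a plain ``key = value`` config file; ``#`` starts a comment."""
    out: dict[str, str] = {}
    for i, ln in enumerate(Path(path).read_text().splitlines(), start=1):
        ln = ln.split("#", 1)[0].strip()
        if not ln:
            continue
        if "=" not in ln:
            raise ValueError(f"config line {i}: expected 'key = value', got {ln!r}")
        k, v = ln.split("=", 1)
        out[k.strip()] = v.strip()
    return out
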