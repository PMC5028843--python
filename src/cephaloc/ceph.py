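"""Cephalometric landmark semantics, clinical parameters and classification.

The 19 landmarks (sella ... articulare) support eight standard clinical
measurements used to diagnose skeletal malformations: the ANB/SNB/SNA angles,
the overbite depth indicator (ODI), the anteroposterior dysplasia indicator
(APDI), the facial height index (FHI), the Frankfurt mandibular angle (FMA)
and the modified Wits appraisal (MW).  Each measurement is assigned to one of
three to five classes (C1 = normal range) with fixed boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "LANDMARK_NAMES",
    "PARAMETER_NAMES",
    "LandmarkSet",
    "angle_at",
    "angle_between_lines",
    "compute_parameters",
    "classify",
]

LANDMARK_NAMES = (
    "sella",                  # L1
    "nasion",                 # L2
    "orbitale",               # L3
    "porion",                 # L4
    "subspinale",             # L5  (A-point)
    "supramentale",           # L6  (B-point)
    "pogonion",               # L7
    "menton",                 # L8
    "gnathion",               # L9
    "gonion",                 # L10
    "incision inferius",      # L11
    "incision superius",      # L12
    "upper lip",              # L13
    "lower lip",              # L14
    "subnasale",              # L15
    "soft tissue pogonion",   # L16
    "posterior nasal spine",  # L17
    "anterior nasal spine",   # L18
    "articulare",             # L19
)

PARAMETER_NAMES = ("ANB", "SNB", "SNA", "ODI", "APDI", "FHI", "FMA", "MW")

N_LANDMARKS = 19


@dataclass
class LandmarkSet:
    """19 named landmark positions in image pixels, with pixel spacing in mm.

    Point order is positional: row ``l`` is landmark ``L{l+1}``.
    """

    points: np.ndarray
    spacing: float = 0.1

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.shape != (N_LANDMARKS, 2):
            raise ValueError(f"expected ({N_LANDMARKS}, 2) landmark array")
        if not self.spacing > 0:
            raise ValueError("spacing must be positive")

    def L(self, i: int) -> np.ndarray:
        """1-based landmark accessor: ``L(1)`` is sella."""
        if not 1 <= i <= N_LANDMARKS:
            raise IndexError(f"landmark index {i} out of range 1..{N_LANDMARKS}")
        return self.points[i - 1]

    def in_mm(self) -> np.ndarray:
        return self.points * self.spacing


def angle_at(vertex, p, q) -> float:
    """Unsigned angle in degrees (0..180) between rays vertex->p and vertex->q."""
    v1 = np.asarray(p, dtype=np.float64) - np.asarray(vertex, dtype=np.float64)
    v2 = np.asarray(q, dtype=np.float64) - np.asarray(vertex, dtype=np.float64)
    n1, n2 = np.hypot(*v1), np.hypot(*v2)
    if n1 == 0 or n2 == 0:
        raise ValueError("angle undefined: ray endpoint coincides with the vertex")
    cross = v1[0] * v2[1] - v1[1] * v2[0]
    dot = float(v1 @ v2)
    return abs(math.degrees(math.atan2(cross, dot)))


def angle_between_lines(a1, a2, b1, b2) -> float:
    """Acute-form unsigned angle in degrees (0..90) between the undirected
    lines a1-a2 and b1-b2."""
    u = np.asarray(a2, dtype=np.float64) - np.asarray(a1, dtype=np.float64)
    v = np.asarray(b2, dtype=np.float64) - np.asarray(b1, dtype=np.float64)
    if not np.hypot(*u) or not np.hypot(*v):
        raise ValueError("degenerate line (coincident endpoints)")
    phi = abs(math.degrees(math.atan2(u[0] * v[1] - u[1] * v[0], float(u @ v))))
    return min(phi, 180.0 - phi)


def compute_parameters(lm: LandmarkSet, flip_mw_sign: bool = False) -> dict[str, float]:
    """The eight clinical measurements from a landmark set.

    Angles are in degrees, FHI is a ratio, MW is in mm (signed by the
    x-ordering of the incision points; ``flip_mw_sign`` for images whose
    anterior direction is leftward).
    """
    L = lm.L
    anb = angle_at(L(2), L(5), L(6))
    snb = angle_at(L(2), L(1), L(6))
    sna = angle_at(L(2), L(1), L(5))
    odi = angle_between_lines(L(5), L(6), L(8), L(10)) \
        + angle_between_lines(L(3), L(4), L(17), L(18))
    apdi = angle_between_lines(L(3), L(4), L(2), L(7)) \
        + angle_between_lines(L(2), L(7), L(5), L(6)) \
        + angle_between_lines(L(3), L(4), L(17), L(18))
    fhi = float(np.linalg.norm(L(1) - L(10)) / np.linalg.norm(L(2) - L(8)))
    fma = angle_between_lines(L(1), L(2), L(10), L(9))
    dx = L(12)[0] - L(11)[0]
    sign = float(np.sign(dx)) * (-1.0 if flip_mw_sign else 1.0)
    mw = sign * float(np.linalg.norm(L(12) - L(11))) * lm.spacing
    return {"ANB": anb, "SNB": snb, "SNA": sna, "ODI": odi,
            "APDI": apdi, "FHI": fhi, "FMA": fma, "MW": mw}


def _three_way(value: float, lo: float, hi: float, above: str, below: str) -> str:
    """C1 owns its closed range [lo, hi]; strict inequalities elsewhere."""
    if lo <= value <= hi:
        return "C1"
    return above if value > hi else below


def classify(values: dict[str, float]) -> dict[str, str]:
    """Map the eight measurement values to their C1..C5 classes.

    The named closed range owns its endpoints; the >/< classes are strict.
    MW uses five classes with C2 reserved for exactly 0 mm.
    """
    missing = [p for p in PARAMETER_NAMES if p not in values]
    if missing:
        raise ValueError(f"missing parameters: {missing}")
    for p in PARAMETER_NAMES:
        if not np.isfinite(values[p]):
            raise ValueError(f"non-finite value for {p}")
    out = {
        "ANB": _three_way(values["ANB"], 3.2, 5.7, above="C2", below="C3"),
        "SNB": _three_way(values["SNB"], 74.6, 78.7, above="C3", below="C2"),
        "SNA": _three_way(values["SNA"], 79.4, 83.2, above="C2", below="C3"),
        "ODI": _three_way(values["ODI"], 68.4, 80.5, above="C2", below="C3"),
        "APDI": _three_way(values["APDI"], 77.6, 85.2, above="C3", below="C2"),
        "FHI": _three_way(values["FHI"], 0.65, 0.75, above="C2", below="C3"),
        "FMA": _three_way(values["FMA"], 26.8, 31.4, above="C2", below="C3"),
    }
    mw = values["MW"]
    if mw == 0.0:
        out["MW"] = "C2"
    elif mw < 0.0:
        out["MW"] = "C3"
    elif mw < 2.0:
        out["MW"] = "C5"
    elif mw <= 4.5:
        out["MW"] = "C1"
    else:
        out["MW"] = "C4"
    return out
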