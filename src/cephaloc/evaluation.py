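"""Agreement statistics between two sets of annotations or classifications.

Point-to-point errors are Euclidean distances in mm between corresponding
landmarks of two annotation sets.  From the n-images × k-landmarks error
matrix the module derives the landmark-specific mean error (PEL, mean over
images), the image-specific mean error (PEI, mean over landmarks), the
overall mean (PE), successful detection rates (SDR: percentage of images
with a landmark within a precision range z), and empirical CDFs of the PEI.
Classification agreement is summarised per clinical parameter by a confusion
matrix whose diagonal row-percentages are the successful classification
rates (SCR), plus the overall accuracy over subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ceph import LandmarkSet

__all__ = [
    "SDR_RANGES",
    "ErrorSummary",
    "error_matrix",
    "summarise",
    "sdr",
    "cdf_curve",
    "scr_confusion",
]

# precision ranges (mm) reported in landmark-detection studies
SDR_RANGES = (2.0, 2.5, 3.0, 4.0)


def error_matrix(manual: list[LandmarkSet], auto: list[LandmarkSet]) -> np.ndarray:
    """Per-image, per-landmark Euclidean distances in mm, shape (n, k)."""
    if len(manual) != len(auto) or not manual:
        raise ValueError("annotation lists must be non-empty and equally long")
    rows = []
    for m, a in zip(manual, auto):
        if m.points.shape != a.points.shape:
            raise ValueError("landmark counts differ between sets")
        if m.spacing != a.spacing:
            raise ValueError("pixel spacings differ between sets")
        d = m.points - a.points
        rows.append(np.hypot(d[:, 0], d[:, 1]) * m.spacing)
    return np.stack(rows)


@dataclass
class ErrorSummary:
    pel: np.ndarray        # (k,) mean error per landmark, mm
    pel_se: np.ndarray     # (k,) standard error over images
    pei: np.ndarray        # (n,) mean error per image, mm
    pe: float              # grand mean, mm
    pe_se: float           # standard error over all n*k entries

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({"PEL_mm": self.pel, "SE_mm": self.pel_se},
                            index=[f"L{i+1}" for i in range(len(self.pel))])


def summarise(errs: np.ndarray) -> ErrorSummary:
    """PEL/PEI/PE with standard errors from an (n, k) error matrix."""
    errs = np.asarray(errs, dtype=np.float64)
    if errs.ndim != 2 or errs.size == 0:
        raise ValueError("error matrix must be non-empty and 2D")
    n, k = errs.shape
    pel = errs.mean(axis=0)
    pel_se = errs.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(k)
    pei = errs.mean(axis=1)
    pe = float(errs.mean())
    pe_se = float(errs.std(ddof=1) / np.sqrt(errs.size)) if errs.size > 1 else 0.0
    return ErrorSummary(pel=pel, pel_se=pel_se, pei=pei, pe=pe, pe_se=pe_se)


def sdr(errs: np.ndarray, z: float | tuple[float, ...] = SDR_RANGES) -> pd.DataFrame:
    """Successful detection rates: percentage of images with error <= z mm.

    Returns a DataFrame with one column per precision range, one row per
    landmark plus an ``average`` row (mean over landmarks).
    """
    errs = np.asarray(errs, dtype=np.float64)
    zs = (z,) if np.isscalar(z) else tuple(z)
    if any(v <= 0 for v in zs):
        raise ValueError("precision ranges must be positive")
    n, k = errs.shape
    data = {}
    for v in zs:
        rates = 100.0 * (errs <= v).sum(axis=0) / n
        data[f"{v:g}mm"] = np.append(rates, rates.mean())
    idx = [f"L{i+1}" for i in range(k)] + ["average"]
    return pd.DataFrame(data, index=idx)


def cdf_curve(pei: np.ndarray, thresholds: np.ndarray | None = None
              ) -> pd.DataFrame:
    """Empirical CDF of image-specific errors over a threshold grid."""
    pei = np.asarray(pei, dtype=np.float64)
    if pei.size == 0:
        raise ValueError("need at least one image error")
    if thresholds is None:
        top = float(pei.max())
        thresholds = np.linspace(0.0, top * 1.05 if top > 0 else 1.0, 101)
    props = [(pei <= t).mean() for t in thresholds]
    return pd.DataFrame({"threshold_mm": thresholds, "proportion": props})


def scr_confusion(manual_classes: list[str], auto_classes: list[str],
                  labels: list[str] | None = None) -> dict:
    """Classification agreement for one clinical parameter.

    Returns the confusion count matrix (rows = manual, columns = automatic),
    its row-normalised percentages (diagonal = per-class SCR), and the
    overall accuracy as the fraction of exact matches over subjects.
    """
    if len(manual_classes) != len(auto_classes) or not manual_classes:
        raise ValueError("class lists must be non-empty and equally long")
    if labels is None:
        labels = sorted(set(manual_classes) | set(auto_classes))
    counts = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    for m, a in zip(manual_classes, auto_classes):
        counts.loc[m, a] += 1
    row_sums = counts.sum(axis=1)
    pct = counts.div(row_sums.replace(0, np.nan), axis=0) * 100.0
    scr = {lab: float(pct.loc[lab, lab]) if row_sums[lab] else np.nan
           for lab in labels}
    accuracy = 100.0 * sum(m == a for m, a in zip(manual_classes, auto_classes)) \
        / len(manual_classes)
    return {"counts": counts, "percent": pct, "scr": scr,
            "accuracy": float(accuracy)}
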