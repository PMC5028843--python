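"""Ready-made system configurations and a one-call training pipeline.

``full_resolution()`` is the configuration for real lateral cephalograms
(1935x2400 px at 0.1 mm/px): refinement frame width 500 with the improved
sampling settings (ps 30, tr ±30, sr ±(0.3 pr + 7)), a coarse stage at width
100 with the original bone-contour settings, and a width-100 detector.

``compact()`` scales the frame widths down (coarse 50, fine 120) with the
stage parameters scaled proportionally; it is sized for the bundled
synthetic-data generator and is what the tests and example scripts use.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .clm import (COARSE_STAGE, FINE_STAGE, StageConfig, TwoStageModel,
                  train_stage)
from .detector import DetectorConfig, DetectorModel, train_detector
from .imaging import Image

__all__ = ["SystemConfig", "full_resolution", "compact", "train_system"]


@dataclass
class SystemConfig:
    detector: DetectorConfig
    coarse: StageConfig
    fine: StageConfig
    n_coarse_iterations: int = 10
    n_fine_iterations: int = 1
    early_stop_threshold: float = 4.0


def full_resolution() -> SystemConfig:
    return SystemConfig(detector=DetectorConfig(),
                        coarse=COARSE_STAGE, fine=FINE_STAGE)


def compact() -> SystemConfig:
    """Scaled-down system (coarse 50, fine 120) for small rasters.

    The refinement-stage sampling parameters are the improved settings
    scaled by 120/500; the coarse stage scales the original settings by
    50/100.
    """
    return SystemConfig(
        detector=DetectorConfig(
            frame_width=50, ps=14, n_features=150, samples_per_image=100,
            n_trees=15, smooth=5, scale_factors=(0.8, 1.0, 1.25),
            scan_angles=tuple(np.deg2rad((-12.0, -6.0, 0.0, 6.0, 12.0)))),
        coarse=StageConfig(frame_width=50, ps=10, tr=7.5, sr_a=1.0, sr_c=7.5,
                           n_features=120, samples_per_image=15),
        fine=StageConfig(frame_width=120, ps=7, tr=7.2, sr_a=0.3, sr_c=1.7,
                         n_features=150, samples_per_image=20),
    )


def train_system(images: list[Image], annotations: list[np.ndarray],
                 cfg: SystemConfig | None = None, seed: int = 0
                 ) -> tuple[DetectorModel, TwoStageModel]:
    """Train detector, coarse and fine stages on annotated images."""
    cfg = cfg or full_resolution()
    det = train_detector(images, annotations, cfg.detector, rng_seed=seed + 11)
    coarse = train_stage(images, annotations, cfg.coarse, rng_seed=seed + 21)
    fine = train_stage(images, annotations, cfg.fine, rng_seed=seed + 31)
    ts = TwoStageModel(coarse=coarse, fine=fine,
                       n_coarse_iterations=cfg.n_coarse_iterations,
                       n_fine_iterations=cfg.n_fine_iterations,
                       early_stop_threshold=cfg.early_stop_threshold)
    return det, ts
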