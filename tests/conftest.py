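"""Shared fixtures: synthetic datasets and trained models.

The heavy fixtures are session-scoped so the 50-image training run and the
held-out searches are done once and shared across the localisation and
acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from cephaloc.clm import search
from cephaloc.presets import compact, train_system
from cephaloc.synth import SyntheticSpec, sample_case

TRAIN_N = 50
TEST_N = 20


@pytest.fixture(scope="session")
def synth_spec():
    return SyntheticSpec(n=TRAIN_N + TEST_N, seed=1)


@pytest.fixture(scope="session")
def train_cases(synth_spec):
    return [sample_case(synth_spec, i) for i in range(TRAIN_N)]


@pytest.fixture(scope="session")
def test_cases(synth_spec):
    return [sample_case(synth_spec, i) for i in range(TRAIN_N, TRAIN_N + TEST_N)]


@pytest.fixture(scope="session")
def trained_system(train_cases):
    """Detector + two-stage model trained on the 50 training cases with the
    compact (scaled-down frame width) configuration."""
    det, ts = train_system([c.image for c in train_cases],
                           [c.truth.points for c in train_cases],
                           compact(), seed=1)
    return det, ts


@pytest.fixture(scope="session")
def search_results(trained_system, test_cases):
    """Early-stop search results on the 20 held-out cases."""
    det, ts = trained_system
    return [search(ts, det, c.image, early_stop=True) for c in test_cases]


def frame_errors(ts, case, points):
    """Point errors in refinement-frame px for one case."""
    from cephaloc.shape import similarity_fit

    fit = similarity_fit(ts.fine.shape_model.mean, case.truth.points)
    d = points - case.truth.points
    return np.hypot(d[:, 0], d[:, 1]) / fit.scale
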