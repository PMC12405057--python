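"""Shared fixtures: session-scoped synthetic cohorts and helper builders.

Heavy artifacts (feature tables for the 3-regime cohort) are computed once
per session and shared between the clustering, anomaly and acceptance
tests.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np
import pytest

from beevein.preprocess import DESK_PROFILE
from beevein.synthetic import STUDY_REGIMES, SyntheticWingSpec, generate_cohort, make_wing

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def medium_wing():
    """One clean medium-regime wing: (image, ground truth)."""
    return make_wing(replace(STUDY_REGIMES["medium"], seed=1))


@pytest.fixture(scope="session")
def regime_cohort():
    """3 regimes x 50 degraded wings, no anomalies (parameter-recovery
    study size)."""
    return generate_cohort(list(STUDY_REGIMES.values()), 50, anomaly_fraction=0.0, seed=11)


@pytest.fixture(scope="session")
def regime_features(regime_cohort):
    """Feature table + regime labels for the 3-regime cohort, via the full
    image pipeline under the desk calibration profile."""
    from beevein.pipeline import process_images

    table = process_images(
        regime_cohort.images, regime_cohort.manifest["image_id"], DESK_PROFILE
    )
    return table, regime_cohort.manifest["regime_label"].to_numpy()


@pytest.fixture(scope="session")
def anomaly_cohort():
    """3 regimes x 40 wings with 10% injected tears/occlusions."""
    return generate_cohort(list(STUDY_REGIMES.values()), 40, anomaly_fraction=0.1, seed=5)


def line_mask(shape, r0, c0, r1, c1, width=1):
    """Straight line fixture on a boolean grid."""
    from skimage.draw import line

    m = np.zeros(shape, dtype=bool)
    rr, cc = line(r0, c0, r1, c1)
    m[rr, cc] = True
    if width > 1:
        from scipy import ndimage

        m = ndimage.binary_dilation(m, iterations=(width - 1) // 2)
    return m
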