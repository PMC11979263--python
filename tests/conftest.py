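"""Shared fixtures: one scaled-down study cohort reused across the suite.

The cohort emulates the target population at desk scale: 75 patients (60
train / 15 test under the study split) with the default class mix, 3 vessels
x up to 8 views each, 120-row images whose 107 x 41 ROI spans the whole
vessel. Radiomic features are deterministic per cohort, so they are
extracted once per session.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest
from hypothesis import settings

from stenograde.pipeline import StudyArtifacts, prepare_cohort
from stenograde.synthetic import CohortSpec

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")

#: Identity of the scaled-down study cohort (fixed: the synthetic "dataset").
STUDY_SEED = 20260927
STUDY_ROI_ROWS = 107


@pytest.fixture(scope="session")
def study_cohort() -> tuple[CohortSpec, StudyArtifacts]:
    spec = CohortSpec(n_patients=75, image_rows=120, seed=STUDY_SEED)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        art = prepare_cohort(spec, target_rows=STUDY_ROI_ROWS)
    return spec, art


@pytest.fixture(scope="session")
def small_cohort():
    """A fast 8-patient cohort for structural checks."""
    from stenograde.synthetic import generate_cohort

    spec = CohortSpec(n_patients=8, image_rows=140, seed=11)
    images, truths = generate_cohort(spec)
    return spec, images, truths


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
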