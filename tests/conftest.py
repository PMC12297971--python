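"""Shared fixtures: viewing conditions and a reusable synthetic image study.

The image study emulates the acquisition protocol (10 s baseline, 30 s cuff
compression, 60 s post-release) for 20 subjects at reduced frame geometry
and frame rate so the whole end-to-end path stays fast; the colour dynamics
are the generator defaults.
"""

import numpy as np
import pytest

from perfcolour.colour import derive_viewing_conditions
from perfcolour.features import ProtocolTiming, build_feature_table
from perfcolour.imaging import Landmarks, ROIBox
from perfcolour.synthetic import SkinDynamicsParams, simulate_sequence

SMALL_SHAPE = (60, 80)
SMALL_ROI = ROIBox(12, 4, 50, 50)
SMALL_LM = Landmarks((5.0, 30.0), (75.0, 30.0))


@pytest.fixture(scope="session")
def vc_default():
    return derive_viewing_conditions()


@pytest.fixture(scope="session")
def vc_literal():
    return derive_viewing_conditions(mode="literal")


@pytest.fixture(scope="session")
def study_timing():
    return ProtocolTiming(fps=3.0)


def make_subject_params(seed: int, blanch_scale: float = 1.0) -> SkinDynamicsParams:
    """Per-subject generator parameters with seeded tone jitter."""
    rng = np.random.default_rng(seed)
    tone = np.asarray((204.0, 160.0, 140.0)) + rng.normal(0, (4.0, 3.0, 3.0))
    base = SkinDynamicsParams()
    return SkinDynamicsParams(
        baseline_rgb=tuple(tone),
        blanch_shift=tuple(blanch_scale * np.asarray(base.blanch_shift)),
        frame_shape=SMALL_SHAPE,
        roi=SMALL_ROI,
        landmarks=SMALL_LM,
        seed=seed,
    )


def simulate_study(n_subjects, timing, blanch_scale=1.0, seed0=100):
    return {
        f"S{k:02d}": simulate_sequence(make_subject_params(seed0 + k, blanch_scale), timing)[0]
        for k in range(n_subjects)
    }


@pytest.fixture(scope="session")
def image_study_table(study_timing, vc_literal):
    """Feature table extracted end-to-end from 20 synthetic subject sequences."""
    sequences = simulate_study(20, study_timing)
    return build_feature_table(sequences, SMALL_ROI, vc_literal, study_timing)
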