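"""Shared fixtures: standard media and cached end-to-end synthetic runs."""

import numpy as np
import pytest

from fdnirs.occlusion import ARTERIAL_PROTOCOL, VENOUS_PROTOCOL, analyze_occlusion
from fdnirs.sensitivity import HemodynamicScenario
from fdnirs.synthetic import (
    FOREARM_COHORT,
    InstrumentModel,
    OcclusionSchedule,
    make_subject,
    noiseless_channel_matrix,
    apply_instrument,
)

#: The six baseline (μa, μs′) property sets of the three-layer forearm
#: parameterization (layer × wavelength), mm⁻¹.
TABLE_PROPERTY_SETS = [
    (0.0084, 1.0),
    (0.0110, 0.98),
    (0.0170, 0.5),
    (0.0233, 0.42),
    (0.0084, 1.5),
    (0.0114, 1.3),
]


@pytest.fixture(scope="session")
def subject1_media():
    """Three-layer media (690/830 nm) for the shallowest-bone subject."""
    return make_subject(FOREARM_COHORT[0])


@pytest.fixture(scope="session")
def venous_run(subject1_media):
    """Noiseless venous occlusion recording + full analysis for subject 1."""
    scen = HemodynamicScenario("venous", (5.0, 10.0, 0.0))
    sched = OcclusionSchedule(scen, VENOUS_PROTOCOL)
    t, resp = noiseless_channel_matrix(subject1_media, sched)
    quiet = InstrumentModel(amplitude_noise_rel=0.0, phase_noise_rad=0.0, seed=0)
    frame = apply_instrument(t, resp, quiet)
    return {
        "media": subject1_media,
        "scenario": scen,
        "schedule": sched,
        "time": t,
        "responses": resp,
        "frame": frame,
        "analysis": analyze_occlusion(frame, VENOUS_PROTOCOL),
    }


@pytest.fixture(scope="session")
def arterial_run(subject1_media):
    """Noiseless arterial occlusion recording + analysis for subject 1."""
    scen = HemodynamicScenario("arterial", (5.0, 10.0, 0.0))
    sched = OcclusionSchedule(scen, ARTERIAL_PROTOCOL)
    t, resp = noiseless_channel_matrix(subject1_media, sched)
    quiet = InstrumentModel(amplitude_noise_rel=0.0, phase_noise_rad=0.0, seed=0)
    frame = apply_instrument(t, resp, quiet)
    return {
        "media": subject1_media,
        "scenario": scen,
        "schedule": sched,
        "time": t,
        "responses": resp,
        "frame": frame,
        "analysis": analyze_occlusion(frame, ARTERIAL_PROTOCOL),
    }
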