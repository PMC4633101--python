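"""Shared fixtures: reference dynamical systems and synthetic cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from armdyn.io_preprocess import ComponentSeries, KinematicRecording
from armdyn.reference_systems import ar2_series, henon_series

__all__ = ["ar2_series", "henon_series"]


@pytest.fixture(scope="session")
def henon2000() -> ComponentSeries:
    return ComponentSeries(henon_series(2000, 0), 100.0, filtered=True)


@pytest.fixture(scope="session")
def normal_recording() -> KinematicRecording:
    from armdyn.synthetic import SimulationParams, simulate_normal_subject

    return simulate_normal_subject(SimulationParams.normal(seed=7))


@pytest.fixture(scope="session")
def patient_recording() -> KinematicRecording:
    from armdyn.synthetic import SimulationParams, simulate_patient_subject

    return simulate_patient_subject(SimulationParams.patient(seed=7))


@pytest.fixture(scope="session")
def filtered_normal(normal_recording):
    from armdyn.io_preprocess import filter_recording

    return filter_recording(normal_recording)


@pytest.fixture(scope="session")
def filtered_patient(patient_recording):
    from armdyn.io_preprocess import filter_recording

    return filter_recording(patient_recording)
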