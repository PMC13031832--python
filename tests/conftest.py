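"""Shared fixtures.

The heavyweight fixtures (the feasibility-filtered training ensemble and
the 45 fitted GP emulators under the default desk-scale study conditions)
are session-scoped: they are built once and shared by the emulator,
calibration and study tests.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from mmscalib.design import PriorBox, build_training_ensemble
from mmscalib.emulator import fit_emulators
from mmscalib.forward_model import (
    PacingProtocol,
    TissueParameters,
    default_cable_grid,
)

#: Study conditions: target ensemble size mirroring the reference workflow.
TARGET_M = 202
ENSEMBLE_SEED = 11
EMULATOR_SEED = 3


@pytest.fixture(scope="session")
def prior_box() -> PriorBox:
    return PriorBox.default()


@pytest.fixture(scope="session")
def training_ensemble(prior_box):
    """Desk-scale training ensemble: 1D cable, S1S2, 15 sites, 3 types."""
    return build_training_ensemble(box=prior_box, target_m=TARGET_M, seed=ENSEMBLE_SEED)


@pytest.fixture(scope="session")
def fitted_emulators(training_ensemble):
    """(EmulatorSet, validation report) with a 20% held-out split."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_emulators(training_ensemble, test_fraction=0.2, seed=EMULATOR_SEED)


@pytest.fixture(scope="session")
def emulators(fitted_emulators):
    return fitted_emulators[0]


@pytest.fixture(scope="session")
def emulator_report(fitted_emulators):
    return fitted_emulators[1]


@pytest.fixture(scope="session")
def cable_grid():
    return default_cable_grid()


@pytest.fixture(scope="session")
def midpoint_params(prior_box) -> TissueParameters:
    return TissueParameters.from_array(prior_box.midpoint)


@pytest.fixture(scope="session")
def short_protocol() -> PacingProtocol:
    """Single-S1 protocol for cheap solver-behaviour tests."""
    return PacingProtocol(n_s1=1, s1_interval=800.0, s2_coupling=500.0)
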