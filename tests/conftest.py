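"""Shared fixtures: small synthetic sessions reused across test modules."""

import dataclasses

import numpy as np
import pytest

from pfcdyn.io_core import AnalysisConfig
from pfcdyn.synthetic_data import SimParams, default_channel_map, make_experiment


@pytest.fixture(scope="session")
def cfg() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture(scope="session")
def small_params() -> SimParams:
    """Reduced unit counts to keep full-session tests fast."""
    return SimParams(n_units_per_region={"IL": 10, "PL": 20, "CG": 10}, seed=11)


@pytest.fixture(scope="session")
def drug_session(small_params):
    """One synthetic 0.3 mg/kg day-0 session (LFP, units, schedule)."""
    return make_experiment(small_params, drug="psi_0.3", seed=11)


@pytest.fixture(scope="session")
def saline_session(small_params):
    return make_experiment(small_params, drug="saline", seed=11)


@pytest.fixture(scope="session")
def small_channels():
    return default_channel_map({"IL": 2, "PL": 2, "CG": 2})
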