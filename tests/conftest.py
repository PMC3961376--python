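"""Shared fixtures: small phantom subjects generated once per session."""

import numpy as np
import pytest

from boldcv.phantom import PhantomSpec, generate_subject


@pytest.fixture(scope="session")
def default_spec() -> PhantomSpec:
    """Desk-scale default acquisition: 32^3 grid, TR 2 s, 180 volumes."""
    return PhantomSpec(seed=42, motion_amp_mm=0.2)


@pytest.fixture(scope="session")
def default_subject(default_spec):
    return generate_subject(default_spec)


@pytest.fixture(scope="session")
def clean_spec() -> PhantomSpec:
    """Phantom with every nuisance source disabled: pure intrinsic fluctuation."""
    return PhantomSpec(
        seed=7,
        drift_slope_frac_per_scan=0.0,
        physio_amp_frac={"GM": 0.0, "WM": 0.0, "CSF": 0.0},
        thermal_sd_frac=0.0,
    )


@pytest.fixture(scope="session")
def clean_subject(clean_spec):
    return generate_subject(clean_spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
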