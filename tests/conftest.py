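import numpy as np
import pytest

from gimkit import (
    LayoutConfig,
    build_gim,
    calibrate_cml,
    estimate_persons,
    make_fsep_fixture,
)

FIXTURE_SEED = 42


@pytest.fixture(scope="session")
def fsep():
    """Exam-shaped fixture: 60 anchored items, 200 candidates, true thetas."""
    return make_fsep_fixture(seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def calibrated_cohort():
    """Large simulated cohort calibrated by CML (for fit/facility checks)."""
    bank, resp, theta = make_fsep_fixture(seed=7, n_persons=2000)
    result = calibrate_cml(resp)
    return bank, resp, theta, result


def build_reference_layout():
    """The frozen-candidate layout used for golden-file comparisons."""
    bank, resp, _ = make_fsep_fixture(seed=FIXTURE_SEED)
    abilities = estimate_persons(resp, bank.difficulties())
    config = LayoutConfig(pass_standard="75%")
    return build_gim("C0001", resp, bank, abilities, config)


@pytest.fixture(scope="session")
def reference_layout():
    return build_reference_layout()
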