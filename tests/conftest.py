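import numpy as np
import pytest

from aeroscope import PhenotypeParams, TraceConfig, run_pipeline
from aeroscope.fixtures import golden_config, noisy_config


@pytest.fixture
def basic_params():
    """A mid-range fish: 60 mg/kg/h SMR at 16 degC, Q10=2, broad MMR peak."""
    return PhenotypeParams(
        individual_id="F01",
        mass_kg=1.0,
        smr_ref=60.0,
        q10_smr=2.0,
        mmr_peak=420.0,
        t_opt_c=16.5,
        breadth_c=8.0,
        tau_recovery_s=3600.0,
        circadian_amp=0.0,
    )


@pytest.fixture
def short_config():
    """Noiseless 2-h protocol: cheap traces with exact slopes."""
    return TraceConfig(
        noise_sd_mg_l=0.0,
        background_slope_mg_l_min=0.0,
        smr_duration_h=2.0,
        recovery_duration_h=1.0,
        background_duration_h=0.5,
        seed=3,
    )


@pytest.fixture(scope="session")
def golden_result():
    """Pipeline output of the noiseless 3-fish golden cohort (1 run/session)."""
    return run_pipeline(golden_config())


@pytest.fixture(scope="session")
def noisy_result():
    """Pipeline output of the 9-fish noisy fixture cohort (1 run/session)."""
    return run_pipeline(noisy_config())


@pytest.fixture
def rng():
    return np.random.default_rng(42)
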