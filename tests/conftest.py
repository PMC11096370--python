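"""Shared fixtures: noiseless synthetic calibration inputs and fitted curves."""

import numpy as np
import pytest

import cornekin as ck
from cornekin import synthetic as syn


@pytest.fixture(scope="session")
def noiseless_config() -> syn.GeneratorConfig:
    return syn.GeneratorConfig(
        seed=1,
        activity=syn.ActivityAssayConfig(noise_sd=0.0),
        calibration=syn.RatioCalibrationConfig(noise_sd=0.0),
    )


@pytest.fixture(scope="session")
def curves(noiseless_config) -> ck.RateFunctions:
    """Rate functions fitted to noiseless synthetic calibration tables."""
    return ck.RateFunctions(
        a_klk=ck.fit_activity_curve(syn.gen_activity_assay(noiseless_config, "klk5")),
        a_meso=ck.fit_activity_curve(syn.gen_activity_assay(noiseless_config, "mesotrypsin")),
        binding=ck.fit_binding_rates(syn.gen_binding_table(noiseless_config)),
    )


@pytest.fixture(scope="session")
def stepwise_profile() -> ck.PHProfile:
    return ck.make_named_profile("stepwise_7.0_6.0_5.4_6.7")


@pytest.fixture(scope="session")
def default_params() -> ck.ModelParams:
    return ck.ModelParams(k_auto=1e4, k_meso=3e5, k_deg=0.0)


@pytest.fixture(scope="session")
def solved_trajectory(default_params, stepwise_profile, curves) -> ck.Trajectory:
    return ck.simulate(default_params, stepwise_profile, curves)


@pytest.fixture(scope="session")
def inert_binding() -> ck.BindingRateCurves:
    """Binding rates so small that complex formation is negligible."""
    return ck.fit_binding_rates(
        ck.BindingRatePoints(ph=[4.0, 6.0, 8.0], ka=[1e-15] * 3, kd=[1e-15] * 3)
    )
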