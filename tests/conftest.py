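"""Shared fixtures: noiseless and noisy synthetic experiments.

All fixtures are generated programmatically; no data files are stored.
"""

import pytest

from cdbind import (
    DPPHGenConfig,
    ITCGenConfig,
    NMRGenConfig,
    gen_cv_dataset,
    gen_dpph_traces,
    gen_itc_heats,
)

# Ground truth shared by the fixtures below.
NMR_TRUE_K = 6.181e3  # M^-1
ITC_TRUE = {"n": 1.098, "K": 3.92e3, "dH": -2.36}  # dH in kJ/mol


@pytest.fixture(scope="session")
def noiseless_cv():
    """11-sample continuous-variation series at 10 mM total, no noise."""
    return gen_cv_dataset(NMRGenConfig(K=NMR_TRUE_K, shift_noise_sd=0.0), seed=0)


@pytest.fixture(scope="session")
def noiseless_itc():
    """25 x 10 uL titration of 4 mM guest into 1 mM host, no noise."""
    return gen_itc_heats(ITCGenConfig(**ITC_TRUE, heat_noise_sd=0.0), seed=0)


@pytest.fixture(scope="session")
def clean_dpph_traces():
    """Free + complex kinetic traces at three concentrations, no noise."""
    return gen_dpph_traces(DPPHGenConfig(absorbance_noise_sd=0.0), seed=0)
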