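import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ptssnmr import ExperimentSettings, SpinSegment, load_default_table
from ptssnmr.peaks import SIGNATURE_GROUPS

settings.register_profile(
    "det", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture(scope="session")
def default_settings() -> ExperimentSettings:
    return ExperimentSettings()


@pytest.fixture(scope="session")
def ch2() -> SpinSegment:
    return SpinSegment(multiplicity=2, label="CH2")


@pytest.fixture(scope="session")
def table():
    return load_default_table()


@pytest.fixture(scope="session")
def signatures(table):
    return [table.signature_set(g) for g in SIGNATURE_GROUPS]


@pytest.fixture(scope="session")
def rh_series_triplets(default_settings, signatures):
    """Processed DP/CP/INEPT triplets over the hydration series at 32 C,
    fixed seed, SNR 50 (shared across tests to keep the suite fast)."""
    from ptssnmr import (SampleState, SpectrumTriplet, process_fid, sc_sample,
                        sigma_for_snr, simulate_triplet)

    triplets = []
    for rh in (80.0, 85.0, 90.0, 93.0, 96.0):
        state = SampleState(rh_percent=rh)
        spec = sc_sample(state, seed=7)
        sigma = sigma_for_snr(spec, 50.0, default_settings)
        fids = simulate_triplet(spec, default_settings, noise_sigma=sigma, seed=7)
        spectra = {k: process_fid(v) for k, v in fids.items()}
        triplets.append(SpectrumTriplet(dp=spectra["DP"], cp=spectra["CP"],
                                        inept=spectra["INEPT"], sample_state=state))
    return triplets
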