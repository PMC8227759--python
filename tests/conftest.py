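import numpy as np
import pytest

from hydroted import DEFAULT_CONSTANTS, CompoundSeries, CompoundTruth, generate_compound


@pytest.fixture
def constants():
    return DEFAULT_CONSTANTS


@pytest.fixture
def spec_truth():
    """A Class A compound with xi_w = 4 on the standard liquid-water grid."""
    return CompoundTruth(
        dH_mot=-104100.0,
        dS_mot=-1868.0,
        n_w=4.0,
        noise_sd_lnK=0.0,
        T_grid=np.arange(273.0, 374.0, 10.0),
    )


@pytest.fixture
def noiseless_series(spec_truth):
    return generate_compound(spec_truth, seed=0)


def make_series(dH_mot, dS_mot, n_w, noise_sd=0.0, seed=0, T_grid=None):
    """Convenience constructor used across test modules."""
    truth = CompoundTruth(
        dH_mot, dS_mot, n_w, noise_sd,
        np.arange(273.0, 374.0, 10.0) if T_grid is None else np.asarray(T_grid, float),
    )
    return truth, generate_compound(truth, seed=seed)


@pytest.fixture
def make_series_fn():
    return make_series
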