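import numpy as np
import pytest

from qpcrcal import PlateModel, SimConfig, simulate_plate


@pytest.fixture(scope="session")
def noiseless_plate():
    """Ideal kinetics, zero noise: closed-form recovery oracle."""
    cfg = SimConfig(noise_sd_frac=0.0, additive_sd=0.0, seed=None)
    return simulate_plate(cfg)


@pytest.fixture(scope="session")
def noiseless_results(noiseless_plate):
    return PlateModel(noiseless_plate.run).fit()


@pytest.fixture(scope="session")
def noisy_plate():
    """Default study conditions: 1% multiplicative noise, seeded."""
    return simulate_plate(SimConfig(seed=11))


def logistic_curve(n, amplitude=1000.0, midpoint=25.0, slope=1.5):
    """Four-parameter-free logistic used as the analytic landmark oracle."""
    n = np.asarray(n, dtype=float)
    return amplitude / (1.0 + np.exp(-(n - midpoint) / slope))


def logistic_sdm_analytic(midpoint, slope):
    """Argmax of the analytic second derivative of the logistic.

    d2F/dn2 of A/(1+exp(-(n-m)/s)) vanishes curvature-wise at
    n = m - s*ln(2+sqrt(3)) (the inflection of the first derivative's
    rising flank), obtained by differentiating twice and solving; used as
    the independent dense-grid-verified oracle for SDM detection.
    """
    return midpoint - slope * np.log(2.0 + np.sqrt(3.0))
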