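import numpy as np
import pytest

from gcnet.synthcohort import BandTarget, VarModelSpec, make_var_model, simulate_var


@pytest.fixture(scope="session")
def coupled_pair_model():
    """2-ROI model with a single 10 Hz coupling 0 -> 1 (fs = 250)."""
    return make_var_model(2, [BandTarget(0, 1, 10.0, 3.0, 0.05)], seed=1,
                          fs=250.0)


@pytest.fixture(scope="session")
def coupled_pair_series(coupled_pair_model):
    """Long simulation (T = 60000) of the coupled pair, shared across tests."""
    return simulate_var(coupled_pair_model, 60000, seed=7)


@pytest.fixture(scope="session")
def fitted_pair(coupled_pair_series):
    from gcnet import specgc

    ts = coupled_pair_series
    return specgc.fit_var(ts.data[0], ts.data[1], 30, fs=ts.fs)


def random_stable_var2(rng, coupling=(0.15, 0.35), max_radius=0.95):
    """Rejection-sample a stable 2-ROI VAR(2) with diagonal noise and a solid
    direct coupling 0 -> 1 (shared helper for identity/calibration tests)."""
    while True:
        coeff = rng.uniform(-0.45, 0.45, size=(2, 2, 2))
        coeff[0, 1, 0] = rng.uniform(*coupling) * rng.choice([-1, 1])
        try:
            model = VarModelSpec(coeff=coeff,
                                 noise_cov=np.diag(rng.uniform(0.8, 1.2, 2)),
                                 fs=500.0)
        except ValueError:
            continue
        if model.companion_spectral_radius() < max_radius:
            return model
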