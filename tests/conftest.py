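import warnings

import numpy as np
import pytest

from cervkin.kinematics import compute_signals
from cervkin.synthetic import TrialGenParams, generate_trial


@pytest.fixture(scope="session")
def clean_trial():
    """Noiseless symmetric minimum-jerk trial (300 °/s peak, 60° amplitude)."""
    return generate_trial(TrialGenParams(peak_speed_deg_s=300.0, rom_deg=60.0, seed=7))


@pytest.fixture(scope="session")
def clean_signals(clean_trial):
    return compute_signals(clean_trial)


@pytest.fixture(scope="session")
def realistic_signals():
    """A trial with asymmetry, ripple, axis wobble and sensor noise."""
    p = TrialGenParams(
        peak_speed_deg_s=300.0,
        rom_deg=60.0,
        ad_asym=0.8,
        ripple_frac=0.04,
        axis_wobble_deg=1.2,
        sensor_noise_deg=0.15,
        seed=3,
    )
    return compute_signals(generate_trial(p))


@pytest.fixture(scope="session")
def small_cohort():
    """8 + 8 subjects, one session — enough for pipeline plumbing tests."""
    from dataclasses import replace

    from cervkin.synthetic import CohortGenConfig, generate_cohort

    cfg = CohortGenConfig(seed=11)
    cfg = replace(cfg, con=replace(cfg.con, n=8), ns=replace(cfg.ns, n=8))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_cohort(cfg)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-ish random rotation via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q
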