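import numpy as np
import pytest

import perisacc as p


def minjerk_trace(
    amplitudes,
    onsets,
    duration_rule=lambda a: 2.7 * a + 25.0,
    total_ms=2000.0,
    noise_sd=0.0,
    direction=(1.0, 0.0),
    seed=0,
):
    """Build a noise-free (or noisy) trace with minimum-jerk saccades.

    Test-local construction, independent of the session generator: each
    saccade moves the eye by ``amplitude * direction`` starting at its
    onset, following s(tau) = 10 tau^3 - 15 tau^4 + 6 tau^5.
    """
    t = np.arange(0.0, total_ms + 0.5, 1.0)
    x = np.zeros_like(t)
    y = np.zeros_like(t)
    dx, dy = direction
    for amp, onset in zip(amplitudes, onsets):
        dur = duration_rule(amp)
        tau = np.clip((t - onset) / dur, 0.0, 1.0)
        s = 10 * tau**3 - 15 * tau**4 + 6 * tau**5
        x = x + amp * dx * s
        y = y + amp * dy * s
    if noise_sd:
        rng = np.random.default_rng(seed)
        x = x + rng.normal(0, noise_sd, len(t))
        y = y + rng.normal(0, noise_sd, len(t))
    return p.EyeTrace(t=t, x=x, y=y, sampling_rate=1000.0)


@pytest.fixture(scope="session")
def real_bundle():
    """Small real-saccade session with traces, shared across tests."""
    cfg = p.SessionConfig(n_trials=120, n_neurons=4, seed=11)
    return p.generate_session(cfg)


@pytest.fixture(scope="session")
def sim_bundle():
    cfg = p.SessionConfig(n_trials=96, n_neurons=2, seed=12,
                          mode="simulated_saccade")
    return p.generate_session(cfg)
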