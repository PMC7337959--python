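import numpy as np
import pytest

from rloopkin.synth import SynthConfig


@pytest.fixture
def synth_config():
    """Default-parameter generator config with a fixed seed."""
    return SynthConfig(seed=12345)


@pytest.fixture
def rng():
    return np.random.default_rng(987654321)


def rk4_integrate(rhs, y0, times, dt=0.005):
    """Fine-step explicit Runge-Kutta integrator, the independent oracle
    for the closed-form/adaptive kinetic solutions."""
    times = np.asarray(times, dtype=float)
    y = np.array(y0, dtype=float)
    t = 0.0
    out = np.empty((times.size, y.size))
    for i, t_target in enumerate(times):
        while t < t_target - 1e-12:
            h = min(dt, t_target - t)
            k1 = rhs(t, y)
            k2 = rhs(t + h / 2, y + h / 2 * k1)
            k3 = rhs(t + h / 2, y + h / 2 * k2)
            k4 = rhs(t + h, y + h * k3)
            y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            t += h
        out[i] = y
    return out
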