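import numpy as np
import pytest

from corneapuff import (
    EyePhantomSpec,
    KVParams,
    PulseSpec,
    generate_force_pulse,
    simulate_eye_response,
)


@pytest.fixture(scope="session")
def default_pulse_spec():
    """Study-condition pulse: 120.8 mN raised cosine, 1600 samples at 50 kHz."""
    return PulseSpec()


@pytest.fixture(scope="session")
def padded_pulse():
    """Pulse with a 4 ms quiet margin, as used by the imaging pipeline."""
    return generate_force_pulse(PulseSpec(rise_time=0.012, onset_delay=0.004))


@pytest.fixture(scope="session")
def default_phantom():
    return EyePhantomSpec(kv=KVParams(k=120.0, c=0.15), seed=42)


@pytest.fixture(scope="session")
def phantom_response(padded_pulse, default_phantom):
    """(force, displacement) pair for the default phantom."""
    x = simulate_eye_response(padded_pulse, default_phantom)
    return padded_pulse, x


def make_triangle_loop(n_load=800, n_unload=800, mad_um=1000.0, peak_force=0.12):
    """Closed loop with linear loading and quadratic unloading in x.

    Loading F = peak * (x / mad); unloading F = peak * (x / mad)^2.
    Returns time-ordered (x_um, F_N) arrays.
    """
    x_up = np.linspace(0.0, mad_um, n_load)
    x_down = np.linspace(mad_um, 0.0, n_unload)[1:]
    f_up = peak_force * x_up / mad_um
    f_down = peak_force * (x_down / mad_um) ** 2
    return np.concatenate([x_up, x_down]), np.concatenate([f_up, f_down])
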