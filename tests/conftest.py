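import numpy as np
import pytest

from dmdcpp.dmd_core import DmdParams, ModeSet


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_mode_set(freqs_hz, modes=None, n_channels=4, fs=500.0):
    """Hand-built ModeSet with given signed frequencies (Hz).

    Positive entries get Im(omega) > 0, negative ones the conjugate.
    """
    freqs = np.asarray(freqs_hz, dtype=float)
    j = freqs.size
    if modes is None:
        gen = np.random.default_rng(0)
        modes = gen.standard_normal((n_channels, j)) + 1j * gen.standard_normal((n_channels, j))
    omegas = 1j * 2 * np.pi * freqs
    lam = np.exp(omegas / fs)
    return ModeSet(
        modes=np.asarray(modes, dtype=complex),
        eigvals=lam,
        omegas=omegas,
        freqs_hz=np.abs(freqs),
        amplitudes=np.ones(j, dtype=complex),
    )


@pytest.fixture
def two_bundle_vectors(rng):
    """Two tight bundles of 12 vectors each; between-bundle cosine ~ 0."""
    p = 30
    base1 = np.zeros(p); base1[:15] = 1.0
    base2 = np.zeros(p); base2[15:] = 1.0
    cols = []
    for base in (base1, base2):
        for _ in range(12):
            cols.append(base + 1e-3 * rng.standard_normal(p))
    return np.column_stack(cols)


@pytest.fixture
def default_dmd_params():
    return DmdParams(stack_size=48, rank=100, fs=500.0)
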