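"""Delay-embedded (stacked) DMD per segment, with mode rectification.

The per-segment decomposition follows the exact-DMD convention on a
delay-embedded snapshot pair: each snapshot column stacks ``S`` consecutive
multichannel samples (channel-major), the reduced operator is obtained from
a rank-truncated SVD, and channel-space modes are the first ``M`` rows of
the augmented modes.  Rectification removes the complex across-channel mean
from every mode column, suppressing sensor-uniform content while leaving
inter-sensor phase differences intact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla

#: Relative singular-value cutoff guarding the pseudo-inverse.
_RANK_RTOL = 1e-10


class InsufficientSamplesError(ValueError):
    """Segment too short for the requested delay embedding."""


@dataclass
class DmdParams:
    """Stacking and truncation configuration."""

    stack_size: int = 48
    rank: int = 100
    fs: float = 500.0

    def __post_init__(self) -> None:
        if self.stack_size < 1:
            raise ValueError("stack_size must be >= 1")
        if self.rank < 1:
            raise ValueError("rank must be >= 1")
        if self.fs <= 0:
            raise ValueError("fs must be positive")


@dataclass
class ModeSet:
    """Channel-space modes with eigenvalues, frequencies and amplitudes.

    ``modes`` holds one complex column per retained mode (M x J).  The
    augmented modes (MS x J) are kept for reconstruction diagnostics.
    """

    modes: np.ndarray
    eigvals: np.ndarray
    omegas: np.ndarray
    freqs_hz: np.ndarray
    amplitudes: np.ndarray
    aug_modes: np.ndarray = field(default=None, repr=False)

    @property
    def n_modes(self) -> int:
        return self.modes.shape[1]

    def select(self, mask: np.ndarray) -> "ModeSet":
        """Subset of the modes along the mode axis."""
        return ModeSet(
            modes=self.modes[:, mask],
            eigvals=self.eigvals[mask],
            omegas=self.omegas[mask],
            freqs_hz=self.freqs_hz[mask],
            amplitudes=self.amplitudes[mask],
            aug_modes=None if self.aug_modes is None else self.aug_modes[:, mask],
        )


def empty_mode_set(n_channels: int) -> ModeSet:
    return ModeSet(
        modes=np.zeros((n_channels, 0), dtype=complex),
        eigvals=np.zeros(0, dtype=complex),
        omegas=np.zeros(0, dtype=complex),
        freqs_hz=np.zeros(0),
        amplitudes=np.zeros(0, dtype=complex),
        aug_modes=np.zeros((0, 0), dtype=complex),
    )


def delay_embed(segment: np.ndarray, stack_size: int):
    """Build the shifted snapshot pair (X, X') from one segment.

    Column ``t`` of X stacks samples ``t .. t+S-1`` over all channels,
    channel index fastest; X' is the one-sample forward shift.  Both are
    ``M*S x (N - S)``.
    """
    segment = np.asarray(segment, dtype=float)
    m, n = segment.shape
    s = int(stack_size)
    if n <= s:
        raise InsufficientSamplesError(
            f"segment of {n} samples cannot be embedded with stack size {s}"
        )
    cols = n - s
    # sliding windows: block j of X holds samples j .. j+cols-1
    x = np.empty((m * s, cols))
    xp = np.empty((m * s, cols))
    for j in range(s):
        x[j * m:(j + 1) * m] = segment[:, j:j + cols]
        xp[j * m:(j + 1) * m] = segment[:, j + 1:j + 1 + cols]
    return x, xp


def fit_dmd(x: np.ndarray, xp: np.ndarray, params: DmdParams) -> ModeSet:
    """Exact DMD on a snapshot pair with rank truncation.

    Eigenvalues with |lambda| = 0 are discarded (no continuous-time
    counterpart on the principal log branch).  A zero snapshot matrix
    yields an empty :class:`ModeSet`.
    """
    x = np.asarray(x, dtype=float)
    xp = np.asarray(xp, dtype=float)
    if x.shape != xp.shape:
        raise ValueError("X and X' must share dimensions")
    m_channels = _n_channels_of(x, params)

    if not np.any(x):
        return empty_mode_set(m_channels)

    u, sv, vh = sla.svd(x, full_matrices=False, lapack_driver="gesdd")
    r = int(np.sum(sv >= _RANK_RTOL * sv[0]))
    r = min(r, params.rank)
    if r == 0:  # pragma: no cover - excluded by the zero-matrix guard
        return empty_mode_set(m_channels)
    u, sv, vh = u[:, :r], sv[:r], vh[:r]

    # reduced operator and its eigenpairs
    xp_v_sinv = (xp @ vh.conj().T) / sv  # MS x r
    atilde = u.conj().T @ xp_v_sinv
    lam, w = np.linalg.eig(atilde)

    phi_aug = xp_v_sinv @ w  # exact-DMD augmented modes
    keep = np.abs(lam) > 0
    lam, phi_aug = lam[keep], phi_aug[:, keep]

    omega = params.fs * np.log(lam)
    freqs = np.abs(omega.imag) / (2.0 * np.pi)
    amps, *_ = np.linalg.lstsq(phi_aug, x[:, 0].astype(complex), rcond=None)

    return ModeSet(
        modes=phi_aug[:m_channels].copy(),
        eigvals=lam,
        omegas=omega,
        freqs_hz=freqs,
        amplitudes=amps,
        aug_modes=phi_aug,
    )


def _n_channels_of(x: np.ndarray, params: DmdParams) -> int:
    ms = x.shape[0]
    if ms % params.stack_size:
        raise ValueError(
            f"row count {ms} not divisible by stack size {params.stack_size}"
        )
    return ms // params.stack_size


def rectify_modes(ms: ModeSet) -> ModeSet:
    """Subtract the complex across-channel mean from every mode column.

    Idempotent linear map; a sensor-uniform mode maps to zero, and the
    pairwise inter-channel phase differences of the residual are those of
    the input minus any channel-constant.
    """
    modes = ms.modes - ms.modes.mean(axis=0, keepdims=True)
    return ModeSet(
        modes=modes,
        eigvals=ms.eigvals,
        omegas=ms.omegas,
        freqs_hz=ms.freqs_hz,
        amplitudes=ms.amplitudes,
        aug_modes=ms.aug_modes,
    )


def segment_mode_set(segment: np.ndarray, params: DmdParams) -> ModeSet:
    """Convenience: delay-embed, fit, and rectify one segment."""
    if not np.any(segment):
        return empty_mode_set(segment.shape[0])
    x, xp = delay_embed(segment, params.stack_size)
    return rectify_modes(fit_dmd(x, xp, params))


def reconstruct(ms: ModeSet, n_snapshots: int) -> np.ndarray:
    """Rebuild augmented snapshots sum_j c_j phi_j lambda_j^t (diagnostic)."""
    if ms.aug_modes is None:
        raise ValueError("augmented modes were not retained")
    t = np.arange(n_snapshots)
    dynamics = ms.amplitudes[:, None] * ms.eigvals[:, None] ** t[None, :]
    return ms.aug_modes @ dynamics
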