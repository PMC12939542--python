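"""Stage 1: fixed-size epoch descriptors from per-segment mode sets.

Per segment, retained in-band modes are sorted by frequency and their
channel-wise magnitudes interpolated onto a common ``P``-point mode axis.
Per epoch, segment images are averaged elementwise and the mean is min-max
rescaled to [0, 1]; the descriptor vector is the column-stacked image.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .dmd_core import ModeSet


@dataclass
class EpochDescriptor:
    """Unit-scaled M x P epoch image and its vectorization."""

    image: np.ndarray
    subject_id: str = ""
    label: str = ""
    epoch_index: int = 0

    @property
    def vector(self) -> np.ndarray:
        # column-stacked: channel index fastest
        return self.image.flatten(order="F")


def unvectorize(vector: np.ndarray, n_channels: int) -> np.ndarray:
    """Inverse of the column-stacking used by :attr:`EpochDescriptor.vector`."""
    return np.asarray(vector).reshape((n_channels, -1), order="F")


def band_filter_modes(ms: ModeSet, lo: float = 4.0, hi: float = 40.0) -> ModeSet:
    """Keep one conjugate-pair representative per in-band eigenfrequency.

    Membership is closed on both ends.  Of each conjugate pair the
    positive-imaginary-frequency member is kept; for an in-band frequency
    the imaginary part is nonzero, so the pair collapses to one mode.
    """
    mask = (ms.freqs_hz >= lo) & (ms.freqs_hz <= hi) & (ms.omegas.imag > 0)
    return ms.select(mask)


def mode_image(ms: ModeSet, width: int = 50) -> np.ndarray:
    """Interpolate sorted channel-wise mode magnitudes to a fixed width.

    Modes are ordered by ascending frequency (ties: descending magnitude
    l2 norm).  Each channel row of |phi| (M x J) is linearly interpolated
    from the normalized index grid ``j/(J-1)`` to ``width`` points.  With
    zero retained modes an all-zero image is returned with a warning.
    """
    m = ms.modes.shape[0]
    j = ms.n_modes
    if j == 0:
        warnings.warn("no retained modes; emitting all-zero mode image")
        return np.zeros((m, width))
    mags = np.abs(ms.modes)
    order = np.lexsort((-np.linalg.norm(mags, axis=0), ms.freqs_hz))
    mags = mags[:, order]
    if j == 1:
        return np.tile(mags, (1, width))
    src = np.arange(j) / (j - 1)
    dst = np.arange(width) / (width - 1)
    out = np.empty((m, width))
    for ch in range(m):
        out[ch] = np.interp(dst, src, mags[ch])
    return out


def epoch_descriptor(images: list, subject_id: str = "", label: str = "",
                     epoch_index: int = 0) -> EpochDescriptor:
    """Elementwise mean over segment images, min-max rescaled to [0, 1].

    The rescale is global over the M x P mean matrix.  A constant mean
    matrix (including all-zero) degenerates to the all-zero descriptor.
    """
    if not images:
        raise ValueError("need at least one segment image")
    stack = np.stack([np.asarray(im, dtype=float) for im in images])
    mean = stack.mean(axis=0)
    lo, hi = mean.min(), mean.max()
    if hi - lo <= 0:
        warnings.warn("degenerate (constant) epoch mean; emitting all-zero descriptor")
        image = np.zeros_like(mean)
    else:
        image = (mean - lo) / (hi - lo)
    return EpochDescriptor(image=image, subject_id=subject_id, label=label,
                           epoch_index=epoch_index)


def descriptor_table(descriptors: list) -> "pd.DataFrame":
    """One row per epoch: subject, label, epoch index, then feature columns."""
    import pandas as pd

    rows = []
    for d in descriptors:
        row = {"subject_id": d.subject_id, "label": d.label,
               "epoch_index": d.epoch_index}
        row.update({f"f{i}": v for i, v in enumerate(d.vector)})
        rows.append(row)
    return pd.DataFrame(rows)
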