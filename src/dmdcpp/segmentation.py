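"""Recording screening, 2 s segmentation, and evenly spaced epoch placement.

A recording's stimulus interval is cut into non-overlapping fixed-length
segments anchored at the stimulus onset; a trailing partial segment is
discarded.  An *epoch* is a run of ``segs_per_epoch`` consecutive segments.
Ten epochs are placed at evenly spaced (possibly overlapping) start indices
spanning the usable range, which requires at least
``n_epochs + segs_per_epoch - 1`` usable segments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

#: Standard 10-20 montage order used for study-conformant recordings.
MONTAGE_19 = [
    "Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2",
    "F7", "F8", "T3", "T4", "T5", "T6", "Fz", "Cz", "Pz",
]

VALID_LABELS = ("AD", "FTD", "CN")


class InvalidIntervalError(ValueError):
    """Stimulus interval with non-positive duration."""


class EligibilityError(ValueError):
    """Recording does not contain enough usable segments."""


class TruncationError(ValueError):
    """Signal ends before the stimulus interval does."""


@dataclass
class Recording:
    """One subject's multichannel signal plus stimulus annotations.

    Parameters
    ----------
    subject_id : str
        Unique subject identifier.
    label : str
        Diagnostic label, one of ``AD``, ``FTD``, ``CN``.
    signal : ndarray, shape (M, n_samples)
        Channels-by-samples signal in microvolts.
    fs : float
        Sampling rate in Hz.
    stim_onset, stim_offset : float
        Stimulus interval boundaries in seconds.
    channel_names : list of str
        Channel names, one per signal row.
    """

    subject_id: str
    label: str
    signal: np.ndarray
    fs: float
    stim_onset: float
    stim_offset: float
    channel_names: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2 or self.signal.shape[0] < 2:
            raise ValueError("signal must be an (M >= 2) x samples matrix")
        if self.label not in VALID_LABELS:
            raise ValueError(f"label must be one of {VALID_LABELS}, got {self.label!r}")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.stim_offset <= self.stim_onset:
            raise InvalidIntervalError(
                f"stim_offset ({self.stim_offset}) must exceed stim_onset ({self.stim_onset})"
            )
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.signal.shape[0])]
        if len(self.channel_names) != self.signal.shape[0]:
            raise ValueError("channel_names length must match number of signal rows")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    def reordered(self, channel_order: list) -> "Recording":
        """Return a copy with rows permuted into ``channel_order`` by name."""
        missing = [c for c in channel_order if c not in self.channel_names]
        if missing:
            raise ValueError(f"channels not present in recording: {missing}")
        idx = [self.channel_names.index(c) for c in channel_order]
        return Recording(
            subject_id=self.subject_id,
            label=self.label,
            signal=self.signal[idx],
            fs=self.fs,
            stim_onset=self.stim_onset,
            stim_offset=self.stim_offset,
            channel_names=list(channel_order),
        )


@dataclass
class EpochPlan:
    """Placement of ``n_epochs`` epochs over the usable segment grid."""

    n_segments_usable: int
    segment_len_samples: int
    n_epochs: int
    segs_per_epoch: int
    start_indices: list  # 1-based segment indices

    def __post_init__(self) -> None:
        starts = list(self.start_indices)
        if sorted(set(starts)) != starts:
            raise ValueError("start_indices must be strictly increasing and distinct")
        hi = self.n_segments_usable - self.segs_per_epoch + 1
        if starts and (starts[0] < 1 or starts[-1] > hi):
            raise ValueError(f"start indices must lie in [1, {hi}]")


def _round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def count_usable_segments(onset: float, offset: float, seg_len: float = 2.0) -> int:
    """Number of whole non-overlapping segments in [onset, offset).

    A tiny relative tolerance absorbs binary-float representation of
    decimal second values (e.g. an interval of nominally 38.00 s).
    """
    if seg_len <= 0:
        raise InvalidIntervalError("seg_len must be positive")
    if offset <= onset:
        raise InvalidIntervalError(
            f"non-positive stimulus duration: onset={onset}, offset={offset}"
        )
    return int(math.floor((offset - onset) / seg_len + 1e-9))


def epoch_start_indices(n_seg: int, n_epochs: int = 10, segs_per_epoch: int = 10) -> list:
    """Evenly spaced 1-based start indices for ``n_epochs`` epochs.

    Start i follows ``1 + (i - 1) * (n_seg - segs_per_epoch) / (n_epochs - 1)``
    rounded half away from zero.  Raises :class:`EligibilityError` when the
    grid cannot host ``n_epochs`` distinct starts.
    """
    minimum = n_epochs + segs_per_epoch - 1
    if n_seg < minimum:
        raise EligibilityError(
            f"need at least {minimum} usable segments for {n_epochs} epochs "
            f"of {segs_per_epoch} segments, got {n_seg}"
        )
    span = n_seg - segs_per_epoch
    starts = [
        _round_half_away(1 + (i - 1) * span / (n_epochs - 1))
        for i in range(1, n_epochs + 1)
    ]
    if sorted(set(starts)) != starts:  # pragma: no cover - guarded by eligibility
        raise AssertionError("rounded start indices are not strictly increasing")
    return starts


def make_epoch_plan(
    rec: Recording,
    seg_len: float = 2.0,
    n_epochs: int = 10,
    segs_per_epoch: int = 10,
) -> EpochPlan:
    """Screen ``rec`` and build its epoch placement."""
    n_seg = count_usable_segments(rec.stim_onset, rec.stim_offset, seg_len)
    starts = epoch_start_indices(n_seg, n_epochs, segs_per_epoch)
    return EpochPlan(
        n_segments_usable=n_seg,
        segment_len_samples=int(round(seg_len * rec.fs)),
        n_epochs=n_epochs,
        segs_per_epoch=segs_per_epoch,
        start_indices=starts,
    )


def segment_matrix(rec: Recording, plan: EpochPlan, seg_index: int) -> np.ndarray:
    """Samples of 1-based segment ``seg_index`` on the onset-anchored grid."""
    if not 1 <= seg_index <= plan.n_segments_usable:
        raise IndexError(f"segment index {seg_index} outside [1, {plan.n_segments_usable}]")
    n = plan.segment_len_samples
    first = int(round(rec.stim_onset * rec.fs)) + (seg_index - 1) * n
    last = first + n
    if last > rec.signal.shape[1]:
        raise TruncationError(
            f"signal of {rec.signal.shape[1]} samples too short for segment "
            f"{seg_index} ending at sample {last}"
        )
    return rec.signal[:, first:last]


def extract_epochs(rec: Recording, plan: EpochPlan) -> list:
    """All epochs as lists of segment matrices (M x segment_len_samples).

    Segments shared between epochs are the *same* array object, so
    downstream per-segment computation can be cached by segment index.
    """
    cache = {}
    epochs = []
    for s in plan.start_indices:
        epoch = []
        for k in range(plan.segs_per_epoch):
            idx = s + k
            if idx not in cache:
                cache[idx] = segment_matrix(rec, plan, idx)
            epoch.append(cache[idx])
        epochs.append(epoch)
    return epochs


def load_study_intervals() -> pd.DataFrame:
    """Bundled stimulus onset/offset annotations for the 88-subject cohort."""
    with resources.files("dmdcpp").joinpath("data/stim_intervals.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def screen_study_cohort(seg_len: float = 2.0, min_segments: int = 19) -> pd.DataFrame:
    """Apply the usable-duration screen to the bundled cohort annotations.

    Returns the annotation table with ``n_segments`` and ``eligible`` columns.
    """
    df = load_study_intervals().copy()
    df["n_segments"] = [
        count_usable_segments(on, off, seg_len)
        for on, off in zip(df["onset"], df["offset"])
    ]
    df["eligible"] = df["n_segments"] >= min_segments
    return df
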