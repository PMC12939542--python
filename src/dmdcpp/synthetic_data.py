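"""Synthetic photic-stimulation EEG cohorts.

Each subject's signal is the sum of (i) a stimulus-entrained sinusoid whose
frequency cycles through the configured stimulus frequencies in blocks,
with a fixed posterior-weighted channel topography, (ii) a background
alpha-band oscillation, and (iii) 1/f (pink) noise.  Diagnostic class
affects only two generative parameters: a gain on components below 12 Hz
and a per-segment probability of resetting the low-frequency phase
(fragmentation).  Everything else is identical across classes.

These distributions are artifact fixtures for testing the pipeline; they
make no claim of biophysical fidelity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .segmentation import MONTAGE_19, Recording

#: Upper edge of the band whose amplitude/fragmentation is class-dependent.
LOW_FREQ_EDGE_HZ = 12.0

# Posterior-weighted entrainment topography over the 19-channel montage;
# occipital/parietal sites respond most strongly to photic stimulation.
_TOPO_WEIGHTS = {
    "O1": 1.0, "O2": 1.0, "P3": 0.8, "P4": 0.8, "Pz": 0.85,
    "T5": 0.6, "T6": 0.6, "C3": 0.45, "C4": 0.45, "Cz": 0.5,
    "F3": 0.3, "F4": 0.3, "Fz": 0.3, "F7": 0.25, "F8": 0.25,
    "T3": 0.35, "T4": 0.35, "Fp1": 0.2, "Fp2": 0.2,
}

_ALPHA_WEIGHTS = {
    "O1": 1.0, "O2": 1.0, "P3": 0.9, "P4": 0.9, "Pz": 0.95,
    "T5": 0.7, "T6": 0.7, "C3": 0.5, "C4": 0.5, "Cz": 0.55,
    "F3": 0.35, "F4": 0.35, "Fz": 0.35, "F7": 0.3, "F8": 0.3,
    "T3": 0.4, "T4": 0.4, "Fp1": 0.25, "Fp2": 0.25,
}


@dataclass
class SynthConfig:
    """Cohort-level generation settings; deterministic given ``seed``."""

    n_per_class: dict = field(default_factory=lambda: {"AD": 8, "FTD": 0, "CN": 8})
    n_channels: int = 19
    fs: float = 500.0
    duration: float = 90.0
    stim_freqs: tuple = (5.0, 10.0, 15.0, 20.0, 30.0)
    block_len: float = 15.0
    seed: int = 42
    low_freq_gain: dict = field(
        default_factory=lambda: {"CN": 1.0, "FTD": 0.6, "AD": 0.35})
    fragmentation_rate: dict = field(
        default_factory=lambda: {"CN": 0.05, "FTD": 0.45, "AD": 0.85})
    noise_sd: float = 0.3
    photic_amp: float = 2.0
    alpha_amp: float = 6.0
    alpha_freq: float = 10.0
    seg_len: float = 2.0
    topo_jitter: float = 0.04

    def __post_init__(self) -> None:
        if any(g < 0 for g in self.low_freq_gain.values()):
            raise ValueError("low_freq_gain values must be >= 0")
        if any(not 0 <= p <= 1 for p in self.fragmentation_rate.values()):
            raise ValueError("fragmentation_rate values must lie in [0, 1]")
        if self.n_channels != 19:
            raise ValueError("the synthetic montage is fixed at 19 channels")


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-sd 1/f-amplitude noise via spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]
    spec /= np.sqrt(f)
    out = np.fft.irfft(spec, n)
    return out / out.std()


def _fragmented_phase(rng, n_samples, n_seg_samples, frag_rate, omega_per_sample):
    """Phase track advancing at a fixed rate; with probability ``frag_rate``
    per segment the phase is reset at a random sample inside that segment,
    so the within-segment coherence of the oscillation is genuinely broken."""
    phase = np.empty(n_samples)
    current = rng.uniform(0, 2 * np.pi)
    for start in range(0, n_samples, n_seg_samples):
        stop = min(start + n_seg_samples, n_samples)
        reset_at = None
        if rng.uniform() < frag_rate and stop - start > 1:
            reset_at = start + int(rng.integers(1, stop - start))
        for cut_start, cut_stop in ((start, reset_at or stop),
                                    (reset_at, stop) if reset_at else (None, None)):
            if cut_start is None:
                continue
            if cut_start == reset_at:
                current = rng.uniform(0, 2 * np.pi)
            k = np.arange(cut_stop - cut_start)
            phase[cut_start:cut_stop] = current + omega_per_sample * k
            current = phase[cut_stop - 1] + omega_per_sample
    return phase


def generate_subject(label: str, cfg: SynthConfig, subject_seed,
                     subject_id: str = None) -> Recording:
    """One labeled synthetic recording; identical seeds give identical signals."""
    rng = np.random.default_rng(subject_seed)
    n = int(round(cfg.duration * cfg.fs))
    n_seg = int(round(cfg.seg_len * cfg.fs))
    gain = cfg.low_freq_gain[label]
    frag = cfg.fragmentation_rate[label]

    topo = np.array([_TOPO_WEIGHTS[c] for c in MONTAGE_19])
    topo = topo * (1 + cfg.topo_jitter * rng.standard_normal(19))
    alpha_topo = np.array([_ALPHA_WEIGHTS[c] for c in MONTAGE_19])
    alpha_topo = alpha_topo * (1 + cfg.topo_jitter * rng.standard_normal(19))

    signal = np.zeros((19, n))

    # photic entrainment: blocks cycling through the stimulus frequencies
    block_samples = int(round(cfg.block_len * cfg.fs))
    start = 0
    b = 0
    while start < n:
        stop = min(start + block_samples, n)
        freq = cfg.stim_freqs[b % len(cfg.stim_freqs)]
        omega = 2 * np.pi * freq / cfg.fs
        low = freq <= LOW_FREQ_EDGE_HZ
        amp = cfg.photic_amp * (gain if low else 1.0)
        phase = _fragmented_phase(rng, stop - start, n_seg,
                                  frag if low else 0.0, omega)
        # small per-channel phase lag preserves inter-sensor structure
        lags = 0.15 * np.arange(19)[:, None]
        signal[:, start:stop] += amp * topo[:, None] * np.sin(phase[None, :] + lags)
        start = stop
        b += 1

    # background alpha, class-gained and fragmented
    omega_a = 2 * np.pi * cfg.alpha_freq / cfg.fs
    phase_a = _fragmented_phase(rng, n, n_seg, frag, omega_a)
    lags_a = 0.1 * np.arange(19)[:, None]
    signal += cfg.alpha_amp * gain * alpha_topo[:, None] * np.sin(phase_a[None, :] + lags_a)

    for ch in range(19):
        signal[ch] += cfg.noise_sd * _pink_noise(rng, n)

    return Recording(
        subject_id=subject_id or f"{label}-synth",
        label=label,
        signal=signal,
        fs=cfg.fs,
        stim_onset=0.0,
        stim_offset=cfg.duration,
        channel_names=list(MONTAGE_19),
    )


def generate_cohort(cfg: SynthConfig):
    """(recordings, labels table); per-subject seeds spawned from cfg.seed.

    Subject seeds come from ``SeedSequence(cfg.seed).spawn`` in a fixed
    order (AD, FTD, CN; then subject counter), so cohort composition
    changes never perturb earlier subjects' signals.
    """
    total = sum(cfg.n_per_class.get(c, 0) for c in ("AD", "FTD", "CN"))
    children = np.random.SeedSequence(cfg.seed).spawn(total)
    recordings = []
    rows = []
    i = 0
    for label in ("AD", "FTD", "CN"):
        for k in range(cfg.n_per_class.get(label, 0)):
            sid = f"{label}{k + 1:02d}"
            recordings.append(generate_subject(label, cfg, children[i], subject_id=sid))
            rows.append({"subject_id": sid, "label": label})
            i += 1
    return recordings, pd.DataFrame(rows)
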