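"""PCA comparison features: train-fitted components retaining 95% variance."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class PcaProjection:
    """Train-fitted affine projection onto the leading principal subspace."""

    mean: np.ndarray
    components: np.ndarray  # (q, p) rows are unit principal axes
    explained_variance_ratio: np.ndarray  # all p fractions

    @property
    def q(self) -> int:
        return self.components.shape[0]


def fit_pca_95(z_train: np.ndarray, variance: float = 0.95) -> PcaProjection:
    """Fit PCA on the train rows and keep the minimal q with cumulative
    explained-variance fraction >= ``variance``.

    Component signs are fixed by forcing each axis's largest-magnitude
    loading positive.
    """
    z = np.asarray(z_train, dtype=float)
    if z.ndim != 2 or z.shape[0] < 2:
        raise ValueError("need at least 2 training vectors")
    mean = z.mean(axis=0)
    centered = z - mean
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    var = s ** 2
    total = var.sum()
    if total <= 0:
        raise ValueError("training data has zero variance (rank 0)")
    frac = var / total
    cum = np.cumsum(frac)
    q = int(np.searchsorted(cum, variance - 1e-12) + 1)
    comps = vt[:q]
    # deterministic sign: largest-|loading| entry positive per axis
    for i in range(q):
        j = np.argmax(np.abs(comps[i]))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
    return PcaProjection(mean=mean, components=comps,
                         explained_variance_ratio=frac)


def apply_pca(proj: PcaProjection, z_any: np.ndarray) -> np.ndarray:
    """Project rows of ``z_any`` with the train mean and components."""
    z = np.asarray(z_any, dtype=float)
    if z.shape[-1] != proj.mean.shape[0]:
        raise ValueError(
            f"dimension mismatch: data has {z.shape[-1]} features, "
            f"projection expects {proj.mean.shape[0]}"
        )
    return (z - proj.mean) @ proj.components.T
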