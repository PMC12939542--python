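"""Cosine projection onto class dictionaries and train-only standardization."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dictionary import DegenerateVectorError, Dictionary

#: Columns with train standard deviation below this are mapped to zero.
SIGMA_FLOOR = 1e-12


class EmptyDictionaryError(ValueError):
    pass


@dataclass
class Standardizer:
    """Per-column affine normalization fitted on the training split only."""

    mu: np.ndarray
    sigma: np.ndarray
    fitted_on: str = "train"

    def transform(self, h: np.ndarray) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        out = (h - self.mu) / np.maximum(self.sigma, SIGMA_FLOOR)
        out[:, self.sigma < SIGMA_FLOOR] = 0.0
        return out


def project(z: np.ndarray, dictionary: Dictionary) -> np.ndarray:
    """Cosine similarity of ``z`` to every atom; values in [-1, 1]."""
    z = np.asarray(z, dtype=float)
    zn = np.linalg.norm(z)
    if zn == 0:
        raise DegenerateVectorError("cannot project a zero vector")
    if dictionary.n_atoms == 0:
        raise EmptyDictionaryError(
            "dictionary has no atoms; relax the clustering thresholds "
            "(tau_sup / n_min / h_stop)"
        )
    atoms = dictionary.atoms
    anorm = np.linalg.norm(atoms, axis=0)
    return (atoms.T @ z) / (anorm * zn)


def build_feature_table(
    z_split: np.ndarray,
    dict_c1: Dictionary,
    dict_c2: Dictionary,
    meta: pd.DataFrame = None,
) -> pd.DataFrame:
    """Concatenated class blocks [F_c1 | F_c2], one row per epoch.

    ``meta`` (same row order) may carry subject/label columns that are
    prefixed onto the returned frame.
    """
    for d in (dict_c1, dict_c2):
        if d.n_atoms == 0:
            raise EmptyDictionaryError(
                f"empty dictionary for class {d.class_label!r}; relax the "
                "clustering thresholds (tau_sup / n_min / h_stop)"
            )
    z = np.asarray(z_split, dtype=float)
    cols = {}
    for d in (dict_c1, dict_c2):
        block = np.column_stack([project(z[:, i], d) for i in range(z.shape[1])]).T
        for k in range(d.n_atoms):
            cols[f"{d.class_label}:{k}"] = block[:, k]
    table = pd.DataFrame(cols)
    if meta is not None:
        table = pd.concat([meta.reset_index(drop=True), table], axis=1)
    return table


def feature_matrix(table: pd.DataFrame) -> np.ndarray:
    """Numeric feature block of a table built by :func:`build_feature_table`."""
    cols = [c for c in table.columns if ":" in str(c)]
    return table[cols].to_numpy(dtype=float)


def standardize(h_train: np.ndarray, h_test: np.ndarray):
    """Column-standardize with train statistics only (sample sd, ddof=1).

    Returns ``(h_train_std, h_test_std, standardizer)``.  Constant train
    columns map to zero in both splits.
    """
    h_train = np.asarray(h_train, dtype=float)
    h_test = np.asarray(h_test, dtype=float)
    if h_train.shape[0] == 0:
        raise ValueError("train split must be non-empty")
    mu = h_train.mean(axis=0)
    sigma = h_train.std(axis=0, ddof=1) if h_train.shape[0] > 1 else np.zeros(h_train.shape[1])
    std = Standardizer(mu=mu, sigma=sigma)
    return std.transform(h_train), std.transform(h_test), std
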