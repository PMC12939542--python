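"""Stage 2: medoid dictionaries by divisive cosine clustering.

A complete-linkage dendrogram is built under cosine dissimilarity and cut
top-down: a node is split into its two dendrogram children only when it is
large enough, merges high enough, and both children clear the minimum
support.  Terminal nodes with enough members survive; each contributes its
medoid as a dictionary atom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform


class DegenerateVectorError(ValueError):
    """A zero-norm column has no cosine direction."""


@dataclass
class ClusterParams:
    """Split/retention thresholds for the divisive cut."""

    tau_sup: int = 11
    n_min: int = 10
    h_stop: float = 0.2
    linkage: str = "complete"

    def __post_init__(self) -> None:
        if not 0 < self.h_stop < 2:
            raise ValueError("h_stop must lie in (0, 2)")
        if self.linkage != "complete":
            raise ValueError("only complete linkage is supported")


@dataclass
class Dictionary:
    """Ordered medoid atoms for one class, with provenance."""

    atoms: np.ndarray  # (p, K) columns are medoid vectors
    group_sizes: list
    medoid_source_ids: list
    class_label: str = ""

    @property
    def n_atoms(self) -> int:
        return self.atoms.shape[1]


def cosine_dissimilarity(z: np.ndarray) -> np.ndarray:
    """Pairwise 1 - cosine similarity between the columns of ``z``."""
    z = np.asarray(z, dtype=float)
    norms = np.linalg.norm(z, axis=0)
    bad = np.flatnonzero(norms == 0)
    if bad.size:
        raise DegenerateVectorError(f"zero-norm column(s) at {bad.tolist()}")
    c = (z / norms).T @ (z / norms)
    d = 1.0 - np.clip(c, -1.0, 1.0)
    np.fill_diagonal(d, 0.0)
    return np.maximum(d, d.T)  # enforce exact symmetry


def divisive_cluster(z: np.ndarray, params: ClusterParams) -> list:
    """Surviving index groups from the top-down dendrogram cut.

    Returns a list of sorted integer index lists (columns of ``z``),
    in left-to-right dendrogram order.
    """
    z = np.asarray(z, dtype=float)
    n = z.shape[1]
    if n == 0:
        return []
    if n == 1:
        return [[0]] if params.n_min <= 1 else []

    d = cosine_dissimilarity(z)
    tree = to_tree(linkage(squareform(d, checks=False), method=params.linkage))

    groups = []

    def descend(node):
        size = node.get_count()
        split = (
            not node.is_leaf()
            and size > params.tau_sup
            and node.dist > params.h_stop
            and node.get_left().get_count() >= params.n_min
            and node.get_right().get_count() >= params.n_min
        )
        if split:
            descend(node.get_left())
            descend(node.get_right())
        elif size >= params.n_min:
            groups.append(sorted(node.pre_order(lambda leaf: leaf.id)))

    descend(tree)
    return groups


def medoid(z: np.ndarray, group: list) -> tuple:
    """(index, vector) of the member minimizing total in-group dissimilarity.

    Ties break toward the lowest index.
    """
    group = list(group)
    if not group:
        raise ValueError("group must be non-empty")
    sub = np.asarray(z, dtype=float)[:, group]
    totals = cosine_dissimilarity(sub).sum(axis=1)
    best = group[int(np.argmin(totals))]
    return best, np.asarray(z)[:, best].copy()


def _farthest_first_order(atoms: np.ndarray) -> list:
    """Reporting order: start at the atom with maximal mean dissimilarity,
    then repeatedly take the atom farthest from those already chosen."""
    k = atoms.shape[1]
    if k <= 1:
        return list(range(k))
    d = cosine_dissimilarity(atoms)
    order = [int(np.argmax(d.mean(axis=1)))]
    remaining = set(range(k)) - set(order)
    while remaining:
        nxt = max(remaining, key=lambda i: (min(d[i, j] for j in order), -i))
        order.append(nxt)
        remaining.remove(nxt)
    return order


def learn_dictionary(
    z_class: np.ndarray,
    params: ClusterParams = None,
    sample_ids: list = None,
    class_label: str = "",
) -> Dictionary:
    """Cluster class-restricted vectors and collect group medoids.

    Columns are l2-normalized before clustering and the atoms keep the
    normalized form; every atom is an exact copy of one (normalized)
    training column.  Atom order is a cosmetic recursive farthest-first
    ranking and does not affect downstream features.
    """
    params = params or ClusterParams()
    z = np.asarray(z_class, dtype=float)
    norms = np.linalg.norm(z, axis=0)
    bad = np.flatnonzero(norms == 0)
    if bad.size:
        raise DegenerateVectorError(f"zero-norm column(s) at {bad.tolist()}")
    z = z / norms
    if sample_ids is None:
        sample_ids = list(range(z.shape[1]))

    groups = divisive_cluster(z, params)
    if not groups:
        warnings.warn(
            f"no surviving groups for class {class_label!r}; empty dictionary"
        )
        return Dictionary(
            atoms=np.zeros((z.shape[0], 0)), group_sizes=[],
            medoid_source_ids=[], class_label=class_label,
        )

    med_idx = [medoid(z, g)[0] for g in groups]
    atoms = z[:, med_idx]
    order = _farthest_first_order(atoms)
    return Dictionary(
        atoms=atoms[:, order],
        group_sizes=[len(groups[i]) for i in order],
        medoid_source_ids=[sample_ids[med_idx[i]] for i in order],
        class_label=class_label,
    )
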