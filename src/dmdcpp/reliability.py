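"""Margin-based subject-level reliability statistics.

Per-subject margin descriptors (median |m|, IQR, sign consistency) are
grouped by classification outcome; group gaps are tested with median-gap
permutation tests and summarized with Cliff's delta effect sizes.
Percentiles use linear interpolation between order statistics (type 7).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .loso_pipeline import majority_vote

OUTCOMES = ("TP", "FP", "TN", "FN")


@dataclass
class MarginRecord:
    subject_id: str
    outcome: str
    margins: np.ndarray
    med_abs: float = field(init=False)
    iqr: float = field(init=False)
    sign_cons: float = field(init=False)

    def __post_init__(self) -> None:
        self.margins = np.asarray(self.margins, dtype=float)
        self.med_abs, self.iqr, self.sign_cons = subject_descriptors(self.margins)


@dataclass
class GroupComparison:
    descriptor: str
    groups: str  # "TP-FP" or "TN-FN"
    delta_med: float
    p_perm: float
    cliffs_delta: float
    ci: tuple
    n1: int
    n2: int


def subject_descriptors(margins: np.ndarray):
    """(median |m|, IQR of m, |P(m > 0) - 0.5|) for one subject's margins."""
    m = np.asarray(margins, dtype=float)
    if m.size == 0:
        raise ValueError("need at least one margin")
    med_abs = float(np.median(np.abs(m)))
    q25, q75 = np.percentile(m, [25, 75])  # linear interpolation (type 7)
    sign_cons = float(np.abs(np.mean(m > 0) - 0.5))
    return med_abs, float(q75 - q25), sign_cons


def outcome_grouping(fold_results: list, positive_class: str) -> dict:
    """Outcome -> list of MarginRecord, decided subjects only.

    Rejected subjects (majority-vote tie) appear in no group.
    """
    groups = {o: [] for o in OUTCOMES}
    for fr in fold_results:
        decision = majority_vote(fr.pred_labels)
        if decision is None:
            continue
        if decision == positive_class:
            outcome = "TP" if fr.true_label == positive_class else "FP"
        else:
            outcome = "FN" if fr.true_label == positive_class else "TN"
        groups[outcome].append(
            MarginRecord(subject_id=fr.held_out_subject, outcome=outcome,
                         margins=fr.margins))
    return groups


def permutation_median_gap(a, b, n_perm: int = 20000, seed: int = 0):
    """Two-sided permutation test on the difference of group medians.

    Subjects are randomly reassigned between the groups preserving the
    group sizes; the add-one rule ``p = (1 + #{|d*| >= |d_obs|}) /
    (1 + n_perm)`` avoids zero p-values.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    delta_obs = float(np.median(a) - np.median(b))
    pooled = np.concatenate([a, b])
    rng = np.random.default_rng(seed)
    hits = 0
    tol = 1e-12 * max(1.0, abs(delta_obs))
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        d = np.median(perm[:a.size]) - np.median(perm[a.size:])
        if abs(d) >= abs(delta_obs) - tol:
            hits += 1
    return delta_obs, (1 + hits) / (1 + n_perm)


def cliffs_delta(a, b, n_boot: int = 2000, conf: float = 0.95, seed: int = 0):
    """Cliff's delta with a percentile-bootstrap CI.

    delta = (#{a_i > b_j} - #{a_i < b_j}) / (n1 * n2); ties contribute 0.
    The CI resamples within each group independently.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")

    def _delta(x, y):
        diff = x[:, None] - y[None, :]
        return float((np.sign(diff)).sum() / (x.size * y.size))

    delta = _delta(a, b)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        boots[i] = _delta(rng.choice(a, a.size, replace=True),
                          rng.choice(b, b.size, replace=True))
    alpha = (1 - conf) / 2
    lo, hi = np.percentile(boots, [100 * alpha, 100 * (1 - alpha)])
    return delta, (float(lo), float(hi))


def compare_groups(
    groups: dict,
    n_perm: int = 20000,
    seed: int = 0,
) -> list:
    """All descriptor x (TP-FP, TN-FN) comparisons with non-empty groups."""
    comparisons = []
    descriptors = [("med_abs", lambda r: r.med_abs),
                   ("iqr", lambda r: r.iqr),
                   ("sign_cons", lambda r: r.sign_cons)]
    for name, getter in descriptors:
        for g1, g2 in (("TP", "FP"), ("TN", "FN")):
            a = np.array([getter(r) for r in groups[g1]])
            b = np.array([getter(r) for r in groups[g2]])
            if a.size == 0 or b.size == 0:
                continue
            delta_med, p = permutation_median_gap(a, b, n_perm=n_perm, seed=seed)
            delta, ci = cliffs_delta(a, b, seed=seed)
            comparisons.append(GroupComparison(
                descriptor=name, groups=f"{g1}-{g2}", delta_med=delta_med,
                p_perm=p, cliffs_delta=delta, ci=ci, n1=a.size, n2=b.size))
    return comparisons
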