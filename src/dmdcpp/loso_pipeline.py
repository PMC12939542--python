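"""Leave-one-subject-out evaluation: folds, linear max-margin classifier,
majority voting with rejection, pooled confusion metrics and Wilson CIs."""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm
from sklearn.svm import SVC

from .dictionary import ClusterParams, learn_dictionary
from .pca_baseline import apply_pca, fit_pca_95
from .projection_features import build_feature_table, feature_matrix, standardize


@dataclass(frozen=True)
class TaskSpec:
    """A binary discrimination task with its designated positive class."""

    name: str
    c1: str
    c2: str
    positive_class: str

    @property
    def class_set(self):
        return (self.c1, self.c2)

    @property
    def negative_class(self):
        return self.c2 if self.positive_class == self.c1 else self.c1


TASKS = {
    "AD_vs_CN": TaskSpec("AD_vs_CN", "AD", "CN", "AD"),
    "FTD_vs_CN": TaskSpec("FTD_vs_CN", "FTD", "CN", "FTD"),
    "AD_vs_FTD": TaskSpec("AD_vs_FTD", "AD", "FTD", "AD"),
}


@dataclass
class FoldResult:
    held_out_subject: str
    true_label: str
    pred_labels: list
    margins: np.ndarray  # signed geometric margins, positive toward positive class


@dataclass
class BinaryConfusion:
    """Counts with the task's positive class as 'positive'."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "BinaryConfusion") -> "BinaryConfusion":
        return BinaryConfusion(self.tp + other.tp, self.fp + other.fp,
                               self.tn + other.tn, self.fn + other.fn)


def _safe_div(num: float, den: float) -> float:
    return num / den if den else 0.0


def accuracy(conf: BinaryConfusion) -> float:
    return _safe_div(conf.tp + conf.tn, conf.total)


def class_metrics(conf: BinaryConfusion, positive: bool = True) -> dict:
    """Precision/recall/F1 treating the positive (or negative) class as positive."""
    if positive:
        tp, fp, fn = conf.tp, conf.fp, conf.fn
    else:
        tp, fp, fn = conf.tn, conf.fn, conf.fp
    precision = _safe_div(tp, tp + fp)
    recall = _safe_div(tp, tp + fn)
    f1 = _safe_div(2 * precision * recall, precision + recall)
    return {"precision": precision, "recall": recall, "f1": f1}


def macro_metrics(conf: BinaryConfusion) -> dict:
    pos = class_metrics(conf, positive=True)
    neg = class_metrics(conf, positive=False)
    return {k: 0.5 * (pos[k] + neg[k]) for k in pos}


def wilson_ci(k: int, n: int, conf: float = 0.95):
    """Wilson score interval for a binomial proportion."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    z = norm.ppf(0.5 + conf / 2.0)
    p = k / n
    denom = 1.0 + z * z / n
    center = (p + z * z / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    return center - half, center + half


def loso_folds(subject_ids: list) -> list:
    """One (train_ids, test_id) pair per subject."""
    ids = list(subject_ids)
    if len(set(ids)) != len(ids):
        dupes = [s for s, c in Counter(ids).items() if c > 1]
        raise ValueError(f"duplicate subject ids: {dupes}")
    if len(ids) < 2:
        raise ValueError("LOSO needs at least 2 subjects")
    return [([t for t in ids if t != s], s) for s in ids]


def majority_vote(epoch_labels: list):
    """Winning class when it holds strictly more than half the epochs; else None."""
    if not epoch_labels:
        raise ValueError("need at least one epoch label")
    winner, count = Counter(epoch_labels).most_common(1)[0]
    return winner if count > len(epoch_labels) / 2 else None


@dataclass
class EvalSummary:
    task: TaskSpec
    epoch_confusion: BinaryConfusion
    epoch_accuracy: float
    per_class: dict  # class label -> precision/recall/f1
    macro: dict
    subject_confusion: BinaryConfusion
    subject_accuracy: float
    reject_rate: float
    wilson: tuple
    n_subjects: int
    n_rejected: int
    degenerate_flags: list = field(default_factory=list)


def _fit_linear_svm(h_train, y_train, h_test, positive_class, svm_c=1.0):
    """Fit a linear max-margin classifier; return (pred_labels, margins).

    Margins are geometric (decision values divided by ||w||) and signed
    positive toward ``positive_class``.
    """
    clf = SVC(kernel="linear", C=svm_c)
    clf.fit(h_train, y_train)
    dec = clf.decision_function(h_test)
    margins = dec / np.linalg.norm(clf.coef_)
    preds = [clf.classes_[1] if d > 0 else clf.classes_[0] for d in dec]
    if positive_class == clf.classes_[0]:
        margins = -margins
    return preds, margins


def run_task(
    descriptors: list,
    task: TaskSpec,
    cluster_params: ClusterParams = None,
    svm_c: float = 1.0,
    feature_mode: str = "cpp",
    pca_variance: float = 0.95,
) -> list:
    """LOSO over the task's two classes; returns one FoldResult per subject.

    ``feature_mode='cpp'`` projects onto per-fold class dictionaries;
    ``'pca'`` replaces Stage 2 with a train-fitted PCA retaining
    ``pca_variance`` of the variance.  Everything downstream (train-only
    standardization, classifier) is identical between the modes.
    """
    if feature_mode not in ("cpp", "pca"):
        raise ValueError("feature_mode must be 'cpp' or 'pca'")
    cluster_params = cluster_params or ClusterParams()

    descs = [d for d in descriptors if d.label in task.class_set]
    if not descs:
        raise ValueError(f"no descriptors for task {task.name}")
    z = np.column_stack([d.vector for d in descs])
    labels = np.array([d.label for d in descs])
    subjects = np.array([d.subject_id for d in descs])
    epoch_ids = [(d.subject_id, d.epoch_index) for d in descs]
    subject_order = sorted(set(subjects))

    results = []
    for _, held_out in loso_folds(subject_order):
        train = subjects != held_out
        test = ~train
        y_train = labels[train]
        for c in task.class_set:
            if c not in y_train:
                raise ValueError(
                    f"class {c!r} absent from training split of fold {held_out!r}"
                )
        if feature_mode == "cpp":
            dicts = {}
            for c in task.class_set:
                sel = train & (labels == c)
                dicts[c] = learn_dictionary(
                    z[:, sel], cluster_params,
                    sample_ids=[e for e, m in zip(epoch_ids, sel) if m],
                    class_label=c,
                )
            h_train = feature_matrix(
                build_feature_table(z[:, train], dicts[task.c1], dicts[task.c2]))
            h_test = feature_matrix(
                build_feature_table(z[:, test], dicts[task.c1], dicts[task.c2]))
        else:
            proj = fit_pca_95(z[:, train].T, variance=pca_variance)
            h_train = apply_pca(proj, z[:, train].T)
            h_test = apply_pca(proj, z[:, test].T)

        h_train, h_test, _ = standardize(h_train, h_test)
        preds, margins = _fit_linear_svm(
            h_train, y_train, h_test, task.positive_class, svm_c)
        results.append(FoldResult(
            held_out_subject=held_out,
            true_label=str(labels[test][0]),
            pred_labels=list(preds),
            margins=np.asarray(margins),
        ))
    return results


def pooled_metrics(fold_results: list, task: TaskSpec) -> EvalSummary:
    """Aggregate fold results into epoch- and subject-level summaries."""
    if not fold_results:
        raise ValueError("need at least one fold")
    pos, neg = task.positive_class, task.negative_class

    epoch_conf = BinaryConfusion(0, 0, 0, 0)
    subj_conf = BinaryConfusion(0, 0, 0, 0)
    n_rejected = 0
    for fr in fold_results:
        for p in fr.pred_labels:
            if fr.true_label == pos:
                epoch_conf += BinaryConfusion(int(p == pos), 0, 0, int(p != pos))
            else:
                epoch_conf += BinaryConfusion(0, int(p == pos), int(p != pos), 0)
        decision = majority_vote(fr.pred_labels)
        if decision is None:
            n_rejected += 1
        elif fr.true_label == pos:
            subj_conf += BinaryConfusion(int(decision == pos), 0, 0, int(decision != pos))
        else:
            subj_conf += BinaryConfusion(0, int(decision == pos), int(decision != pos), 0)

    flags = []
    decided = subj_conf.total
    if decided == 0:
        flags.append("all subjects rejected; subject metrics reported as 0")
    subject_acc = _safe_div(subj_conf.tp + subj_conf.tn, decided)
    wilson = wilson_ci(subj_conf.tp + subj_conf.tn, decided) if decided else (0.0, 0.0)
    return EvalSummary(
        task=task,
        epoch_confusion=epoch_conf,
        epoch_accuracy=accuracy(epoch_conf),
        per_class={
            pos: class_metrics(epoch_conf, positive=True),
            neg: class_metrics(epoch_conf, positive=False),
        },
        macro=macro_metrics(epoch_conf),
        subject_confusion=subj_conf,
        subject_accuracy=subject_acc,
        reject_rate=_safe_div(n_rejected, len(fold_results)),
        wilson=wilson,
        n_subjects=len(fold_results),
        n_rejected=n_rejected,
        degenerate_flags=flags,
    )


def summary_from_confusions(
    task: TaskSpec,
    epoch_confusion: BinaryConfusion = None,
    subject_confusion: BinaryConfusion = None,
    n_rejected: int = 0,
) -> EvalSummary:
    """Metrics directly from given pooled confusion counts (worked examples)."""
    epoch_conf = epoch_confusion or BinaryConfusion(0, 0, 0, 0)
    subj_conf = subject_confusion or BinaryConfusion(0, 0, 0, 0)
    pos, neg = task.positive_class, task.negative_class
    decided = subj_conf.total
    n_subjects = decided + n_rejected
    return EvalSummary(
        task=task,
        epoch_confusion=epoch_conf,
        epoch_accuracy=accuracy(epoch_conf),
        per_class={
            pos: class_metrics(epoch_conf, positive=True),
            neg: class_metrics(epoch_conf, positive=False),
        },
        macro=macro_metrics(epoch_conf),
        subject_confusion=subj_conf,
        subject_accuracy=_safe_div(subj_conf.tp + subj_conf.tn, decided),
        reject_rate=_safe_div(n_rejected, n_subjects),
        wilson=wilson_ci(subj_conf.tp + subj_conf.tn, decided) if decided else (0.0, 0.0),
        n_subjects=n_subjects,
        n_rejected=n_rejected,
    )
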