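"""Clustering performance metrics.

Unlabelled clusterings are scored by pairwise comparison: over all unordered
pairs of individuals, the true positive rate (TPR) is the proportion of
same-population pairs that the method clustered together, and the true
negative rate (TNR) the proportion of different-population pairs it kept
apart.  Both are invariant to any relabelling of the inferred clusters, and
TPR + TNR is proportional to the Rand index.  Counting is exact at any N
via the truth x prediction contingency table.

Hybrid-mode fits have *named* classes, so individuals can additionally be
scored directly: the correct-assignment rate per class, and the "support"
for the true class (the mean membership probability the model gives it).
The only labelling freedom left is which inferred parental cluster is A;
it is resolved by majority vote among the true parental individuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["EvalReport", "pairwise_tpr_tnr", "correct_assignment", "mean_support", "evaluate_hybrid_fit"]


@dataclass
class EvalReport:
    """Bundle of evaluation metrics for one fitted dataset."""

    tpr: float
    tnr: float
    n_pairs_same: int
    n_pairs_diff: int
    per_class_correct: dict[str, float] = field(default_factory=dict)
    per_class_support: dict[str, float] = field(default_factory=dict)
    overall_correct: float | None = None
    overall_support: float | None = None
    parental_swap: bool = False

    @property
    def rand_like(self) -> float:
        return self.tpr + self.tnr

    def to_dict(self) -> dict:
        d = {
            "tpr": self.tpr,
            "tnr": self.tnr,
            "rand_like": self.rand_like,
            "n_pairs_same": self.n_pairs_same,
            "n_pairs_diff": self.n_pairs_diff,
        }
        if self.overall_correct is not None:
            d["overall_correct"] = self.overall_correct
            d["overall_support"] = self.overall_support
            d["parental_swap"] = self.parental_swap
            for c, v in self.per_class_correct.items():
                d[f"correct[{c}]"] = v
            for c, v in self.per_class_support.items():
                d[f"support[{c}]"] = v
        return d


def pairwise_tpr_tnr(truth, predicted) -> tuple[float, float]:
    """Pairwise true positive and true negative rates of a clustering.

    Computed from the contingency table: with C the truth x prediction
    count matrix, the number of pairs sharing both labels is
    sum(C choose 2), etc.  Either rate is NaN (with a warning) when its
    pair set is empty (all-same or all-distinct truth).
    """
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if truth.shape != predicted.shape or truth.ndim != 1:
        raise ValueError("truth and predicted must be equal-length 1-D sequences")
    n = truth.size
    if n < 2:
        raise ValueError("need at least two individuals")

    def _choose2(x: np.ndarray) -> float:
        return float((x * (x - 1) / 2).sum())

    _, ti = np.unique(truth, return_inverse=True)
    _, pi = np.unique(predicted, return_inverse=True)
    table = np.zeros((ti.max() + 1, pi.max() + 1))
    np.add.at(table, (ti, pi), 1)
    total = n * (n - 1) / 2
    same_truth = _choose2(table.sum(axis=1))
    same_pred = _choose2(table.sum(axis=0))
    same_both = _choose2(table)
    diff_truth = total - same_truth
    diff_both = total - same_truth - same_pred + same_both
    if same_truth == 0:
        warnings.warn("TPR undefined: no pair shares a true population")
        tpr = float("nan")
    else:
        tpr = same_both / same_truth
    if diff_truth == 0:
        warnings.warn("TNR undefined: every pair shares the true population")
        tnr = float("nan")
    else:
        tnr = diff_both / diff_truth
    return tpr, tnr


# ---------------------------------------------------------------------------
# labelled (hybrid-mode) scoring
# ---------------------------------------------------------------------------

_PARENT_TRUTH = ("P1", "P2")


def _truth_to_class(label: str, p1_is_a: bool) -> str:
    """Map a truth label (P1/P2/F1/BC?-P?) onto a fitted class name."""
    first, second = ("A", "B") if p1_is_a else ("B", "A")
    out = label.replace("P1", first).replace("P2", second)
    return out


def _resolve_polarity(
    truth: np.ndarray, predicted_names: list[str]
) -> tuple[bool, bool]:
    """Decide whether inferred parental class A corresponds to truth P1.

    Majority vote among true parental individuals; ties go to P1 = A and
    are flagged.
    """
    votes_direct = votes_swapped = 0
    for t, p in zip(truth, predicted_names):
        if t == "P1":
            votes_direct += p == "A"
            votes_swapped += p == "B"
        elif t == "P2":
            votes_direct += p == "B"
            votes_swapped += p == "A"
    tie = votes_direct == votes_swapped
    return (votes_direct >= votes_swapped), tie


def _predicted_names(result, class_labels=None) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Extract (predicted class names, class label list, memberships)."""
    if class_labels is None:
        if hasattr(result, "class_labels_"):
            class_labels = list(result.class_labels_)
        elif hasattr(result, "frequencies") and result.frequencies is not None:
            class_labels = list(result.frequencies.group_labels)
        else:
            raise ValueError("class labels could not be inferred; pass class_labels")
    if hasattr(result, "labels_"):
        assignment = np.asarray(result.labels_)
        memberships = np.asarray(result.membership_probs_)
    else:
        assignment = np.asarray(result.assignment)
        memberships = np.asarray(result.memberships)
    names = np.array([class_labels[k] for k in assignment])
    return names, class_labels, memberships


def correct_assignment(truth, result, class_labels=None) -> dict[str, float]:
    """Proportion of individuals assigned to their true class, per class.

    ``truth`` uses P1/P2 parental names; the fitted A/B polarity is resolved
    by majority vote.  Returns per-class proportions plus an ``overall``
    entry; invariant to swapping the fitted parental labels.
    """
    truth = np.asarray(truth)
    names, class_labels, _ = _predicted_names(result, class_labels)
    p1_is_a, tie = _resolve_polarity(truth, names)
    if tie:
        warnings.warn("parental matching tied; defaulting to P1 = A")
    mapped = np.array([_truth_to_class(t, p1_is_a) for t in truth])
    correct = mapped == names
    out: dict[str, float] = {}
    for cls in dict.fromkeys(truth):  # preserve truth order
        sel = truth == cls
        out[str(cls)] = float(correct[sel].mean())
    out["overall"] = float(correct.mean())
    return out


def mean_support(truth, result, class_labels=None) -> dict[str, float]:
    """Mean membership probability granted to each individual's true class."""
    truth = np.asarray(truth)
    names, class_labels, memberships = _predicted_names(result, class_labels)
    p1_is_a, tie = _resolve_polarity(truth, names)
    if tie:
        warnings.warn("parental matching tied; defaulting to P1 = A")
    index = {c: k for k, c in enumerate(class_labels)}
    true_idx = np.array([index[_truth_to_class(t, p1_is_a)] for t in truth])
    support = memberships[np.arange(len(truth)), true_idx]
    out: dict[str, float] = {}
    for cls in dict.fromkeys(truth):
        sel = truth == cls
        out[str(cls)] = float(support[sel].mean())
    out["overall"] = float(support.mean())
    return out


def evaluate_hybrid_fit(truth, result, class_labels=None) -> EvalReport:
    """Full report for a hybrid-mode fit: pairwise rates plus per-class
    correct-assignment and support."""
    truth = np.asarray(truth)
    names, class_labels, _ = _predicted_names(result, class_labels)
    tpr, tnr = pairwise_tpr_tnr(truth, names)
    correct = correct_assignment(truth, result, class_labels)
    support = mean_support(truth, result, class_labels)
    _, tie = _resolve_polarity(truth, names)
    n = len(truth)
    _, counts = np.unique(truth, return_counts=True)
    n_same = int((counts * (counts - 1) // 2).sum())
    return EvalReport(
        tpr=tpr,
        tnr=tnr,
        n_pairs_same=n_same,
        n_pairs_diff=n * (n - 1) // 2 - n_same,
        per_class_correct={k: v for k, v in correct.items() if k != "overall"},
        per_class_support={k: v for k, v in support.items() if k != "overall"},
        overall_correct=correct["overall"],
        overall_support=support["overall"],
        parental_swap=tie,
    )


def batch_report(rows: list[dict]) -> pd.DataFrame:
    """Aggregate per-dataset metric dicts into a tidy one-row-per-simulation
    table (for external meta-analysis)."""
    return pd.DataFrame(rows)
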