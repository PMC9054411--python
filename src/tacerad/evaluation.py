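"""Response labels, validation splits and ROC analysis.

RECIST categories collapse to two treatment-response groups: CR/PR form
the ease (response, +1) group and SD/PD the relief (non-response, -1)
group. Models are assessed by hold-out, stratified k-fold or bootstrap
out-of-bag splits, and scored by the ROC curve: AUC (trapezoidal area,
identical to the tie-halved concordant-pair probability), plus
sensitivity and specificity at the Youden-optimal threshold. AUC is
graded excellent (> 0.9), good (0.7 - 0.9) or average (< 0.7).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from sklearn import metrics
from sklearn.model_selection import StratifiedKFold, train_test_split

RECIST_TO_GROUP = {"CR": 1, "PR": 1, "SD": -1, "PD": -1}
GROUP_NAMES = {1: "ease", -1: "relief"}


def map_recist(recist: str) -> int:
    """RECIST category -> binary group (+1 ease/response, -1 relief)."""
    try:
        return RECIST_TO_GROUP[recist]
    except KeyError:
        raise ValueError(
            f"unknown RECIST code {recist!r}; expected one of {sorted(RECIST_TO_GROUP)}"
        ) from None


def split(
    y: np.ndarray,
    scheme: str,
    seed: int,
    test_fraction: float = 0.25,
    k: int = 5,
    n_bootstrap: int = 50,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Train/test index pairs under one of the three validation schemes.

    holdout: one stratified split at ``test_fraction``. kfold: stratified
    k disjoint folds, every case tested exactly once. bootstrap: n draws
    with replacement; the out-of-bag cases form each test set.
    """
    y = np.asarray(y)
    n = len(y)
    if scheme in ("holdout", "kfold") and n < 4:
        raise ValueError("need at least 4 cases")
    if scheme == "holdout":
        idx = np.arange(n)
        tr, te = train_test_split(idx, test_size=test_fraction, stratify=y, random_state=seed)
        return [(np.sort(tr), np.sort(te))]
    if scheme == "kfold":
        counts = [int((y == g).sum()) for g in np.unique(y)]
        if k > min(counts):
            raise ValueError(f"k={k} exceeds the smallest class count {min(counts)}")
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        return [(np.sort(tr), np.sort(te)) for tr, te in skf.split(np.zeros(n), y)]
    if scheme == "bootstrap":
        rng = np.random.default_rng(seed)
        out = []
        for _ in range(n_bootstrap):
            tr = np.sort(rng.integers(0, n, size=n))
            te = np.setdiff1d(np.arange(n), tr)
            if len(np.unique(y[tr])) == 2 and len(te) > 0 and len(np.unique(y[te])) == 2:
                out.append((tr, te))
        if not out:
            raise ValueError("no bootstrap replicate had both classes in train and test")
        return out
    raise ValueError(f"unknown scheme {scheme!r}; expected holdout|kfold|bootstrap")


def auc_grade(auc: float) -> str:
    """Qualitative AUC band: excellent > 0.9, good 0.7-0.9, average < 0.7."""
    if auc > 0.9:
        return "excellent"
    if auc >= 0.7:
        return "good"
    return "average"


@dataclasses.dataclass
class EvalReport:
    """ROC points and operating characteristics of one scored test set."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    auc_grade: str
    threshold: float
    sensitivity: float
    specificity: float
    scheme: str = "holdout"
    per_fold: list[dict] = dataclasses.field(default_factory=list)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("fpr", "tpr", "thresholds"):
            d[key] = np.asarray(d[key]).tolist()
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def roc_points(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """ROC by threshold sweep over the unique scores (ties step diagonally).

    The positive class is +1 (ease/response). Points run from (0,0) to
    (1,1) with both coordinates non-decreasing.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) != 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, thr = metrics.roc_curve(labels, scores, pos_label=1, drop_intermediate=False)
    return fpr, tpr, thr


def operating_point(
    fpr: np.ndarray, tpr: np.ndarray, thresholds: np.ndarray
) -> tuple[float, float, float]:
    """Youden-optimal threshold: maximize TPR - FPR; ties -> lower threshold."""
    j = tpr - fpr
    best = np.flatnonzero(j == j.max())
    i = int(best[-1])  # thresholds are descending; last tie = lowest threshold
    return float(thresholds[i]), float(tpr[i]), float(1.0 - fpr[i])


def roc_auc(scores: np.ndarray, labels: np.ndarray, scheme: str = "holdout") -> EvalReport:
    """Full ROC report for one set of decision scores."""
    fpr, tpr, thr = roc_points(scores, labels)
    auc = float(np.trapezoid(tpr, fpr))
    threshold, sens, spec = operating_point(fpr, tpr, thr)
    return EvalReport(
        fpr=fpr, tpr=tpr, thresholds=thr, auc=auc, auc_grade=auc_grade(auc),
        threshold=threshold, sensitivity=sens, specificity=spec, scheme=scheme,
    )
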