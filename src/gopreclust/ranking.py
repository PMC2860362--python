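"""Mahalanobis "interestingness" ranking of (sub)classes and ROC evaluation.

In the first two principal components, interesting (sub)classes sit away
from the center of the score cloud while flat or cancelled profiles crowd
the origin.  Classes are therefore ranked by the Mahalanobis distance of
their 2-D score to the cloud center (sample mean, sample covariance).  Given
a reference list of GO terms expected to respond to the experiment, sweeping
a distance threshold yields sensitivity/specificity pairs and an ROC curve;
comparing the preclustered against the unclustered ranking quantifies how
much preclustering improves the identification of relevant terms.  A
subclass inherits the relevance of its parent term.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io_annotation import GO_ID_PATTERN

__all__ = [
    "RankedClasses",
    "ROCCurve",
    "ReferenceTermList",
    "msc_reference_list",
    "read_reference_list",
    "mahalanobis_rank",
    "label_classes",
    "roc_curve",
    "compare_rocs",
    "parent_term",
    "write_roc",
    "plot_rocs",
]


@dataclass
class RankedClasses:
    """Classes sorted by decreasing Mahalanobis distance from the score center."""

    class_labels: list[str]
    distances: np.ndarray
    center: np.ndarray
    covariance: np.ndarray


@dataclass
class ROCCurve:
    """Sensitivity/specificity sweep over the distance threshold, with trapezoidal AUC."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    n_reference: int


@dataclass
class ReferenceTermList:
    term_ids: frozenset[str]

    def __post_init__(self) -> None:
        self.term_ids = frozenset(self.term_ids)
        for t in self.term_ids:
            if not GO_ID_PATTERN.match(t):
                raise ValueError(f"malformed GO identifier in reference list: {t!r}")


def msc_reference_list() -> ReferenceTermList:
    """The packaged 24-term osteogenesis/differentiation reference list."""
    from importlib import resources

    path = resources.files("gopreclust") / "data" / "msc_reference_terms.txt"
    return ReferenceTermList(
        frozenset(
            line.split()[0]
            for line in path.read_text(encoding="utf-8").splitlines()
            if line.strip() and not line.startswith("#")
        )
    )


def read_reference_list(path: str | Path) -> ReferenceTermList:
    """One GO id per line (leading token of the line; rest is free description)."""
    terms = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            terms.append(line.split()[0])
    return ReferenceTermList(frozenset(terms))


def parent_term(label: str) -> str:
    """``GO:0007047.2`` → ``GO:0007047``; plain term ids pass through."""
    head, _, tail = label.rpartition(".")
    if head and tail.isdigit():
        return head
    return label


def mahalanobis_rank(scores2: np.ndarray, class_labels: list[str]) -> RankedClasses:
    """Rank classes by Mahalanobis distance to the center of the 2-D score cloud.

    Center and covariance are the sample mean and sample covariance of all
    scores; ties keep input order (stable sort).
    """
    scores2 = np.asarray(scores2, dtype=float)
    if scores2.ndim != 2 or scores2.shape[1] != 2:
        raise ValueError("scores2 must be an n × 2 matrix")
    n = scores2.shape[0]
    if n < 3:
        raise ValueError("need at least 3 classes to estimate the score covariance")
    center = scores2.mean(axis=0)
    cov = np.cov(scores2, rowvar=False)
    if not np.isfinite(np.linalg.cond(cov)) or np.linalg.cond(cov) > 1e12:
        raise ValueError(
            "singular score covariance; jitter the scores or drop a dimension"
        )
    prec = np.linalg.inv(cov)
    diff = scores2 - center
    d2 = np.einsum("ni,ij,nj->n", diff, prec, diff)
    dist = np.sqrt(np.maximum(d2, 0.0))
    order = np.argsort(-dist, kind="stable")
    return RankedClasses(
        class_labels=[class_labels[i] for i in order],
        distances=dist[order],
        center=center,
        covariance=cov,
    )


def label_classes(class_labels: list[str], reference: ReferenceTermList) -> np.ndarray:
    """Binary relevance labels: positive iff the parent term is in the reference list."""
    return np.array([parent_term(lab) in reference.term_ids for lab in class_labels], dtype=int)


def roc_curve(ranked: RankedClasses, labels: np.ndarray) -> ROCCurve:
    """ROC by sweeping the distance threshold down through every distinct distance.

    ``labels`` is aligned with ``ranked.class_labels`` (i.e. already in ranked
    order).  Tied distances enter at a single threshold step.
    """
    labels = np.asarray(labels, dtype=int)
    if labels.shape[0] != len(ranked.class_labels):
        raise ValueError("labels must align with the ranked classes")
    P = int(labels.sum())
    N = int(len(labels) - P)
    if P == 0 or N == 0:
        raise ValueError("ROC needs at least one positive and one negative label")
    thresholds = [np.inf]
    sens = [0.0]
    spec = [1.0]
    dist = ranked.distances
    i = 0
    tp = fp = 0
    while i < len(dist):
        thr = dist[i]
        while i < len(dist) and dist[i] == thr:  # all ties at one step
            tp += labels[i]
            fp += 1 - labels[i]
            i += 1
        thresholds.append(thr)
        sens.append(tp / P)
        spec.append((N - fp) / N)
    fpr = 1.0 - np.asarray(spec)
    auc = float(np.trapezoid(np.asarray(sens), fpr))
    return ROCCurve(
        thresholds=np.asarray(thresholds),
        sensitivity=np.asarray(sens),
        specificity=np.asarray(spec),
        auc=auc,
        n_reference=P,
    )


def _sens_at(curve: ROCCurve, fpr_grid: np.ndarray) -> np.ndarray:
    """Step-function sensitivity of the sweep at given 1−specificity values."""
    fpr = 1.0 - curve.specificity
    out = np.empty_like(fpr_grid)
    for i, x in enumerate(fpr_grid):
        out[i] = curve.sensitivity[fpr <= x + 1e-12].max(initial=0.0)
    return out


def compare_rocs(curve_a: ROCCurve, curve_b: ROCCurve) -> dict:
    """AUC difference (a − b) and whether a weakly dominates b on the common grid."""
    grid = np.unique(np.concatenate([1.0 - curve_a.specificity, 1.0 - curve_b.specificity]))
    sa, sb = _sens_at(curve_a, grid), _sens_at(curve_b, grid)
    return {
        "delta_auc": curve_a.auc - curve_b.auc,
        "dominates": bool(np.all(sa >= sb - 1e-12)),
    }


def write_roc(curve: ROCCurve, path: str | Path) -> Path:
    pd.DataFrame(
        {
            "threshold": curve.thresholds,
            "sensitivity": curve.sensitivity,
            "specificity": curve.specificity,
        }
    ).to_csv(path, sep="\t", index=False)
    return Path(path)


def plot_rocs(
    preclustered: ROCCurve,
    unclustered: ROCCurve | None = None,
    out_path: str | Path | None = None,
):
    """Overlay ROC curves: grey = preclustered, black = unclustered."""
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(1 - preclustered.specificity, preclustered.sensitivity, color="grey",
            label=f"preclustered (AUC {preclustered.auc:.3f})")
    if unclustered is not None:
        ax.plot(1 - unclustered.specificity, unclustered.sensitivity, color="black",
                label=f"unclustered (AUC {unclustered.auc:.3f})")
    ax.plot([0, 1], [0, 1], ls=":", color="0.7", lw=0.8)
    ax.set_xlabel("1 − specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(fontsize=8)
    if out_path is not None:
        fig.savefig(out_path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return fig
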