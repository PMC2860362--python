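"""Mean-profile matrix construction, SVD-based PCA, and biplots.

Each (sub)class is summarized by the mean expression (or interaction)
profile of its member genes — equivalently ``EᵀG`` with the binary
membership columns normalized to sum one.  The classes × conditions profile
matrix ``X`` is then decomposed by SVD, ``X = U Λ Vᵀ``, and the first two
components of the scores (classes) and loadings (time points or treatments)
are drawn together in a biplot: classes close to a loading direction are
associated with that condition, classes near the origin have flat or
cancelled profiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .io_annotation import ExpressionMatrix
from .preclust import SubclassCatalog

__all__ = [
    "ProfileMatrix",
    "PCAModel",
    "ProfilePCA",
    "combine",
    "pca",
    "biplot",
    "write_profiles",
    "write_pca",
]


@dataclass
class ProfileMatrix:
    """(Sub)classes × conditions matrix of mean member-gene profiles."""

    class_labels: list[str]
    condition_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.class_labels), len(self.condition_ids)):
            raise ValueError("profile matrix shape mismatch")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.class_labels, columns=self.condition_ids)


@dataclass
class PCAModel:
    """Full SVD decomposition of the (optionally column-centered) profile matrix.

    ``scores`` = U·Λ (classes as objects), ``loadings`` = columns of V
    (orthonormal), with r = min(n_classes, n_conditions) components.  Signs
    are fixed by forcing the largest-magnitude element of each loading
    vector positive, so repeated runs are identical.
    """

    class_labels: list[str]
    condition_ids: list[str]
    scores: np.ndarray
    loadings: np.ndarray
    singular_values: np.ndarray
    explained_variance_fraction: np.ndarray
    column_means: np.ndarray


class ProfilePCA(BaseEstimator, TransformerMixin):
    """PCA of class mean profiles via SVD.

    Parameters
    ----------
    center : subtract column (condition) means before the SVD (default).
        ``center=False`` decomposes the raw profile matrix.

    Attributes after ``fit``: ``scores_`` (n × r, U·Λ), ``loadings_``
    (m × r, orthonormal columns of V), ``singular_values_``,
    ``explained_variance_ratio_``, ``mean_``.
    """

    def __init__(self, center: bool = True):
        self.center = center

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        n, m = X.shape
        if n < 2 or m < 2:
            raise ValueError("PCA needs at least 2 classes and 2 conditions")
        self.mean_ = X.mean(axis=0) if self.center else np.zeros(m)
        Xc = X - self.mean_
        U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
        total = float((S**2).sum())
        if total <= np.finfo(float).tiny:
            raise ValueError("matrix has no variance to decompose")
        # sign convention: largest-|.| loading element positive
        V = Vt.T
        for j in range(V.shape[1]):
            if V[np.abs(V[:, j]).argmax(), j] < 0:
                V[:, j] *= -1.0
                U[:, j] *= -1.0
        self.loadings_ = V
        self.scores_ = U * S[None, :]
        self.singular_values_ = S
        self.explained_variance_ratio_ = S**2 / total
        return self

    def transform(self, X):
        return (np.asarray(X, dtype=float) - self.mean_) @ self.loadings_


def combine(expression: ExpressionMatrix, catalog: SubclassCatalog) -> ProfileMatrix:
    """Mean profile per catalog entry: X[c, t] = (1/n_c)·Σ_{g ∈ c} E[g, t]."""
    idx = expression.row_index()
    rows = []
    for e in catalog.entries:
        for g in e.member_gene_ids:
            if g not in idx:
                raise KeyError(f"gene {g!r} of term {e.term_id} missing from expression matrix")
        rows.append(expression.values[[idx[g] for g in e.member_gene_ids], :].mean(axis=0))
    return ProfileMatrix(catalog.labels, list(expression.condition_ids), np.asarray(rows))


def pca(profiles: ProfileMatrix, center: bool = True) -> PCAModel:
    """SVD decomposition of the profile matrix → :class:`PCAModel`."""
    est = ProfilePCA(center=center).fit(profiles.values)
    return PCAModel(
        class_labels=list(profiles.class_labels),
        condition_ids=list(profiles.condition_ids),
        scores=est.scores_,
        loadings=est.loadings_,
        singular_values=est.singular_values_,
        explained_variance_fraction=est.explained_variance_ratio_,
        column_means=est.mean_,
    )


def biplot(
    model: PCAModel,
    icc_by_class: dict[str, float] | None = None,
    icc_threshold: float = 0.2,
    highlight: list[str] | None = None,
    connect_loadings: bool = False,
    out_path: str | Path | None = None,
) -> dict:
    """First-two-component biplot of class scores and condition loadings.

    Classes with ICC above ``icc_threshold`` are drawn dark, the rest light
    grey; terms in ``highlight`` (matched on the parent term id) become star
    markers.  Loadings are drawn as arrows (treatments) or, with
    ``connect_loadings=True``, as labeled points joined in condition order
    (time courses).  Loadings are rescaled to the score range for legibility;
    the scale factor is reported in the legend and the returned summary.

    Returns a summary dict (dark/light/star counts, segment count, scale).
    """
    import warnings

    import matplotlib
    import matplotlib.pyplot as plt

    if model.scores.shape[1] < 2:
        raise ValueError("biplot needs at least 2 components")
    icc_by_class = icc_by_class or {}
    highlight = list(highlight or [])
    labels = model.class_labels
    known_terms = {lab.split(".")[0] for lab in labels}
    for term in highlight:
        if term not in known_terms:
            warnings.warn(f"highlight term {term} not present in the model", stacklevel=2)

    s2 = model.scores[:, :2]
    l2 = model.loadings[:, :2]
    score_range = np.abs(s2).max()
    load_range = np.abs(l2).max()
    scale = float(score_range / load_range) if load_range > 0 else 1.0
    l2s = l2 * scale

    dark = np.array([icc_by_class.get(lab, 0.0) > icc_threshold for lab in labels])
    star = np.array([lab.split(".")[0] in highlight for lab in labels])

    fig, ax = plt.subplots(figsize=(7, 7))
    plain = ~star
    ax.scatter(s2[plain & dark, 0], s2[plain & dark, 1], c="black", s=18,
               label=f"ICC > {icc_threshold:g}")
    ax.scatter(s2[plain & ~dark, 0], s2[plain & ~dark, 1], c="lightgrey", s=18,
               label=f"ICC ≤ {icc_threshold:g}")
    if star.any():
        col = np.where(dark[star], "black", "lightgrey")
        ax.scatter(s2[star, 0], s2[star, 1], c=col, marker="*", s=160,
                   edgecolors="black", label="highlighted term")
    n_segments = 0
    if connect_loadings:
        ax.plot(l2s[:, 0], l2s[:, 1], "-", color="tab:blue", lw=1)
        ax.scatter(l2s[:, 0], l2s[:, 1], c="tab:blue", s=10)
        n_segments = len(model.condition_ids) - 1
        for name, (x, y) in zip(model.condition_ids, l2s):
            ax.annotate(str(name), (x, y), fontsize=7, color="tab:blue")
    else:
        for name, (x, y) in zip(model.condition_ids, l2s):
            ax.annotate("", xy=(x, y), xytext=(0, 0),
                        arrowprops=dict(arrowstyle="->", color="tab:blue"))
            ax.annotate(str(name), (x, y), fontsize=8, color="tab:blue")
    ev = model.explained_variance_fraction
    ax.set_xlabel(f"PC 1 ({100 * ev[0]:.1f}% of variance)")
    ax.set_ylabel(f"PC 2 ({100 * ev[1]:.1f}% of variance)")
    ax.axhline(0, color="0.8", lw=0.5)
    ax.axvline(0, color="0.8", lw=0.5)
    ax.legend(fontsize=8, title=f"loadings × {scale:.3g}")
    summary = {
        "n_dark": int((dark & plain).sum() + (dark & star).sum()),
        "n_light": int((~dark).sum()),
        "n_star": int(star.sum()),
        "n_segments": n_segments,
        "loading_scale": scale,
    }
    if out_path is not None:
        fig.savefig(out_path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return summary


def write_profiles(profiles: ProfileMatrix, path: str | Path) -> Path:
    profiles.to_frame().to_csv(path, sep="\t", index_label="class")
    return Path(path)


def write_pca(model: PCAModel, out_dir: str | Path, prefix: str = "pca") -> dict[str, Path]:
    """Serialize scores, loadings and the variance table as TSV files."""
    out_dir = Path(out_dir)
    r = len(model.singular_values)
    comps = [f"PC{i + 1}" for i in range(r)]
    paths = {}
    scores = pd.DataFrame(model.scores, index=model.class_labels, columns=comps)
    paths["scores"] = out_dir / f"{prefix}_scores.tsv"
    scores.to_csv(paths["scores"], sep="\t", index_label="class")
    loadings = pd.DataFrame(model.loadings, index=model.condition_ids, columns=comps)
    paths["loadings"] = out_dir / f"{prefix}_loadings.tsv"
    loadings.to_csv(paths["loadings"], sep="\t", index_label="condition")
    var = pd.DataFrame(
        {
            "component": comps,
            "singular_value": model.singular_values,
            "explained_variance_fraction": model.explained_variance_fraction,
        }
    )
    paths["variance"] = out_dir / f"{prefix}_variance.tsv"
    var.to_csv(paths["variance"], sep="\t", index=False)
    return paths
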