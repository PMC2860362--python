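"""Per-GO-class preclustering and the Intra Cluster Correlation statistic.

GO classes are frequently heterogeneous: the genes annotated to one term can
carry several distinct — phase-shifted or even anti-correlated — expression
profiles, so the class mean cancels out and the term looks uninteresting.
Preclustering runs model-based clustering *within* each GO class and replaces
a heterogeneous class by its expression-homogeneous subclasses before any
summarization:

1. for each term, take the expression submatrix of its member genes;
2. select the best mixture (family × k, k ≤ k_max) by BIC;
3. if k = 1 keep the class as is, otherwise split it by the hard assignments,
   retaining only subclasses with at least ``min_size`` genes;
4. the catalog of (sub)classes replaces the original membership columns.

Cluster tightness is measured by the Intra Cluster Correlation (ICC): the
mean of all pairwise Pearson correlations between member genes, i.e. the mean
of the strictly-lower-triangle entries of their correlation matrix.  High ICC
marks a coherent profile; near-zero ICC marks noise or a cancelling mixture.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .io_annotation import ExpressionMatrix, MembershipMatrix
from .mixture import DEFAULT_FAMILIES, DegenerateFitError, MixtureModelSelector

__all__ = [
    "PreclustConfig",
    "SubclassDef",
    "SubclassCatalog",
    "GOPreclusterer",
    "icc",
    "precluster_class",
    "precluster_catalog",
    "identity_catalog",
    "icc_scatter_data",
    "term_subseed",
    "write_catalog",
    "write_counts",
]

COUNTS_COLUMNS = ("# GO cl.", "# split", "# new", "# > min", "total")


@dataclass
class PreclustConfig:
    """Tunables of the preclustering stage (defaults: min 4 genes, k ≤ 8)."""

    min_size: int = 4
    k_max: int = 8
    families: tuple[str, ...] = DEFAULT_FAMILIES
    seed: int = 0
    reg: float | None = None
    max_iter: int = 500
    tol: float = 1e-8

    def __post_init__(self) -> None:
        if self.min_size < 2:
            raise ValueError("min_size must be ≥ 2")
        if self.k_max < 1:
            raise ValueError("k_max must be ≥ 1")


@dataclass
class SubclassDef:
    """One catalog entry: a whole class (subclass_index 0) or one subclass."""

    term_id: str
    subclass_index: int
    member_gene_ids: list[str]
    icc: float | None = None

    @property
    def label(self) -> str:
        """Plot/report label: ``GO:NNNNNNN`` or ``GO:NNNNNNN.k`` for subclasses."""
        if self.subclass_index == 0:
            return self.term_id
        return f"{self.term_id}.{self.subclass_index}"


@dataclass
class SubclassCatalog:
    """All (sub)classes after preclustering plus the bookkeeping counts.

    ``counts`` carries n_classes_in, n_split, n_subclasses_formed (clusters
    produced by split classes, before the size filter), n_subclasses_retained
    (those with ≥ min_size genes) and n_total_out, which always satisfies
    n_total_out = (n_classes_in − n_split) + n_subclasses_retained.
    """

    entries: list[SubclassDef] = field(default_factory=list)
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.counts:
            c = self.counts
            if c["n_total_out"] != (c["n_classes_in"] - c["n_split"]) + c["n_subclasses_retained"]:
                raise ValueError("catalog count identity violated")
            if c["n_total_out"] != len(self.entries):
                raise ValueError("n_total_out does not match number of entries")
        by_term: dict[str, list[int]] = {}
        for e in self.entries:
            by_term.setdefault(e.term_id, []).append(e.subclass_index)
        for term, idxs in by_term.items():
            if 0 in idxs and len(idxs) > 1:
                raise ValueError(f"term {term} appears both unsplit and split")

    @property
    def labels(self) -> list[str]:
        return [e.label for e in self.entries]

    def icc_by_label(self) -> dict[str, float]:
        return {e.label: e.icc for e in self.entries if e.icc is not None}


def icc(profiles: np.ndarray, gene_ids: list[str] | None = None) -> float:
    """Mean pairwise Pearson correlation over the lower triangle (the ICC).

    ``profiles`` is genes × conditions with n ≥ 2 rows and d ≥ 3 columns; a
    constant (zero-variance) row makes the correlation undefined and raises,
    naming the offending gene when ``gene_ids`` is given.
    """
    profiles = np.asarray(profiles, dtype=float)
    n, d = profiles.shape
    if n < 2:
        raise ValueError("ICC needs at least 2 gene profiles")
    if d < 3:
        raise ValueError("ICC needs at least 3 conditions")
    flat = np.flatnonzero(profiles.std(axis=1) == 0.0)
    if flat.size:
        name = gene_ids[flat[0]] if gene_ids is not None else f"row {flat[0]}"
        raise ValueError(f"zero-variance profile for {name}: correlation undefined")
    corr = np.corrcoef(profiles)
    return float(corr[np.tril_indices(n, k=-1)].mean())


def term_subseed(seed: int, term_id: str) -> int:
    """Stable per-term sub-seed < 2^31, independent of term iteration order."""
    digest = hashlib.blake2s(f"{seed}:{term_id}".encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31)


def precluster_class(
    class_profiles: np.ndarray,
    gene_ids: list[str],
    config: PreclustConfig,
    seed: int | None = None,
) -> tuple[list[tuple[int, list[str]]], int]:
    """Cluster one GO class; return ([(cluster_index, member gene ids), ...], selected k).

    When the BIC-best model has k = 1, the whole class comes back as one
    subset with cluster_index 0 (unsplit).  Otherwise each retained subset
    keeps its 1-based mixture-component index, and clusters smaller than
    ``config.min_size`` are dropped.
    """
    X = np.asarray(class_profiles, dtype=float)
    if X.shape[0] < config.min_size:
        raise ValueError(f"class has {X.shape[0]} genes, fewer than min_size={config.min_size}")
    sel = MixtureModelSelector(
        k_max=config.k_max,
        families=config.families,
        random_state=config.seed if seed is None else seed,
        max_iter=config.max_iter,
        tol=config.tol,
        reg=config.reg,
    )
    best = sel.fit(X).best_
    k = best.n_components
    if k == 1:
        return [(0, list(gene_ids))], 1
    subsets: list[tuple[int, list[str]]] = []
    for j in range(k):
        members = [g for g, lab in zip(gene_ids, best.labels_) if lab == j]
        if len(members) >= config.min_size:
            subsets.append((j + 1, members))
    return subsets, k


class GOPreclusterer(BaseEstimator):
    """Preclustering of every GO class of a membership matrix.

    ``fit(expression, membership)`` runs BIC-selected model-based clustering
    inside each term column and stores the resulting catalog under
    ``catalog_``.  Per-term sub-seeds derived from ``random_state`` and the
    term id make the result independent of term iteration order.
    """

    def __init__(
        self,
        min_size: int = 4,
        k_max: int = 8,
        families: tuple[str, ...] = DEFAULT_FAMILIES,
        random_state: int = 0,
        reg: float | None = None,
        max_iter: int = 500,
        tol: float = 1e-8,
    ):
        self.min_size = min_size
        self.k_max = k_max
        self.families = families
        self.random_state = random_state
        self.reg = reg
        self.max_iter = max_iter
        self.tol = tol

    def _config(self) -> PreclustConfig:
        return PreclustConfig(
            min_size=self.min_size, k_max=self.k_max, families=self.families,
            seed=self.random_state, reg=self.reg, max_iter=self.max_iter, tol=self.tol,
        )

    def fit(self, expression: ExpressionMatrix, membership: MembershipMatrix):
        if membership.n_terms == 0:
            raise ValueError("empty membership matrix")
        if membership.gene_ids != expression.gene_ids:
            raise ValueError("expression and membership are not row-aligned")
        config = self._config()
        entries: list[SubclassDef] = []
        n_split = n_formed = n_retained = 0
        for term in membership.term_ids:
            genes = membership.members_of(term)
            sub = expression.submatrix(genes)
            try:
                subsets, k = precluster_class(
                    sub, genes, config, seed=term_subseed(self.random_state, term)
                )
            except (DegenerateFitError, ValueError) as exc:
                raise type(exc)(f"term {term}: {exc}") from exc
            if k > 1:
                n_split += 1
                n_formed += k
                n_retained += len(subsets)
            for idx, members in subsets:
                entries.append(
                    SubclassDef(term, idx, members, icc=icc(expression.submatrix(members), members))
                )
        counts = {
            "n_classes_in": membership.n_terms,
            "n_split": n_split,
            "n_subclasses_formed": n_formed,
            "n_subclasses_retained": n_retained,
            "n_total_out": len(entries),
        }
        self.catalog_ = SubclassCatalog(entries, counts)
        return self


def precluster_catalog(
    expression: ExpressionMatrix,
    membership: MembershipMatrix,
    config: PreclustConfig | None = None,
) -> SubclassCatalog:
    """Run the preclustering algorithm over every term and assemble the catalog."""
    config = config or PreclustConfig()
    est = GOPreclusterer(
        min_size=config.min_size, k_max=config.k_max, families=config.families,
        random_state=config.seed, reg=config.reg, max_iter=config.max_iter, tol=config.tol,
    )
    return est.fit(expression, membership).catalog_


def identity_catalog(
    expression: ExpressionMatrix, membership: MembershipMatrix
) -> SubclassCatalog:
    """The no-preclustering catalog: every term kept whole (the comparison branch)."""
    if membership.n_terms == 0:
        raise ValueError("empty membership matrix")
    entries = [
        SubclassDef(term, 0, membership.members_of(term))
        for term in membership.term_ids
    ]
    for e in entries:
        e.icc = icc(expression.submatrix(e.member_gene_ids), e.member_gene_ids)
    counts = {
        "n_classes_in": membership.n_terms,
        "n_split": 0,
        "n_subclasses_formed": 0,
        "n_subclasses_retained": 0,
        "n_total_out": len(entries),
    }
    return SubclassCatalog(entries, counts)


def icc_scatter_data(
    catalog: SubclassCatalog,
    expression: ExpressionMatrix,
    membership: MembershipMatrix,
) -> list[tuple[float, float, str, int]]:
    """Pairs (parent-class ICC, entry ICC) for the before/after scatter diagnostic.

    Unsplit entries land on the diagonal (parent == entry); subclasses of a
    heterogeneous class typically move above it.
    """
    parent_icc: dict[str, float] = {}
    for term in membership.term_ids:
        genes = membership.members_of(term)
        if len(genes) >= 2:
            parent_icc[term] = icc(expression.submatrix(genes), genes)
    out = []
    for e in catalog.entries:
        if e.term_id not in parent_icc:
            continue
        entry_icc = e.icc
        if entry_icc is None:
            entry_icc = icc(expression.submatrix(e.member_gene_ids), e.member_gene_ids)
        out.append((parent_icc[e.term_id], entry_icc, e.term_id, e.subclass_index))
    return out


def write_catalog(catalog: SubclassCatalog, path: str | Path) -> Path:
    """Serialize the catalog as TSV (one row per (sub)class)."""
    path = Path(path)
    rows = [
        {
            "term_id": e.term_id,
            "subclass_index": e.subclass_index,
            "n_genes": len(e.member_gene_ids),
            "icc": e.icc,
            "member_gene_ids": ",".join(e.member_gene_ids),
        }
        for e in catalog.entries
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


def write_counts(catalog: SubclassCatalog, path: str | Path) -> Path:
    """One-row TSV with the class-count bookkeeping (before/after preclustering)."""
    path = Path(path)
    c = catalog.counts
    row = dict(
        zip(
            COUNTS_COLUMNS,
            [
                c["n_classes_in"], c["n_split"], c["n_subclasses_formed"],
                c["n_subclasses_retained"], c["n_total_out"],
            ],
        )
    )
    pd.DataFrame([row]).to_csv(path, sep="\t", index=False)
    return path
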