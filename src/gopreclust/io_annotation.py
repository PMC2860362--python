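"""Reading expression matrices and gene→GO annotations, and building the
binary membership matrix.

The two inputs of the method are an expression matrix ``E`` (genes ×
conditions, where conditions are time points of a synchronised time course
or treatment interaction effects from an upstream ANOVA) and a gene→GO-term
mapping from which the binary membership matrix ``G`` (genes × terms) is
built.  Only terms of one GO namespace (Biological Process by default) that
annotate at least ``min_genes`` measured genes are kept, and genes without
any surviving annotation are dropped, so that the rows of ``E`` and ``G``
stay aligned.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "AnnotationRecord",
    "AnnotationTable",
    "MembershipMatrix",
    "read_expression",
    "write_expression",
    "read_annotation",
    "build_membership",
]

GO_ID_PATTERN = re.compile(r"^GO:\d{7}$")

NAMESPACES = ("biological_process", "molecular_function", "cellular_component", "unknown")

#: GAF column-9 aspect codes → namespace names.
GAF_ASPECT = {"P": "biological_process", "F": "molecular_function", "C": "cellular_component"}

MissingPolicy = Literal["drop_gene", "row_mean_impute"]


@dataclass
class ExpressionMatrix:
    """Genes × conditions numeric matrix (log-ratios or interaction effects).

    Rows are genes, columns are conditions (time points or treatments).
    After construction through :func:`read_expression` the matrix contains
    no missing values.
    """

    gene_ids: list[str]
    condition_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids in ExpressionMatrix")
        if len(set(self.condition_ids)) != len(self.condition_ids):
            raise ValueError("duplicate condition ids in ExpressionMatrix")
        if self.values.shape != (len(self.gene_ids), len(self.condition_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes × {len(self.condition_ids)} conditions"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_conditions(self) -> int:
        return len(self.condition_ids)

    def row_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def submatrix(self, gene_ids: Iterable[str]) -> np.ndarray:
        idx = self.row_index()
        return self.values[[idx[g] for g in gene_ids], :]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.condition_ids)


@dataclass(frozen=True)
class AnnotationRecord:
    gene_id: str
    term_id: str
    namespace: str = "unknown"


@dataclass
class AnnotationTable:
    """Deduplicated set of gene→GO-term annotations."""

    records: list[AnnotationRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: dict[tuple[str, str], AnnotationRecord] = {}
        for rec in self.records:
            if rec.namespace not in NAMESPACES:
                raise ValueError(f"unknown namespace {rec.namespace!r}")
            if not GO_ID_PATTERN.match(rec.term_id):
                raise ValueError(f"malformed GO identifier {rec.term_id!r} (expected GO:NNNNNNN)")
            seen.setdefault((rec.gene_id, rec.term_id), rec)
        self.records = list(seen.values())

    def __len__(self) -> int:
        return len(self.records)

    def term_members(self, namespace: str | None = None) -> dict[str, list[str]]:
        """Mapping term_id → sorted gene ids, optionally restricted to one namespace."""
        out: dict[str, set[str]] = {}
        for rec in self.records:
            if namespace is not None and rec.namespace != namespace:
                continue
            out.setdefault(rec.term_id, set()).add(rec.gene_id)
        return {t: sorted(gs) for t, gs in out.items()}


@dataclass
class MembershipMatrix:
    """Binary genes × terms matrix G ("1" if the gene carries the annotation)."""

    gene_ids: list[str]
    term_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.gene_ids), len(self.term_ids)):
            raise ValueError("membership shape mismatch")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("membership entries must be 0 or 1")
        self.values = self.values.astype(np.int8)

    @property
    def n_terms(self) -> int:
        return len(self.term_ids)

    def members_of(self, term_id: str) -> list[str]:
        j = self.term_ids.index(term_id)
        return [g for g, v in zip(self.gene_ids, self.values[:, j]) if v]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.term_ids)


def read_expression(path: str | Path, missing_policy: MissingPolicy = "drop_gene") -> ExpressionMatrix:
    """Read a TSV expression matrix (header = condition labels, first column = gene ids).

    Empty cells and the literal ``NA`` are treated as missing and resolved per
    ``missing_policy``: ``drop_gene`` removes the gene's row, ``row_mean_impute``
    replaces the cell with the mean of the gene's observed values.  File row
    order is preserved.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    if df.empty or df.shape[1] == 0:
        raise ValueError(f"{path}: empty expression file")
    dup = df.index[df.index.duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate gene id {dup[0]!r}")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        for i, cell in enumerate(df[col]):
            cell = cell.strip()
            if cell in ("", "NA"):
                values[i, j] = np.nan
                continue
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric value {cell!r} for gene {df.index[i]!r}, "
                    f"condition {col!r}"
                ) from None
    gene_ids = [str(g) for g in df.index]
    condition_ids = [str(c) for c in df.columns]
    missing_rows = np.isnan(values).any(axis=1)
    if missing_rows.any():
        if missing_policy == "drop_gene":
            keep = ~missing_rows
            gene_ids = [g for g, k in zip(gene_ids, keep) if k]
            values = values[keep]
        elif missing_policy == "row_mean_impute":
            for i in np.flatnonzero(missing_rows):
                row = values[i]
                if np.isnan(row).all():
                    raise ValueError(f"{path}: gene {gene_ids[i]!r} has no observed values")
                row[np.isnan(row)] = np.nanmean(row)
        else:
            raise ValueError(f"unknown missing_policy {missing_policy!r}")
    if not gene_ids:
        raise ValueError(f"{path}: no genes left after applying missing policy")
    return ExpressionMatrix(gene_ids, condition_ids, values)


def write_expression(expression: ExpressionMatrix, path: str | Path) -> Path:
    """Write a TSV that :func:`read_expression` round-trips bit-exactly."""
    path = Path(path)
    expression.to_frame().to_csv(path, sep="\t", index_label="gene_id")
    return path


def read_annotation(
    path: str | Path,
    format: Literal["tsv2col", "gaf"] = "tsv2col",
    gaf_gene_column: Literal["symbol", "id"] = "symbol",
) -> AnnotationTable:
    """Read a gene→GO mapping from a 2/3-column TSV or a GAF 2.x file.

    tsv2col rows are ``gene_id<TAB>term_id[<TAB>namespace]``.  For GAF input the
    gene id is taken from the DB Object Symbol (column 3) or DB Object ID
    (column 2) per ``gaf_gene_column``; the GO id from column 5; the aspect
    (column 9) P/F/C maps onto the three GO namespaces.
    """
    path = Path(path)
    records: list[AnnotationRecord] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if format == "gaf":
                if line.startswith("!"):
                    continue
                cols = line.split("\t")
                if len(cols) < 9:
                    raise ValueError(f"{path}:{lineno}: GAF line has {len(cols)} columns, expected ≥ 9")
                gene = cols[2] if gaf_gene_column == "symbol" else cols[1]
                term = cols[4]
                namespace = GAF_ASPECT.get(cols[8], "unknown")
            elif format == "tsv2col":
                cols = line.split("\t")
                if len(cols) < 2:
                    raise ValueError(f"{path}:{lineno}: expected ≥ 2 tab-separated columns")
                gene, term = cols[0].strip(), cols[1].strip()
                namespace = cols[2].strip() if len(cols) > 2 and cols[2].strip() else "unknown"
            else:
                raise ValueError(f"unknown annotation format {format!r}")
            if not GO_ID_PATTERN.match(term):
                raise ValueError(f"{path}:{lineno}: malformed GO identifier {term!r}")
            records.append(AnnotationRecord(gene, term, namespace))
    return AnnotationTable(records)


def build_membership(
    annotation: AnnotationTable,
    expression: ExpressionMatrix,
    namespace: str | None = "biological_process",
    min_genes: int = 4,
) -> tuple[MembershipMatrix, ExpressionMatrix]:
    """Build the binary G matrix, keeping terms with ≥ ``min_genes`` measured genes.

    Terms outside the requested namespace are discarded first (pass
    ``namespace=None`` to keep all).  Genes without any surviving annotation
    are removed from the returned expression matrix, so both outputs are
    row-aligned.
    """
    if min_genes < 2:
        raise ValueError("min_genes must be ≥ 2")
    measured = set(expression.gene_ids)
    members = {
        term: [g for g in genes if g in measured]
        for term, genes in annotation.term_members(namespace).items()
    }
    members = {t: gs for t, gs in members.items() if len(gs) >= min_genes}
    if not members:
        raise ValueError(
            f"zero GO classes survive filtering (namespace={namespace!r}, min_genes={min_genes})"
        )
    term_ids = sorted(members)
    annotated = set().union(*(members[t] for t in term_ids))
    keep = [g for g in expression.gene_ids if g in annotated]
    expr_out = ExpressionMatrix(keep, list(expression.condition_ids), expression.submatrix(keep))
    row = {g: i for i, g in enumerate(keep)}
    values = np.zeros((len(keep), len(term_ids)), dtype=np.int8)
    for j, term in enumerate(term_ids):
        for g in members[term]:
            values[row[g], j] = 1
    return MembershipMatrix(keep, term_ids, values), expr_out
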