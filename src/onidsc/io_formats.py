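"""Readers and writers for every on-disk artifact the pipeline touches.

All formats are plain text: Matrix Market (``.mtx``) with ``genes.tsv`` /
``barcodes.tsv`` sidecars or dense CSV for expression; two-column TSV for
gold standards and externally computed pseudotimes; four-column TSV for
ranked edge lists.  Every reader validates its result and raises
:class:`ValidationError` naming the offending record rather than silently
coercing.  Gene and cell identifiers are opaque, case-sensitive strings.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

__all__ = [
    "ValidationError",
    "ExpressionMatrix",
    "GoldStandard",
    "RankedEdgeList",
    "read_expression",
    "write_expression",
    "read_gold_standard",
    "read_edges",
    "write_edges",
    "read_gene_list",
    "read_pseudotime",
    "write_pseudotime",
]


class ValidationError(ValueError):
    """An on-disk artifact or in-memory container violates its contract."""


def _check_unique(ids, kind: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise ValidationError(f"duplicate {kind} id: {x!r}")
        seen.add(x)


@dataclass
class ExpressionMatrix:
    """A gene-by-cell matrix of nonnegative expression values.

    ``values`` is dense float64 with genes in rows.  ``normalized`` records
    whether values are in log(x+1) space; the lagged-regression stages
    require normalized input.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = list(self.gene_ids)
        self.cell_ids = list(self.cell_ids)
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-D matrix")
        n_genes, n_cells = self.values.shape
        if len(self.gene_ids) != n_genes:
            raise ValidationError(
                f"{len(self.gene_ids)} gene ids for {n_genes} rows"
            )
        if len(self.cell_ids) != n_cells:
            raise ValidationError(
                f"{len(self.cell_ids)} cell ids for {n_cells} columns"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.cell_ids, "cell")
        bad = ~np.isfinite(self.values)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"non-finite value at gene {self.gene_ids[i]!r}, "
                f"cell {self.cell_ids[j]!r}"
            )
        neg = self.values < 0
        if neg.any():
            i, j = np.argwhere(neg)[0]
            raise ValidationError(
                f"negative value {self.values[i, j]} at gene "
                f"{self.gene_ids[i]!r}, cell {self.cell_ids[j]!r}"
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene_id)]

    def subset_genes(self, keep: list[str]) -> "ExpressionMatrix":
        idx = [self.gene_ids.index(g) for g in keep]
        return ExpressionMatrix(
            self.values[idx], keep, self.cell_ids, self.normalized
        )

    def subset_cells(self, keep: list[str]) -> "ExpressionMatrix":
        idx = [self.cell_ids.index(c) for c in keep]
        return ExpressionMatrix(
            self.values[:, idx], self.gene_ids, keep, self.normalized
        )


@dataclass
class GoldStandard:
    """Directed regulator→target interactions treated as ground truth."""

    edges: set
    gene_universe: set | None = None

    def __post_init__(self) -> None:
        self.edges = {(str(r), str(t)) for r, t in self.edges}
        for r, t in self.edges:
            if r == t:
                raise ValidationError(f"self-loop in gold standard: {r!r}")
            if self.gene_universe is not None and (
                r not in self.gene_universe or t not in self.gene_universe
            ):
                raise ValidationError(
                    f"edge ({r!r}, {t!r}) outside gene universe"
                )

    def __len__(self) -> int:
        return len(self.edges)


@dataclass
class RankedEdgeList:
    """Scored, ranked directed predictions.

    ``records`` is an ordered list of ``(regulator, target, score, rank)``
    with dense ranks 1..m, non-increasing scores, and deterministic
    lexicographic tie-breaks on ``(regulator, target)``.
    """

    records: list = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        prev_score = None
        for i, (reg, tgt, score, rank) in enumerate(self.records):
            if reg == tgt:
                raise ValidationError(f"self-loop predicted: {reg!r}")
            if (reg, tgt) in seen:
                raise ValidationError(f"duplicate edge ({reg!r}, {tgt!r})")
            seen.add((reg, tgt))
            if rank != i + 1:
                raise ValidationError(
                    f"rank {rank} at position {i}; ranks must be dense 1..m"
                )
            if score < 0 or not np.isfinite(score):
                raise ValidationError(f"bad score {score} for ({reg}, {tgt})")
            if prev_score is not None and score > prev_score + 1e-12:
                raise ValidationError("scores must be non-increasing in rank")
            prev_score = score

    @classmethod
    def from_scores(cls, scored_edges) -> "RankedEdgeList":
        """Build a valid list from ``(regulator, target, score)`` triples.

        Sorts by descending score, breaking ties lexicographically, and
        assigns dense ranks.
        """
        items = sorted(scored_edges, key=lambda e: (-e[2], e[0], e[1]))
        return cls(
            [(r, t, float(s), i + 1) for i, (r, t, s) in enumerate(items)]
        )

    def edges(self) -> list:
        return [(r, t) for r, t, _, _ in self.records]

    def top(self, k: int) -> "RankedEdgeList":
        return RankedEdgeList(self.records[:k])

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# expression matrices


def read_expression(path, format=None, orientation="genes") -> ExpressionMatrix:
    """Read an expression matrix from MTX (+sidecars) or dense CSV.

    Parameters
    ----------
    path
        For ``mtx``, the Matrix Market file; ``genes.tsv`` and
        ``barcodes.tsv`` must sit alongside it.  For ``csv``, a dense file
        with gene ids in the first column and cell ids in the header.
    format
        ``"mtx"`` or ``"csv"``; inferred from the suffix when omitted.
    orientation
        ``"genes"`` (genes in rows on disk, the default) or ``"cells"``.
        When the sidecar lengths disambiguate a transposed MTX file, the
        orientation is auto-corrected.
    """
    path = os.fspath(path)
    if format is None:
        format = "mtx" if path.endswith(".mtx") else "csv"
    if format == "mtx":
        return _read_mtx(path, orientation)
    if format == "csv":
        df = pd.read_csv(path, index_col=0)
        return ExpressionMatrix(
            df.to_numpy(dtype=float),
            [str(g) for g in df.index],
            [str(c) for c in df.columns],
        )
    raise ValueError(f"unknown expression format: {format!r}")


def _read_sidecar(path: str) -> list[str]:
    if not os.path.exists(path):
        raise ValidationError(f"missing sidecar file: {path}")
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            out.append(line.split("\t")[0])
    return out


def _read_mtx(path: str, orientation: str) -> ExpressionMatrix:
    d = os.path.dirname(path) or "."
    genes = _read_sidecar(os.path.join(d, "genes.tsv"))
    cells = _read_sidecar(os.path.join(d, "barcodes.tsv"))
    mat = scipy.io.mmread(path)
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    mat = np.asarray(mat, dtype=float)
    shape = mat.shape
    if shape == (len(genes), len(cells)) and shape != (len(cells), len(genes)):
        pass
    elif shape == (len(cells), len(genes)) and shape != (
        len(genes),
        len(cells),
    ):
        mat = mat.T
    elif orientation == "cells":
        mat = mat.T
    if mat.shape != (len(genes), len(cells)):
        raise ValidationError(
            f"matrix shape {shape} incompatible with {len(genes)} genes "
            f"and {len(cells)} barcodes"
        )
    return ExpressionMatrix(mat, genes, cells)


def write_expression(X: ExpressionMatrix, path, format="mtx") -> None:
    """Write to MTX with sidecars (directory inferred from ``path``) or CSV."""
    path = os.fspath(path)
    if format == "mtx":
        d = os.path.dirname(path) or "."
        os.makedirs(d, exist_ok=True)
        scipy.io.mmwrite(path, scipy.sparse.coo_matrix(X.values))
        with open(os.path.join(d, "genes.tsv"), "w") as fh:
            fh.write("".join(g + "\n" for g in X.gene_ids))
        with open(os.path.join(d, "barcodes.tsv"), "w") as fh:
            fh.write("".join(c + "\n" for c in X.cell_ids))
    elif format == "csv":
        pd.DataFrame(X.values, index=X.gene_ids, columns=X.cell_ids).to_csv(
            path
        )
    else:
        raise ValueError(f"unknown expression format: {format!r}")


# ---------------------------------------------------------------------------
# gold standards and edge lists


def read_gold_standard(path, gene_universe=None) -> GoldStandard:
    """Read a two-column regulator/target TSV into a :class:`GoldStandard`.

    Duplicate pairs are collapsed and self-loops dropped; when
    ``gene_universe`` is given, edges with an endpoint outside it are
    dropped too.  Each category of dropped rows is logged.  An empty result
    is an error because downstream evaluation would be undefined.
    """
    rows = []
    with open(os.fspath(path)) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValidationError(f"expected two columns, got: {line!r}")
            rows.append((parts[0], parts[1]))
    if rows and rows[0] == ("regulator", "target"):
        rows = rows[1:]
    edges, n_dup, n_self, n_out = set(), 0, 0, 0
    for r, t in rows:
        if r == t:
            n_self += 1
            continue
        if gene_universe is not None and (
            r not in gene_universe or t not in gene_universe
        ):
            n_out += 1
            continue
        if (r, t) in edges:
            n_dup += 1
            continue
        edges.add((r, t))
    if n_dup or n_self or n_out:
        logger.info(
            "gold standard %s: dropped %d duplicates, %d self-loops, "
            "%d edges outside universe",
            path,
            n_dup,
            n_self,
            n_out,
        )
    if not edges:
        raise ValidationError(f"gold standard {path} is empty after filtering")
    universe = set(gene_universe) if gene_universe is not None else None
    return GoldStandard(edges, universe)


def write_edges(edges: RankedEdgeList, path, header_comment=None) -> None:
    """Write a ranked edge list as TSV with 12 significant digits."""
    with open(os.fspath(path), "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write("regulator\ttarget\tscore\trank\n")
        for r, t, s, k in edges.records:
            fh.write(f"{r}\t{t}\t{s:.12g}\t{k}\n")


def read_edges(path) -> RankedEdgeList:
    records = []
    with open(os.fspath(path)) as fh:
        header = None
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if header is None:
                header = line.split("\t")
                if header[:2] != ["regulator", "target"]:
                    raise ValidationError(
                        f"unexpected edge-list header: {header}"
                    )
                continue
            r, t, s, k = line.split("\t")
            records.append((r, t, float(s), int(k)))
    return RankedEdgeList(records)


# ---------------------------------------------------------------------------
# gene lists and pseudotime


def read_gene_list(path) -> list[str]:
    """Read one gene symbol per line; ``#`` comments allowed.

    Order is preserved; duplicates are removed with a warning.  An empty
    list is an error.
    """
    out, seen = [], set()
    with open(os.fspath(path)) as fh:
        for line in fh:
            sym = line.strip()
            if not sym or sym.startswith("#"):
                continue
            if sym in seen:
                logger.warning("duplicate gene %r in %s; keeping first", sym, path)
                continue
            seen.add(sym)
            out.append(sym)
    if not out:
        raise ValidationError(f"gene list {path} is empty")
    return out


def read_pseudotime(path):
    """Read an externally computed (cell_id, pseudotime) TSV.

    Returns a :class:`~onidsc.preprocess.PseudotimeOrdering` with source
    ``"external"``; cells are re-sorted ascending by pseudotime with ties
    broken by cell id, matching the ordering contract.
    """
    from .preprocess import PseudotimeOrdering

    cells, times = [], []
    with open(os.fspath(path)) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "cell_id":
                continue
            cells.append(parts[0])
            times.append(float(parts[1]))
    if not cells:
        raise ValidationError(f"pseudotime file {path} is empty")
    order = sorted(range(len(cells)), key=lambda i: (times[i], cells[i]))
    return PseudotimeOrdering(
        cell_ids=[cells[i] for i in order],
        pseudotime=np.array([times[i] for i in order]),
        source="external",
    )


def write_pseudotime(ordering, path, header_comment=None) -> None:
    with open(os.fspath(path), "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write("cell_id\tpseudotime\n")
        for c, t in zip(ordering.cell_ids, ordering.pseudotime):
            fh.write(f"{c}\t{t:.12g}\n")
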