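"""Normalization, gene filtering, cell typing and marker-sum pseudotime.

The ordering strategy is deliberately supervised: rather than deriving a
cell order from all genes in an unsupervised manner, cells are ordered by
the summed normalized expression of a user-supplied marker panel (for
immune activation, the type I/II interferon-stimulated genes).  The sum is
the pseudotime; higher marker activity means later pseudotime by default.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "PseudotimeOrdering",
    "CellTypeAssignment",
    "log1p_normalize",
    "filter_genes",
    "assign_cell_types",
    "marker_pseudotime",
]


@dataclass
class PseudotimeOrdering:
    """A total order of cells with numeric pseudotimes.

    ``pseudotime`` is sorted ascending and aligned to ``cell_ids``; ties in
    pseudotime are broken by lexicographic cell id so the order is
    deterministic.
    """

    cell_ids: list[str]
    pseudotime: np.ndarray
    source: str = "marker_sum"

    def __post_init__(self) -> None:
        self.cell_ids = list(self.cell_ids)
        self.pseudotime = np.asarray(self.pseudotime, dtype=float)
        if len(self.cell_ids) != len(self.pseudotime):
            raise ValidationError("cell_ids and pseudotime lengths differ")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValidationError("duplicate cell ids in ordering")
        if not np.all(np.isfinite(self.pseudotime)):
            raise ValidationError("non-finite pseudotime")
        if np.any(np.diff(self.pseudotime) < 0):
            raise ValidationError("pseudotime must be non-decreasing")
        for i in range(len(self.cell_ids) - 1):
            if (
                self.pseudotime[i] == self.pseudotime[i + 1]
                and self.cell_ids[i] > self.cell_ids[i + 1]
            ):
                raise ValidationError(
                    "tied pseudotimes must be ordered by cell id"
                )

    def __len__(self) -> int:
        return len(self.cell_ids)

    def times_for(self, cell_ids) -> np.ndarray:
        lookup = dict(zip(self.cell_ids, self.pseudotime))
        return np.array([lookup[c] for c in cell_ids])

    def rank_time(self) -> "PseudotimeOrdering":
        """Replace pseudotime values by ranks 1..n (uniform spacing)."""
        return PseudotimeOrdering(
            self.cell_ids,
            np.arange(1, len(self.cell_ids) + 1, dtype=float),
            self.source,
        )


@dataclass
class CellTypeAssignment:
    assignments: dict
    exclusion_log: list = field(default_factory=list)


def log1p_normalize(X: ExpressionMatrix, base: float | str = "e") -> ExpressionMatrix:
    """Replace each value v by log(v + 1) to reduce skewness.

    Natural log by default (the dominant single-cell convention); pass
    ``base=2`` or ``base=10`` to override.  Zeros stay zeros.  Normalizing
    an already-normalized matrix is an error.
    """
    if X.normalized:
        raise ValidationError("matrix is already log-normalized")
    vals = np.log1p(X.values)
    if base != "e":
        vals = vals / math.log(float(base))
    return ExpressionMatrix(vals, X.gene_ids, X.cell_ids, normalized=True)


def filter_genes(
    X: ExpressionMatrix,
    min_nonzero: int = 4,
    min_unique: int = 5,
    drop_constant: bool = True,
):
    """Remove genes unsuitable for penalized regression and cross-validation.

    Rules (a gene is dropped on the first rule it violates):

    * fewer than ``min_nonzero`` nonzero values;
    * constant expression (zero standard deviation), which would break
      standardization;
    * fewer than ``min_unique`` distinct values, which the ten-fold
      cross-validation of the response requires.

    Returns the filtered matrix and a report DataFrame with columns
    ``gene_id`` and ``rule``.  Idempotent: a second application drops
    nothing.  Dropping every gene is an error.
    """
    dropped = []
    keep = []
    for i, g in enumerate(X.gene_ids):
        row = X.values[i]
        if int(np.count_nonzero(row)) < min_nonzero:
            dropped.append((g, "min_nonzero"))
        elif drop_constant and np.all(row == row[0]):
            dropped.append((g, "constant"))
        elif len(np.unique(row)) < min_unique:
            dropped.append((g, "min_unique"))
        else:
            keep.append(g)
    if not keep:
        raise ValidationError("all genes removed by filtering")
    report = pd.DataFrame(dropped, columns=["gene_id", "rule"])
    if len(dropped):
        logger.info("filter_genes dropped %d of %d genes", len(dropped), X.n_genes)
    return X.subset_genes(keep), report


def assign_cell_types(memberships: dict, rules) -> CellTypeAssignment:
    """Apply ordered pairwise-exclusion rules to per-type cell sets.

    Each rule is ``(type_a, type_b, drop_from)`` with ``drop_from`` in
    ``{"both", "a", "b"}``: cells in the current intersection of the two
    types are removed from the indicated side(s).  Every removal is
    recorded in the exclusion log as ``(cell_id, removed_from, reason)``.
    """
    out = {t: set(cells) for t, cells in memberships.items()}
    log = []
    for type_a, type_b, drop_from in rules:
        if type_a not in out or type_b not in out:
            unknown = type_a if type_a not in out else type_b
            raise ValidationError(f"rule references unknown cell type {unknown!r}")
        if drop_from not in ("both", "a", "b"):
            raise ValidationError(f"bad drop_from {drop_from!r}")
        overlap = out[type_a] & out[type_b]
        reason = f"intersection {type_a}/{type_b} (drop {drop_from})"
        for cell in sorted(overlap):
            if drop_from in ("both", "a"):
                out[type_a].discard(cell)
                log.append((cell, type_a, reason))
            if drop_from in ("both", "b"):
                out[type_b].discard(cell)
                log.append((cell, type_b, reason))
    return CellTypeAssignment(out, log)


def marker_pseudotime(
    X_norm: ExpressionMatrix, markers, descending: bool = False
) -> PseudotimeOrdering:
    """Order cells by the sum of normalized marker-gene expression.

    The per-cell score is the sum over markers found in the matrix; cells
    are sorted ascending by score (use ``descending=True`` to invert) and
    the scores themselves are the pseudotime values.  Markers missing from
    the matrix are skipped with a warning; finding none is an error.
    """
    if not X_norm.normalized:
        raise ValidationError("marker_pseudotime requires log-normalized input")
    found = [m for m in markers if m in X_norm.gene_ids]
    missing = [m for m in markers if m not in X_norm.gene_ids]
    if missing:
        logger.warning("markers absent from matrix, skipped: %s", missing)
    if not found:
        raise ValidationError("no marker genes found in the matrix")
    idx = [X_norm.gene_ids.index(m) for m in found]
    scores = X_norm.values[idx].sum(axis=0)
    if descending:
        # inverted direction: pseudotime is the negated sum so it still
        # increases along the inferred order
        scores = -scores
    order = sorted(
        range(X_norm.n_cells), key=lambda i: (scores[i], X_norm.cell_ids[i])
    )
    return PseudotimeOrdering(
        cell_ids=[X_norm.cell_ids[i] for i in order],
        pseudotime=scores[order],
        source="marker_sum",
    )
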