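"""Synthetic pseudotemporal expression with planted regulatory edges.

The generator is the test substrate for the whole pipeline.  It emulates
the features the method relies on — cells ordered along a process, marker
genes monotone in that order, targets driven by lagged regulator
expression, dropout zeros — while remaining simple enough that ground
truth is exact:

* cells sit at integer pseudotimes 1..n;
* background genes are independent half-normal noise, |N(0, 1)|;
* marker genes increase strictly with pseudotime (slope differing per
  marker) plus N(0, noise_sd) jitter;
* each planted edge (regulator -> target, coefficient c, lag l) makes the
  target's value at time t equal sum of c * regulator(t - l) plus noise,
  so with zero noise the lagged linear relation is exact;
* values are clipped at zero and dropout sets entries to zero
  independently with the configured probability.

Values are continuous and nonnegative rather than integer counts: the
inference stages operate post-normalization and gain nothing from count
noise.  Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import ExpressionMatrix, GoldStandard, ValidationError
from .preprocess import PseudotimeOrdering

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_network_expression",
    "inject_dropout",
]


@dataclass
class SimulationConfig:
    """Settings of one simulated dataset.

    ``planted_edges`` is a list of (regulator_index, target_index,
    coefficient, lag) tuples over non-marker gene indices; markers occupy
    the last ``marker_gene_count`` indices.
    """

    n_cells: int = 300
    n_genes: int = 10
    planted_edges: list = field(default_factory=list)
    marker_gene_count: int = 0
    noise_sd: float = 0.05
    dropout_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 2 or self.n_genes < 1:
            raise ValidationError("need n_cells >= 2 and n_genes >= 1")
        if not 0 <= self.marker_gene_count <= self.n_genes:
            raise ValidationError("marker_gene_count out of range")
        if not 0.0 <= self.dropout_prob <= 1.0:
            raise ValidationError("dropout_prob must be in [0, 1]")
        n_regular = self.n_genes - self.marker_gene_count
        for reg, tgt, coef, lag in self.planted_edges:
            if not (0 <= reg < n_regular and 0 <= tgt < n_regular):
                raise ValidationError(
                    f"planted edge ({reg}, {tgt}) references a marker or "
                    "out-of-range gene"
                )
            if reg == tgt:
                raise ValidationError("planted self-loop")
            if not np.isfinite(coef):
                raise ValidationError("non-finite planted coefficient")
            if not 1 <= lag < self.n_cells:
                raise ValidationError(
                    f"lag {lag} must be in 1..{self.n_cells - 1}"
                )


@dataclass
class SimulatedDataset:
    matrix: ExpressionMatrix
    true_order: PseudotimeOrdering
    truth: GoldStandard
    marker_genes: list


def simulate_network_expression(config: SimulationConfig) -> SimulatedDataset:
    """Generate expression, the true cell order, and the planted edges."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    n, G = config.n_cells, config.n_genes
    n_regular = G - config.marker_gene_count
    gene_ids = [f"g{i:03d}" for i in range(G)]
    cell_ids = [f"c{i:04d}" for i in range(n)]
    t = np.arange(1, n + 1, dtype=float)

    values = np.abs(rng.normal(0.0, 1.0, size=(G, n)))
    # markers: strictly increasing base plus jitter, distinct slopes
    for j in range(config.marker_gene_count):
        gi = n_regular + j
        base = (1.0 + 0.5 * j) * t / n
        values[gi] = base + rng.normal(0.0, config.noise_sd, size=n)
    # planted lagged effects overwrite the target rows
    targets = sorted({tgt for _, tgt, _, _ in config.planted_edges})
    for tgt in targets:
        row = rng.normal(0.0, config.noise_sd, size=n)
        if config.noise_sd == 0:
            row = np.zeros(n)
        for reg, tgt2, coef, lag in config.planted_edges:
            if tgt2 != tgt:
                continue
            row[lag:] = row[lag:] + coef * values[reg, :-lag]
        values[tgt] = row
    values = np.clip(values, 0.0, None)

    X = ExpressionMatrix(values, gene_ids, cell_ids, normalized=False)
    if config.dropout_prob > 0:
        X = inject_dropout(X, config.dropout_prob, rng)
    truth = GoldStandard(
        {
            (gene_ids[reg], gene_ids[tgt])
            for reg, tgt, _, _ in config.planted_edges
        }
        or set(),
        gene_universe=set(gene_ids),
    ) if config.planted_edges else GoldStandard(set(), set(gene_ids))
    order = PseudotimeOrdering(cell_ids, t, source="external")
    markers = gene_ids[n_regular:]
    return SimulatedDataset(X, order, truth, markers)


def inject_dropout(X: ExpressionMatrix, p: float, rng) -> ExpressionMatrix:
    """Set each entry to zero independently with probability ``p``."""
    if not 0.0 <= p <= 1.0:
        raise ValidationError("dropout probability must be in [0, 1]")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    keep = rng.random(X.values.shape) >= p
    return ExpressionMatrix(
        X.values * keep, X.gene_ids, X.cell_ids, X.normalized
    )
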