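"""Kernel-smoothed lagged lasso Granger network inference over an ensemble.

Cells ordered in pseudotime form an irregularly sampled "time" series per
gene.  For a target gene, each candidate regulator contributes L lagged
features: the feature for lag l at target observation time t_i is a
Gaussian-kernel weighted average of the regulator's samples, centered at
t_i - l*dt and restricted to samples strictly in the past of t_i (the
causal direction).  The target's own lags enter as covariates and are
discarded from the output, so a regulator is credited only for predictive
power beyond the target's autoregression — the Granger criterion.  A lasso
fit at a single cross-validated penalty selects regulators; the edge
weight is the sum of absolute coefficients over lags.

Dropout zeros are mitigated by removing each zero-valued sample (and its
pseudotime) with a configurable probability before smoothing; technical
replicas repeat inference with independent zero-removal draws.  Each
ensemble instance — one (time resolution, lag count) pair x kernel width x
replica — yields an adjacency matrix whose nonzero weights are ranked; a
modified Borda count (score = sum of 1/rank over instances, 0 where an
edge is absent) aggregates the instance rankings into one ranked edge
list.  Zero-removal RNG streams are keyed by (seed, instance settings,
gene index), so results do not depend on scheduling or on the order in
which hyperparameter combinations are listed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from joblib import Parallel, delayed
from scipy.stats import rankdata

from .io_formats import ExpressionMatrix, RankedEdgeList, ValidationError
from .lasso_opt import ConvergenceError, LassoProblem, fit_lasso_cd
from .preprocess import PseudotimeOrdering

logger = logging.getLogger(__name__)

__all__ = [
    "GLGHyperparams",
    "EnsembleSpec",
    "AdjacencyMatrix",
    "apply_zero_removal",
    "smooth_lagged_design",
    "fit_target_glg",
    "infer_network",
    "borda_aggregate",
]


@dataclass
class GLGHyperparams:
    """Settings of one GLG instance.

    lam: lasso penalty (the single optimized value).
    dt: pseudotime resolution between successive lags.
    num_lags: number of lagged features L per candidate regulator.
    sigma: Gaussian kernel width, in pseudotime units.
    zero_handling: integer code; only 0 (no handling beyond probabilistic
        removal) is implemented, other codes are rejected.
    prob_zero_removal: probability of dropping each zero-valued sample.
    replicas: technical replicas differing only in zero-removal draws.
    seed: base seed for all RNG streams.
    """

    lam: float
    dt: float = 1.0
    num_lags: int = 2
    sigma: float = 1.0
    zero_handling: int = 0
    prob_zero_removal: float = 0.0
    replicas: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValidationError("lambda must be nonnegative")
        if self.dt <= 0 or self.sigma <= 0:
            raise ValidationError("dt and sigma must be positive")
        if self.num_lags < 1 or self.replicas < 1:
            raise ValidationError("num_lags and replicas must be >= 1")
        if not 0.0 <= self.prob_zero_removal <= 1.0:
            raise ValidationError("prob_zero_removal must be in [0, 1]")
        if self.zero_handling != 0:
            raise ValidationError(
                f"zero_handling code {self.zero_handling} is not implemented"
            )


@dataclass
class EnsembleSpec:
    """The ensemble: (dt, L) pairs x kernel widths x replicas, one lambda."""

    lam: float
    dt_lag_pairs: list = field(default_factory=lambda: [(1.0, 2)])
    sigmas: list = field(default_factory=lambda: [1.0])
    prob_zero_removal: float = 0.2
    replicas: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.dt_lag_pairs or not self.sigmas:
            raise ValidationError("dt_lag_pairs and sigmas must be nonempty")

    def instances(self):
        for dt, num_lags in self.dt_lag_pairs:
            for sigma in self.sigmas:
                for rep in range(self.replicas):
                    yield GLGHyperparams(
                        lam=self.lam,
                        dt=float(dt),
                        num_lags=int(num_lags),
                        sigma=float(sigma),
                        prob_zero_removal=self.prob_zero_removal,
                        replicas=1,
                        seed=self.seed,
                    ), rep


@dataclass
class AdjacencyMatrix:
    """Regulator-by-target nonnegative weights with a zero diagonal."""

    weights: np.ndarray
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        G = len(self.gene_ids)
        if self.weights.shape != (G, G):
            raise ValidationError("adjacency must be gene x gene")
        if not np.all(np.isfinite(self.weights)) or np.any(self.weights < 0):
            raise ValidationError("weights must be finite and nonnegative")
        if np.any(np.diag(self.weights) != 0):
            raise ValidationError("self-edges are not allowed")

    def ranked_nonzero(self):
        """Nonzero entries as (regulator, target, weight), ranked descending.

        Within-matrix weight ties receive the mean of the tied rank
        positions (resolved later by the aggregator's deterministic sort).
        """
        ri, ci = np.nonzero(self.weights)
        w = self.weights[ri, ci]
        return [
            (self.gene_ids[i], self.gene_ids[j], float(x))
            for i, j, x in zip(ri, ci, w)
        ]


def _instance_rng(seed: int, hyper: GLGHyperparams, replica: int, gene_index: int):
    """RNG keyed by instance content so execution order is irrelevant."""
    key = (
        int(round(hyper.dt * 1e9)),
        hyper.num_lags,
        int(round(hyper.sigma * 1e9)),
        replica,
        gene_index,
    )
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=key)
    )


def apply_zero_removal(values, pseudotimes, p_z: float, rng):
    """Drop each zero-valued sample (with its pseudotime) w.p. ``p_z``.

    Nonzero samples are always kept and order is preserved.  An empty
    result is allowed and handled downstream.
    """
    if not 0.0 <= p_z <= 1.0:
        raise ValidationError("p_z must be in [0, 1]")
    values = np.asarray(values, dtype=float)
    pseudotimes = np.asarray(pseudotimes, dtype=float)
    if values.shape != pseudotimes.shape:
        raise ValidationError("values and pseudotimes must align")
    draws = rng.random(len(values))  # one draw per sample keeps streams aligned
    keep = (values != 0) | (draws >= p_z)
    return values[keep], pseudotimes[keep]


def smooth_lagged_design(
    reg_values, reg_times, target_times, lag: int, dt: float, sigma: float
) -> np.ndarray:
    """Kernel-smoothed lagged regulator feature at each target time.

    feature(t_i) = sum_k K((t_k - (t_i - lag*dt)) / sigma) * x(t_k)
                   / sum_k K(...),
    with Gaussian K and the sum restricted to regulator samples strictly
    before t_i.  Entries with no past sample are NaN (unusable rows).  When
    every kernel weight underflows but past samples exist, the sample
    nearest the lag center is used (the delta-kernel limit).
    """
    if sigma <= 0 or dt <= 0:
        raise ValidationError("sigma and dt must be positive")
    reg_values = np.asarray(reg_values, dtype=float)
    reg_times = np.asarray(reg_times, dtype=float)
    target_times = np.asarray(target_times, dtype=float)
    if len(reg_values) == 0:
        return np.full(len(target_times), np.nan)
    centers = target_times - lag * dt
    D = centers[:, None] - reg_times[None, :]
    past = reg_times[None, :] < target_times[:, None]
    K = np.exp(-0.5 * (D / sigma) ** 2) * past
    denom = K.sum(axis=1)
    out = np.full(len(target_times), np.nan)
    ok = denom > 0
    out[ok] = (K[ok] @ reg_values) / denom[ok]
    # underflow fallback: nearest past sample to the lag center
    fallback = (~ok) & past.any(axis=1)
    for i in np.nonzero(fallback)[0]:
        cand = np.nonzero(past[i])[0]
        out[i] = reg_values[cand[np.argmin(np.abs(D[i, cand]))]]
    return out


def _fit_target(series, gene_ids, target, hyper: GLGHyperparams):
    """Lasso fit of one target on all genes' lagged features.

    ``series`` maps gene id -> (values, pseudotimes) after zero removal.
    Returns a dict regulator -> weight (sum of |coef| over lags, self
    excluded), or None when too few usable rows remain.
    """
    t_vals, t_times = series[target]
    L = hyper.num_lags
    n = len(t_vals)
    if n == 0:
        logger.warning("target %s: no samples left after zero removal", target)
        return None
    cols = []
    col_meta = []
    for g in gene_ids:
        g_vals, g_times = series[g]
        for lag in range(1, L + 1):
            cols.append(
                smooth_lagged_design(
                    g_vals, g_times, t_times, lag, hyper.dt, hyper.sigma
                )
            )
            col_meta.append(g)
    design = np.column_stack(cols)
    usable = ~np.isnan(design).any(axis=1)
    if usable.sum() < L + 2:
        logger.warning(
            "target %s skipped: %d usable rows (< %d)",
            target,
            int(usable.sum()),
            L + 2,
        )
        return None
    y = t_vals[usable]
    Xd = design[usable]
    if np.all(y == y[0]):
        # constant response carries no signal: no incoming edges
        return {g: 0.0 for g in gene_ids if g != target}
    problem = LassoProblem(Xd, y, alpha=1.0, standardize=True)
    try:
        fit = fit_lasso_cd(problem, hyper.lam)
    except ConvergenceError as exc:
        logger.warning("target %s skipped: %s", target, exc)
        return None
    weights: dict[str, float] = {}
    for g, coef in zip(col_meta, fit.coefficients):
        weights[g] = weights.get(g, 0.0) + abs(float(coef))
    weights.pop(target, None)
    return weights


def fit_target_glg(
    X: ExpressionMatrix,
    ordering: PseudotimeOrdering,
    target: str,
    hyper: GLGHyperparams,
    replica: int = 0,
):
    """Incoming edge weights for one target under one hyperparameter set.

    Zero removal uses per-gene RNG streams derived from the instance
    settings and ``replica``, so a standalone call reproduces the
    corresponding ensemble member.  Returns a dict regulator -> weight or
    None when the target is skipped.
    """
    series = _filtered_series(X, ordering, hyper, replica)
    return _fit_target(series, X.gene_ids, target, hyper)


def _filtered_series(X, ordering, hyper, replica):
    times = ordering.times_for(X.cell_ids)
    order = np.argsort(times, kind="stable")
    series = {}
    for gi, g in enumerate(X.gene_ids):
        vals = X.values[gi][order]
        ts = times[order]
        if hyper.prob_zero_removal > 0:
            rng = _instance_rng(hyper.seed, hyper, replica, gi)
            vals, ts = apply_zero_removal(vals, ts, hyper.prob_zero_removal, rng)
        series[g] = (vals, ts)
    return series


def _instance_adjacency(X, ordering, hyper, replica, n_jobs=1):
    series = _filtered_series(X, ordering, hyper, replica)
    gene_ids = X.gene_ids
    if n_jobs == 1:
        results = [
            _fit_target(series, gene_ids, target, hyper) for target in gene_ids
        ]
    else:
        results = Parallel(n_jobs=n_jobs)(
            delayed(_fit_target)(series, gene_ids, target, hyper)
            for target in gene_ids
        )
    G = len(gene_ids)
    W = np.zeros((G, G))
    any_fit = False
    for tj, weights in enumerate(results):
        if weights is None:
            continue
        any_fit = True
        for g, w in weights.items():
            W[gene_ids.index(g), tj] = w
    if not any_fit:
        return None
    return AdjacencyMatrix(W, gene_ids)


def infer_network(
    X: ExpressionMatrix,
    ordering: PseudotimeOrdering,
    spec: EnsembleSpec,
    n_jobs: int = 1,
) -> RankedEdgeList:
    """Run the full GLG ensemble and aggregate instance rankings.

    One adjacency matrix per (dt, L) x sigma x replica; results are fully
    determined by (X, ordering, spec) including the seed, and identical
    for any ``n_jobs``.
    """
    rankings = []
    for hyper, replica in spec.instances():
        adj = _instance_adjacency(X, ordering, hyper, replica, n_jobs=n_jobs)
        if adj is None:
            logger.warning(
                "instance (dt=%s, L=%d, sigma=%s, rep=%d) produced no fits",
                hyper.dt,
                hyper.num_lags,
                hyper.sigma,
                replica,
            )
            continue
        ranked = adj.ranked_nonzero()
        if ranked:
            rankings.append(ranked)
    if not rankings:
        raise ValidationError("every ensemble instance skipped every target")
    return borda_aggregate(rankings)


def borda_aggregate(rankings) -> RankedEdgeList:
    """Modified Borda count over instance rankings.

    Each ranking is a list of (regulator, target, score) for one instance's
    nonzero edges.  Within a ranking, ranks are computed from descending
    scores with ties taking the mean of the tied positions; an edge scores
    1/rank in each ranking where it appears and 0 elsewhere.  The aggregate
    list is ordered by total score, ties broken lexicographically.
    """
    rankings = list(rankings)
    if not rankings:
        raise ValidationError("no rankings to aggregate")
    contributions: dict[tuple, list] = {}
    for ranked in rankings:
        if not ranked:
            continue
        pairs = [(r, t) for r, t, _ in ranked]
        if len(set(pairs)) != len(pairs):
            raise ValidationError("duplicate edge within one ranking")
        scores = np.array([s for _, _, s in ranked], dtype=float)
        ranks = rankdata(-scores, method="average")
        for (r, t), rk in zip(pairs, ranks):
            contributions.setdefault((r, t), []).append(1.0 / rk)
    # fsum is exact, so aggregate scores do not depend on instance order
    return RankedEdgeList.from_scores(
        (r, t, math.fsum(c)) for (r, t), c in contributions.items()
    )
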