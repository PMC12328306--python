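"""Penalized regression via cyclical coordinate descent with CV-chosen penalty.

This module is the optimization core of the package.  It solves the
elastic-net problem for the Gaussian family,

    min_{b0, b}  (1/2N) sum_i w_i (y_i - b0 - x_i'b)^2
                 + lambda [ (1-alpha)/2 ||b||_2^2 + alpha ||b||_1 ],

by cyclical coordinate descent: each coordinate update is a closed-form
soft-thresholding step

    b_j <- S( (1/N) sum_i w_i x_ij (y_i - b0 - sum_{l!=j} x_il b_l), lambda*alpha )
           / ( v_j + lambda*(1-alpha) ),

where S(z, g) = sign(z) (|z| - g)_+ and v_j is the (weighted) mean square of
predictor j (1 after standardization).  With alpha = 1 this is the lasso,
the configuration used throughout the network-inference pipeline.

On top of the solver sit k-fold cross-validation over a geometric lambda
path (``lambda_min`` = CV-MSE minimizer, ``lambda_1se`` = largest lambda
within one standard error of that minimum), a per-gene scan that regresses
each gene on all others over a shared grid so that modal lambdas are well
defined, and the selection of a single common lambda across data subsets.

Implementation notes: the solver works on centered (optionally
standardized) data using precomputed Gram products, so one coordinate
update costs O(p) regardless of N, and paths are fitted warm-starting from
the previous lambda.  Zero-variance predictors receive coefficient 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "LassoProblem",
    "LassoFit",
    "CVResult",
    "LambdaSummary",
    "ConvergenceError",
    "soft_threshold",
    "fit_lasso_cd",
    "make_lambda_path",
    "cross_validate_lambda",
    "scan_genes_lambda",
    "select_common_lambda",
]


class ConvergenceError(RuntimeError):
    """Coordinate descent did not converge; ``.fit`` holds the last iterate."""

    def __init__(self, message: str, fit=None):
        super().__init__(message)
        self.fit = fit


@dataclass
class LassoProblem:
    """One penalized-regression problem: predictors, response, weights."""

    predictors: np.ndarray
    response: np.ndarray
    obs_weights: np.ndarray | None = None
    alpha: float = 1.0
    standardize: bool = True

    def __post_init__(self) -> None:
        self.predictors = np.asarray(self.predictors, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.predictors.ndim != 2:
            raise ValidationError("predictors must be 2-D")
        n, p = self.predictors.shape
        if n < 2 or p < 1:
            raise ValidationError(f"need N >= 2 and p >= 1, got N={n}, p={p}")
        if self.response.shape != (n,):
            raise ValidationError("response length must match predictor rows")
        if self.obs_weights is None:
            self.obs_weights = np.ones(n)
        self.obs_weights = np.asarray(self.obs_weights, dtype=float)
        if self.obs_weights.shape != (n,):
            raise ValidationError("weight length must match predictor rows")
        if not (
            np.all(np.isfinite(self.predictors))
            and np.all(np.isfinite(self.response))
            and np.all(np.isfinite(self.obs_weights))
        ):
            raise ValidationError("NaN or infinite values in problem data")
        if np.any(self.obs_weights < 0) or not np.any(self.obs_weights > 0):
            raise ValidationError("weights must be nonnegative, not all zero")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValidationError(f"alpha must be in [0, 1], got {self.alpha}")

    @property
    def n_obs(self) -> int:
        return self.predictors.shape[0]

    @property
    def n_predictors(self) -> int:
        return self.predictors.shape[1]


@dataclass
class LassoFit:
    """Solution of one lasso problem at a fixed penalty.

    ``objective`` (and ``objective_history`` when tracked) is evaluated on
    the internal centered/standardized problem, the space in which the
    coordinate updates run; for ``standardize=False`` this coincides with
    the original-scale objective.
    """

    intercept: float
    coefficients: np.ndarray
    lam: float
    n_iter: int
    objective: float
    objective_history: list = field(default_factory=list)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.intercept + np.asarray(X, dtype=float) @ self.coefficients


@dataclass
class CVResult:
    lambda_grid: np.ndarray
    mse_mean: np.ndarray
    mse_se: np.ndarray
    lambda_min: float
    lambda_1se: float
    fold_assignment_seed: int

    def __post_init__(self) -> None:
        if self.lambda_1se < self.lambda_min:
            raise ValidationError("lambda_1se must be >= lambda_min")


@dataclass
class LambdaSummary:
    """Per-gene CV penalties plus their modes on the shared grid."""

    per_gene: pd.DataFrame  # gene_id, lambda_min, lambda_1se, mse_at_min
    mode_min: float
    mode_max: float
    lambda_grid: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.mode_min > self.mode_max:
            raise ValidationError("mode_min must be <= mode_max")


def soft_threshold(z: float, gamma: float):
    """Soft-thresholding operator S(z, gamma) = sign(z) (|z| - gamma)_+."""
    if gamma < 0:
        raise ValueError("gamma must be nonnegative")
    return np.sign(z) * np.maximum(np.abs(z) - gamma, 0.0)


# ---------------------------------------------------------------------------
# internal solver machinery


def _prepare(problem: LassoProblem):
    """Center (and optionally scale) the problem; return Gram products.

    Returns a dict with the standardized design products G = Xs' V Xs and
    q = Xs' V yc (V = normalized weights summing to one), plus the pieces
    needed to map coefficients back to the original scale.
    """
    X, y, w = problem.predictors, problem.response, problem.obs_weights
    v = w / w.sum()
    xm = v @ X
    ym = float(v @ y)
    Xc = X - xm
    yc = y - ym
    xs = np.sqrt(v @ (Xc**2))
    degenerate = xs <= 0
    scale = np.where(degenerate, 1.0, xs) if problem.standardize else np.ones_like(xs)
    Xs = Xc / scale
    Vx = Xs * v[:, None]
    G = Xs.T @ Vx
    if not problem.standardize:
        # degenerate columns still need a harmless diagonal to divide by
        G[np.diag_indices_from(G)] = np.where(
            degenerate, 1.0, np.diag(G)
        )
    q = Vx.T @ yc
    q[degenerate] = 0.0
    yy = float(v @ yc**2)
    return {
        "G": G,
        "q": q,
        "yy": yy,
        "scale": scale,
        "xm": xm,
        "ym": ym,
        "degenerate": degenerate,
    }


def _internal_objective(b, G, q, yy, lam, alpha) -> float:
    quad = 0.5 * (yy - 2.0 * (q @ b) + b @ (G @ b))
    pen = lam * ((1 - alpha) / 2 * (b @ b) + alpha * np.abs(b).sum())
    return float(quad + pen)


def _cd_solve(G, q, lam, alpha, b, tol, max_iter, yy=None, track=False):
    """Cyclical coordinate descent on precomputed Gram products.

    Mutates and returns ``b``.  ``Gb`` (= G @ b) is maintained
    incrementally so each coordinate update is O(p) and free for inactive
    zero coordinates.
    """
    p = len(b)
    gamma = lam * alpha
    ridge = lam * (1 - alpha)
    diag = np.diag(G).copy()
    Gb = G @ b
    history = []
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        max_delta = 0.0
        for j in range(p):
            bj = b[j]
            zj = q[j] - Gb[j] + diag[j] * bj
            az = abs(zj) - gamma
            new = 0.0 if az <= 0.0 else np.copysign(az, zj) / (diag[j] + ridge)
            if new != bj:
                delta = new - bj
                b[j] = new
                Gb += G[:, j] * delta
                if abs(delta) > max_delta:
                    max_delta = abs(delta)
        if track:
            history.append(_internal_objective(b, G, q, yy, lam, alpha))
        if max_delta < tol:
            break
    else:
        return b, max_iter, history, False
    return b, n_iter, history, True


def fit_lasso_cd(
    problem: LassoProblem,
    lam: float,
    tol: float = 1e-7,
    max_iter: int = 100000,
    track_objective: bool = False,
) -> LassoFit:
    """Solve one lasso/elastic-net problem at penalty ``lam``.

    Coordinates are cycled until the largest coefficient change in a full
    cycle drops below ``tol``; the objective is non-increasing across
    cycles.  Coefficients are returned on the original predictor scale and
    the intercept is recovered from the weighted means.
    """
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    prep = _prepare(problem)
    p = problem.n_predictors
    b = np.zeros(p)
    b, n_iter, history, converged = _cd_solve(
        prep["G"],
        prep["q"],
        lam,
        problem.alpha,
        b,
        tol,
        max_iter,
        yy=prep["yy"],
        track=track_objective,
    )
    obj = _internal_objective(
        b, prep["G"], prep["q"], prep["yy"], lam, problem.alpha
    )
    coef = b / prep["scale"]
    intercept = prep["ym"] - float(prep["xm"] @ coef)
    fit = LassoFit(intercept, coef, lam, n_iter, obj, history)
    if not converged:
        raise ConvergenceError(
            f"coordinate descent did not converge in {max_iter} cycles "
            f"(lambda={lam})",
            fit=fit,
        )
    return fit


def _path_solve(prep, lambdas, alpha, tol, max_iter):
    """Warm-started fits along a descending lambda path (internal scale)."""
    p = len(prep["q"])
    B = np.zeros((len(lambdas), p))
    b = np.zeros(p)
    for i, lam in enumerate(lambdas):
        b, _, _, converged = _cd_solve(
            prep["G"], prep["q"], lam, alpha, b, tol, max_iter
        )
        if not converged:
            raise ConvergenceError(
                f"path fit did not converge at lambda={lam}"
            )
        B[i] = b
    return B


def make_lambda_path(
    problem: LassoProblem, n_lambda: int = 100, ratio: float | None = None
) -> np.ndarray:
    """Geometric lambda grid from lambda_max down to lambda_max * ratio.

    ``lambda_max`` is the smallest penalty at which every coefficient is
    zero, max_j |(1/N) sum_i w_i x_ij (y_i - ybar)| on the (standardized)
    predictors, divided by alpha.  ``ratio`` defaults to 1e-4 when N > p
    and 1e-2 otherwise, the usual path convention.
    """
    y = problem.response
    if np.all(y == y[0]):
        raise ValidationError("constant response: lambda_max is zero")
    prep = _prepare(problem)
    lam_max = float(np.max(np.abs(prep["q"]))) / max(problem.alpha, 1e-3)
    if lam_max <= 0:
        raise ValidationError(
            "lambda_max is zero (constant response or degenerate predictors)"
        )
    if ratio is None:
        ratio = 1e-4 if problem.n_obs > problem.n_predictors else 1e-2
    if n_lambda == 1:
        return np.array([lam_max])
    return lam_max * ratio ** (np.arange(n_lambda) / (n_lambda - 1))


def cross_validate_lambda(
    problem: LassoProblem,
    k: int = 10,
    seed: int = 0,
    lambda_grid: np.ndarray | None = None,
    n_lambda: int = 100,
    ratio: float | None = None,
    tol: float = 1e-7,
    max_iter: int = 100000,
) -> CVResult:
    """k-fold cross-validation of the penalty over a lambda path.

    Folds are assigned by a seeded shuffle into k near-equal blocks; for
    each grid lambda the held-out MSE is averaged over folds and its
    standard error computed as sd/sqrt(k).  ``lambda_min`` minimizes the
    mean CV MSE (largest such lambda on ties); ``lambda_1se`` is the
    largest grid lambda whose mean MSE is within one standard error of the
    minimum.  Identical inputs and seed give identical results.
    """
    n = problem.n_obs
    if n < k:
        raise ValidationError(f"need at least k={k} observations, got {n}")
    if lambda_grid is None:
        lambda_grid = make_lambda_path(problem, n_lambda, ratio)
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, k)
    mse = np.empty((k, len(lambda_grid)))
    for f, test_idx in enumerate(folds):
        if len(test_idx) < 2:
            raise ValidationError(
                f"fold {f} has {len(test_idx)} observations (< 2)"
            )
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        sub = LassoProblem(
            problem.predictors[train_mask],
            problem.response[train_mask],
            problem.obs_weights[train_mask],
            alpha=problem.alpha,
            standardize=problem.standardize,
        )
        prep = _prepare(sub)
        B = _path_solve(prep, lambda_grid, problem.alpha, tol, max_iter)
        coefs = B / prep["scale"]
        intercepts = prep["ym"] - coefs @ prep["xm"]
        Xt = problem.predictors[test_idx]
        yt = problem.response[test_idx]
        wt = problem.obs_weights[test_idx]
        pred = Xt @ coefs.T + intercepts  # (n_test, n_lambda)
        err = (pred - yt[:, None]) ** 2
        mse[f] = (wt @ err) / wt.sum()
    mse_mean = mse.mean(axis=0)
    mse_se = mse.std(axis=0, ddof=1) / np.sqrt(k)
    # grid is descending: argmin returns the first (largest) minimizer
    i_min = int(np.argmin(mse_mean))
    thresh = mse_mean[i_min] + mse_se[i_min]
    i_1se = int(np.nonzero(mse_mean <= thresh)[0][0])
    return CVResult(
        lambda_grid=lambda_grid,
        mse_mean=mse_mean,
        mse_se=mse_se,
        lambda_min=float(lambda_grid[i_min]),
        lambda_1se=float(lambda_grid[i_1se]),
        fold_assignment_seed=seed,
    )


def _gene_seed(seed: int, gene_index: int) -> int:
    """Stable per-gene fold seed derived from (global seed, gene index)."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(gene_index,))
    return int(ss.generate_state(1)[0] % (2**31))


def scan_genes_lambda(
    X: ExpressionMatrix,
    k: int = 10,
    seed: int = 0,
    n_lambda: int = 100,
    ratio: float | None = None,
    tol: float = 1e-7,
) -> LambdaSummary:
    """Per-gene lambda scan: regress each gene on all others, CV the penalty.

    Every gene's cross-validation runs on one shared geometric grid (the
    path of the gene with the largest lambda_max), so "most frequent
    minimum and maximum lambda" are exact counts over grid values rather
    than modes of a continuous quantity.  ``mode_min`` is the most frequent
    ``lambda_min`` (ties broken toward the smaller value) and ``mode_max``
    the most frequent ``lambda_1se`` (ties toward the larger).  Genes whose
    CV fails are dropped with a logged reason.
    """
    if X.n_genes < 2:
        raise ValidationError("need at least 2 genes to scan")
    if not X.normalized:
        logger.warning("lambda scan on a matrix not flagged as normalized")
    problems = []
    lam_maxes = []
    for gi in range(X.n_genes):
        mask = np.ones(X.n_genes, dtype=bool)
        mask[gi] = False
        prob = LassoProblem(
            X.values[mask].T, X.values[gi], alpha=1.0, standardize=True
        )
        problems.append(prob)
        prep = _prepare(prob)
        lam_maxes.append(float(np.max(np.abs(prep["q"]))))
    ref = int(np.argmax(lam_maxes))
    if lam_maxes[ref] <= 0:
        raise ValidationError("all responses constant; no lambda path")
    grid = make_lambda_path(problems[ref], n_lambda, ratio)
    rows = []
    for gi, gene in enumerate(X.gene_ids):
        try:
            cv = cross_validate_lambda(
                problems[gi],
                k=k,
                seed=_gene_seed(seed, gi),
                lambda_grid=grid,
                tol=tol,
            )
        except (ValidationError, ConvergenceError) as exc:
            logger.warning("gene %s dropped from lambda scan: %s", gene, exc)
            continue
        rows.append(
            (
                gene,
                cv.lambda_min,
                cv.lambda_1se,
                float(cv.mse_mean[np.argmin(cv.mse_mean)]),
            )
        )
    if not rows:
        raise ValidationError("no gene produced a CV result")
    per_gene = pd.DataFrame(
        rows, columns=["gene_id", "lambda_min", "lambda_1se", "mse_at_min"]
    )
    mode_min = _modal_value(per_gene["lambda_min"], prefer="small")
    mode_max = _modal_value(per_gene["lambda_1se"], prefer="large")
    return LambdaSummary(per_gene, mode_min, mode_max, grid)


def _modal_value(values: pd.Series, prefer: str) -> float:
    counts = values.value_counts()
    best = counts[counts == counts.max()].index
    return float(min(best) if prefer == "small" else max(best))


def select_common_lambda(summaries, mse_tables=None) -> float:
    """Choose one penalty shared across data subsets.

    Candidates are the modal ``lambda_min`` values of each subset's scan.
    The winner has the highest pooled frequency (count of genes across all
    subsets whose ``lambda_min`` equals the candidate); frequency ties are
    broken by lower pooled median MSE at the minimum, remaining ties by the
    smaller lambda.
    """
    summaries = list(summaries)
    if not summaries:
        raise ValidationError("no lambda summaries given")
    tables = (
        [s.per_gene for s in summaries] if mse_tables is None else list(mse_tables)
    )
    pooled = pd.concat(tables, ignore_index=True)
    candidates = sorted({s.mode_min for s in summaries})
    if not candidates:
        raise ValidationError("empty candidate set")
    scored = []
    for lam in candidates:
        hits = pooled[pooled["lambda_min"] == lam]
        freq = len(hits)
        med = float(hits["mse_at_min"].median()) if freq else np.inf
        scored.append((-freq, med, lam))
    scored.sort()
    return float(scored[0][2])
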