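"""Independent reference implementations used to check the package.

These deliberately avoid the code paths they verify: the lasso oracle is a
smooth bound-constrained quadratic program over a positive/negative split
of the coefficients, the PR oracle recomputes full confusion matrices at
every cutoff, and the smoothing oracle is a direct per-element summation.
"""

import numpy as np
import scipy.optimize


def lasso_qp_oracle(X, y, lam, tol=1e-12):
    """Solve min (1/2N)||y - b0 - Xb||^2 + lam*||b||_1 by smooth QP.

    Splits b = u - v with u, v >= 0, giving a differentiable objective
    minimized with L-BFGS-B.  Returns (intercept, coefficients).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape

    def fun(z):
        b0, u, v = z[0], z[1 : p + 1], z[p + 1 :]
        b = u - v
        r = y - b0 - X @ b
        f = 0.5 / n * (r @ r) + lam * (u.sum() + v.sum())
        g_b = -(X.T @ r) / n
        grad = np.concatenate([[-r.mean()], g_b + lam, -g_b + lam])
        return f, grad

    z0 = np.zeros(1 + 2 * p)
    bounds = [(None, None)] + [(0, None)] * (2 * p)
    res = scipy.optimize.minimize(
        fun,
        z0,
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 50000, "ftol": tol, "gtol": 1e-12},
    )
    b = res.x[1 : p + 1] - res.x[p + 1 :]
    b0 = float(res.x[0])
    # exact polish: with the support and signs fixed, the KKT conditions are
    # a linear system in (b_S, b0); solve it directly
    support = np.nonzero(np.abs(b) > 1e-7)[0]
    if len(support):
        Xs = X[:, support]
        s = np.sign(b[support])
        k = len(support)
        A = np.zeros((k + 1, k + 1))
        A[:k, :k] = Xs.T @ Xs / n
        A[:k, k] = Xs.mean(axis=0)
        A[k, :k] = Xs.mean(axis=0)
        A[k, k] = 1.0
        rhs = np.concatenate([Xs.T @ y / n - lam * s, [y.mean()]])
        sol = np.linalg.solve(A, rhs)
        if np.all(np.sign(sol[:k]) == s):
            b = np.zeros(p)
            b[support] = sol[:k]
            b0 = float(sol[k])
    else:
        b0 = float(np.mean(y))
    return b0, b


def confusion_at_k(pred_edges, gold_edges, k, M):
    """tp/fp/fn/tn from an explicit confusion matrix at cutoff k."""
    top = set(pred_edges[:k])
    gold = set(gold_edges)
    tp = len(top & gold)
    fp = len(top - gold)
    fn = len(gold - top)
    tn = M - tp - fp - fn
    return tp, fp, fn, tn


def pr_curve_oracle(pred_edges, gold_edges, M):
    """Precision/recall/accuracy at every cutoff by brute enumeration."""
    P = len(set(gold_edges))
    rows = []
    for k in range(1, len(pred_edges) + 1):
        tp, fp, fn, tn = confusion_at_k(pred_edges, gold_edges, k, M)
        rows.append((k, tp, tp / k, tp / P, (tp + tn) / M))
    return rows


def average_precision_oracle(pred_edges, gold_edges):
    gold = set(gold_edges)
    tp = 0
    total = 0.0
    for k, e in enumerate(pred_edges, start=1):
        if e in gold:
            tp += 1
            total += tp / k
    return total / len(gold)


def smooth_feature_oracle(reg_values, reg_times, t_i, lag, dt, sigma):
    """Direct summation of the kernel-weighted lagged feature at one time."""
    center = t_i - lag * dt
    num = den = 0.0
    for x, tk in zip(reg_values, reg_times):
        if tk < t_i:
            w = np.exp(-0.5 * ((tk - center) / sigma) ** 2)
            num += w * x
            den += w
    return num / den if den > 0 else np.nan


def borda_oracle(rankings):
    """Sum of 1/rank recount with average ranks for ties."""
    totals = {}
    for ranked in rankings:
        scores = [s for _, _, s in ranked]
        order = sorted(range(len(scores)), key=lambda i: -scores[i])
        ranks = [0.0] * len(scores)
        i = 0
        while i < len(order):
            j = i
            while (
                j + 1 < len(order)
                and scores[order[j + 1]] == scores[order[i]]
            ):
                j += 1
            mean_rank = (i + j) / 2 + 1
            for idx in order[i : j + 1]:
                ranks[idx] = mean_rank
            i = j + 1
        for (r, t, _), rk in zip(ranked, ranks):
            totals[(r, t)] = totals.get((r, t), 0.0) + 1.0 / rk
    return totals
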