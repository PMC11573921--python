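"""Independent reference implementations used only to check the package.

Each oracle takes a deliberately different computational route from the
code under test: brute-force enumeration, pair counting, or a separately
written optimizer.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def newton_linesearch_fit(X, y, tol=1e-10, max_iter=200):
    """Logistic MLE by damped Newton with Armijo backtracking on the NLL.

    Returns (beta, covariance) with covariance the inverse Hessian of the
    negative log-likelihood at the optimum.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape

    def nll(b):
        eta = X @ b
        return float(np.sum(np.logaddexp(0.0, eta) - y * eta))

    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
        grad = X.T @ (mu - y)
        if np.max(np.abs(grad)) < tol:
            break
        W = mu * (1.0 - mu)
        H = X.T @ (X * W[:, None])
        direction = np.linalg.solve(H, -grad)
        f0 = nll(beta)
        slope = float(grad @ direction)
        t = 1.0
        while nll(beta + t * direction) > f0 + 1e-4 * t * slope and t > 1e-12:
            t *= 0.5
        beta = beta + t * direction
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    H = X.T @ (X * (mu * (1 - mu))[:, None])
    return beta, np.linalg.inv(H)


def auc_pair_count(scores, labels):
    """Mann-Whitney AUC by explicit pairwise comparison (half credit for ties)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    diff = pos[:, None] - neg[None, :]
    return float((np.sum(diff > 0) + 0.5 * np.sum(diff == 0)) / (len(pos) * len(neg)))


def auc_pair_count_rows(score_matrix, labels, chunk=256):
    """Row-wise pair-counting AUC for a (models x observations) matrix."""
    labels = np.asarray(labels)
    out = np.empty(score_matrix.shape[0])
    for start in range(0, score_matrix.shape[0], chunk):
        block = score_matrix[start : start + chunk]
        pos = block[:, labels == 1]
        neg = block[:, labels == 0]
        diff = pos[:, :, None] - neg[:, None, :]
        out[start : start + chunk] = (
            (diff > 0).sum(axis=(1, 2)) + 0.5 * (diff == 0).sum(axis=(1, 2))
        ) / (pos.shape[1] * neg.shape[1])
    return out


def brute_fairness_metrics(preds, labels, groups):
    """Equal opportunity / equalized odds / BER equality from raw triples.

    Conditional probabilities are computed by direct counting per subgroup;
    subgroups lacking a class are skipped for the affected rate family.
    """
    preds = np.asarray(preds)
    labels = np.asarray(labels)
    groups = np.asarray(groups)
    tprs, fprs, bers = [], [], []
    for g in np.unique(groups):
        m = groups == g
        y, yhat = labels[m], preds[m]
        tpr = fpr = None
        if np.any(y == 1):
            tpr = np.mean(yhat[y == 1] == 1)
            tprs.append(tpr)
        if np.any(y == 0):
            fpr = np.mean(yhat[y == 0] == 1)
            fprs.append(fpr)
        if tpr is not None and fpr is not None:
            bers.append(fpr + (1.0 - tpr))

    def rng(vals):
        return max(vals) - min(vals) if vals else 0.0

    eo = rng(tprs)
    return eo, max(eo, rng(fprs)), rng(bers)


def youden_scan(scores, labels):
    """Exhaustive threshold scan; ties broken toward the largest threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    best_t, best_num = None, None
    for t in sorted(set(scores.tolist())):
        pred = scores >= t
        tp = int(np.sum(pred[labels == 1]))
        tn = int(np.sum(~pred[labels == 0]))
        num = tp * n_neg + tn * n_pos  # J+1 scaled by n_pos*n_neg: exact ints
        if best_num is None or num >= best_num:  # >= keeps the largest tying t
            best_num, best_t = num, t
    return best_t, best_num / (n_pos * n_neg) - 1.0


def shapley_enumeration(beta, mu, x):
    """Exact Shapley values by summing over all feature coalitions.

    Value function: the linear predictor with features outside the coalition
    fixed at the background mean (intercept excluded from the game).
    """
    beta = np.asarray(beta, dtype=float)
    mu = np.asarray(mu, dtype=float)
    x = np.asarray(x, dtype=float)
    p = len(beta)

    def value(S):
        return sum(beta[j] * (x[j] if j in S else mu[j]) for j in range(p))

    phi = np.zeros(p)
    players = set(range(p))
    for j in range(p):
        rest = sorted(players - {j})
        for r in range(p):
            for S in itertools.combinations(rest, r):
                S = set(S)
                w = math.factorial(len(S)) * math.factorial(p - len(S) - 1) / math.factorial(p)
                phi[j] += w * (value(S | {j}) - value(S))
    return phi
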