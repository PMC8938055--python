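"""Independent brute-force oracles, written before (and kept independent of)
the implementation paths they check."""

from __future__ import annotations

import math

import numpy as np


def pair_counts_oracle(x, y):
    """Exhaustive O(n^2) enumeration of all observation pairs."""
    x = list(x)
    y = list(y)
    n = len(x)
    n_c = n_d = n_1 = n_2 = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = x[i] - x[j]
            dy = y[i] - y[j]
            if dx * dy > 0:
                n_c += 1
            elif dx * dy < 0:
                n_d += 1
            else:
                if dx == 0:
                    n_1 += 1
                if dy == 0:
                    n_2 += 1
    return {"n_c": n_c, "n_d": n_d, "n_0": n * (n - 1) // 2, "n_1": n_1, "n_2": n_2}


def midranks_oracle(v):
    """Average-rank transform by direct definition."""
    v = list(v)
    out = []
    for a in v:
        less = sum(1 for b in v if b < a)
        equal = sum(1 for b in v if b == a)
        out.append(less + (equal + 1) / 2.0)
    return out


def spearman_oracle(x, y):
    """Pearson correlation of midranks, computed from first principles."""
    rx = midranks_oracle(x)
    ry = midranks_oracle(y)
    n = len(rx)
    mx = sum(rx) / n
    my = sum(ry) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    sxx = sum((a - mx) ** 2 for a in rx)
    syy = sum((b - my) ** 2 for b in ry)
    if sxx == 0 or syy == 0:
        return 0.0
    return sxy / math.sqrt(sxx * syy)


def theil_u_oracle(x, y):
    """U(x|y) from explicit entropy sums over the joint distribution."""
    n = len(x)
    px = {}
    pj = {}
    py = {}
    for a, b in zip(x, y):
        px[a] = px.get(a, 0) + 1
        py[b] = py.get(b, 0) + 1
        pj[(a, b)] = pj.get((a, b), 0) + 1
    h_x = -sum((c / n) * math.log(c / n) for c in px.values())
    if h_x == 0:
        return 0.0
    h_xy = -sum((c / n) * math.log(c / n) for c in pj.values())
    h_y = -sum((c / n) * math.log(c / n) for c in py.values())
    h_x_given_y = h_xy - h_y
    return (h_x - h_x_given_y) / h_x


def nipals_oracle(Z, y, n_components):
    """Textbook standard-PLS (covariance weights) NIPALS, no shared code."""
    Z = np.array(Z, dtype=float)
    y = np.array(y, dtype=float)
    Zc = Z - Z.mean(axis=0)
    yc = y - y.mean()
    W, T, P, q = [], [], [], []
    for _ in range(n_components):
        w = Zc.T @ yc
        w = w / np.linalg.norm(w)
        if w[np.argmax(np.abs(w))] < 0:
            w = -w
        t = Zc @ w
        tt = t @ t
        p = Zc.T @ t / tt
        qc = yc @ t / tt
        W.append(w)
        T.append(t)
        P.append(p)
        q.append(qc)
        Zc = Zc - np.outer(t, p)
        yc = yc - t * qc
    W = np.column_stack(W)
    P = np.column_stack(P)
    q = np.array(q)
    beta = W @ np.linalg.solve(P.T @ W, q)
    return {"W": W, "T": np.column_stack(T), "P": P, "q": q, "beta": beta}


def ols_predictions(Z, y):
    """Normal-equations least squares with intercept."""
    Z = np.asarray(Z, float)
    y = np.asarray(y, float)
    X = np.column_stack([np.ones(len(y)), Z])
    coef = np.linalg.solve(X.T @ X, X.T @ y)
    return X @ coef, coef


def _lda_classify_oracle(X_train, y_train, x):
    """Textbook Gaussian LDA with pooled (n - k) covariance and count priors,
    written with explicit per-class loops."""
    X_train = np.asarray(X_train, float)
    y_train = np.asarray(y_train)
    classes = sorted(set(y_train.tolist()))
    n, d = X_train.shape
    means = {}
    scatter = np.zeros((d, d))
    for c in classes:
        rows = X_train[y_train == c]
        mu = rows.mean(axis=0)
        means[c] = mu
        for r in rows:
            diff = (r - mu)[:, None]
            scatter += diff @ diff.T
    cov = scatter / max(n - len(classes), 1)
    try:
        cov_inv = np.linalg.inv(cov)
    except np.linalg.LinAlgError:
        cov_inv = np.linalg.inv(cov + 1e-6 * np.trace(cov) / d * np.eye(d))
    best, best_score = None, -np.inf
    for c in classes:
        mu = means[c]
        prior = (y_train == c).mean()
        score = x @ cov_inv @ mu - 0.5 * mu @ cov_inv @ mu + math.log(prior)
        if score > best_score:
            best, best_score = c, score
    return best


def loocv_lda_oracle(T, labels):
    """Brute-force leave-one-out loop, refitting the oracle LDA per fold."""
    T = np.atleast_2d(np.asarray(T, float))
    labels = np.asarray(labels)
    n = T.shape[0]
    correct = 0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        pred = _lda_classify_oracle(T[mask], labels[mask], T[i])
        correct += int(pred == labels[i])
    return correct / n
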