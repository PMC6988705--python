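"""Independent reference implementations used only to check the package.

These are deliberately naive (loops, exact rational arithmetic) and share
no code with the implementation they verify.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np


def holm_bruteforce(pvalues):
    """Step-down Holm adjustment, straight from the definition."""
    p = list(map(float, pvalues))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    running = 0.0
    for rank, i in enumerate(order):
        val = min(1.0, (m - rank) * p[i])
        running = max(running, val)
        adj[i] = running
    return np.array(adj)


def bh_bruteforce(pvalues):
    """Step-up Benjamini-Hochberg adjustment, straight from the definition."""
    p = list(map(float, pvalues))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m - 1, -1, -1):
        i = order[rank]
        val = min(1.0, m * p[i] / (rank + 1))
        running = min(running, val)
        adj[i] = running
    return np.array(adj)


def binom_tail_exact(k: int, n: int) -> Fraction:
    """P(X >= k) for X ~ Binomial(n, 1/2) in exact rational arithmetic."""
    total = sum(math.comb(n, j) for j in range(k, n + 1))
    return Fraction(total, 2 ** n)


def pooled_t_pvalue(a, b) -> float:
    """Classic two-sample pooled-variance t-test, two-sided, from scratch."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
    from scipy.stats import t as tdist
    return 2 * tdist.sf(abs(t), na + nb - 2)


def angle_from_side_lengths(a, vertex, c) -> float:
    """Interior angle at the vertex via the law of cosines on the three
    side lengths only (no vector algebra)."""
    a = np.asarray(a, float)
    v = np.asarray(vertex, float)
    c = np.asarray(c, float)
    la = np.linalg.norm(a - v)
    lc = np.linalg.norm(c - v)
    lac = np.linalg.norm(a - c)
    cosang = (la ** 2 + lc ** 2 - lac ** 2) / (2 * la * lc)
    return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))


def gaussian_lda_predict(X_train, y_train, X_test):
    """Two-class linear discriminant from the closed-form Gaussian rule
    with pooled covariance and empirical priors."""
    X_train = np.asarray(X_train, float)
    X_test = np.asarray(X_test, float)
    y_train = np.asarray(y_train)
    classes = np.unique(y_train)
    assert len(classes) == 2
    mus, ns = [], []
    pooled = np.zeros((X_train.shape[1], X_train.shape[1]))
    for cl in classes:
        Xc = X_train[y_train == cl]
        mu = Xc.mean(axis=0)
        mus.append(mu)
        ns.append(len(Xc))
        pooled += (Xc - mu).T @ (Xc - mu)
    pooled /= (len(X_train) - 2)
    pinv = np.linalg.inv(pooled)
    scores = []
    for cl, mu, n in zip(classes, mus, ns):
        prior = n / len(X_train)
        s = X_test @ pinv @ mu - 0.5 * mu @ pinv @ mu + math.log(prior)
        scores.append(s)
    return np.where(scores[1] > scores[0], classes[1], classes[0])


def random_rigid_motion(rng):
    """A Haar-random rotation plus a random translation."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q = q * np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, [0, 1]] = q[:, [1, 0]]
    t = rng.normal(0, 30, 3)
    return q, t
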