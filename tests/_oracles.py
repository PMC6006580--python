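"""Independent brute-force reference implementations used only by tests.

Everything here is deliberately naive (literal sums, double loops, exhaustive
recursion) and shares no code with the package internals it checks.
"""

from __future__ import annotations

import numpy as np


def objective_bruteforce(A, X, Y, Wd, Ws, mu, lam) -> float:
    """Term-by-term literal evaluation of the factorization objective."""
    n, m = A.shape
    k = X.shape[1]
    L = 0.0
    for i in range(n):
        for j in range(m):
            L += 0.5 * (A[i, j] - float(np.dot(X[i], Y[j]))) ** 2
    for i in range(n):
        L += 0.5 * mu * float(np.dot(X[i], X[i]))
    for j in range(m):
        L += 0.5 * mu * float(np.dot(Y[j], Y[j]))
    for i in range(n):
        for j in range(n):
            d = X[i] - X[j]
            L += 0.5 * lam * float(np.dot(d, d)) * Wd[i, j]
    for i in range(m):
        for j in range(m):
            d = Y[i] - Y[j]
            L += 0.5 * lam * float(np.dot(d, d)) * Ws[i, j]
    return L


def fd_gradient(f, x, h=1e-6):
    """Central finite-difference gradient of scalar f at vector x."""
    x = np.asarray(x, dtype=float)
    g = np.zeros_like(x)
    for c in range(x.size):
        e = np.zeros_like(x)
        e[c] = h
        g[c] = (f(x + e) - f(x - e)) / (2 * h)
    return g


def fd_jacobian(g, x, h=1e-5):
    """Central finite-difference Jacobian of vector-valued g at x."""
    x = np.asarray(x, dtype=float)
    k = x.size
    J = np.zeros((k, k))
    for c in range(k):
        e = np.zeros_like(x)
        e[c] = h
        J[c] = (g(x + e) - g(x - e)) / (2 * h)
    return J


def contributions_recursive(children_of, terms, delta):
    """All C_A(d) values by plain recursion on the children mapping."""

    def c(node):
        if node in terms:
            return 1.0
        return max(delta * c(ch) for ch in children_of[node])

    return {node: c(node) for node in children_of}


def semantic_similarity_bruteforce(tn_a, tn_b, delta):
    """S(A, B) evaluated from scratch from two tree-number lists."""

    def dag(tree_numbers):
        children = {}
        terms = set()
        for tn in tree_numbers:
            parts = tn.split(".")
            prefixes = [".".join(parts[: i + 1]) for i in range(len(parts))]
            for p in prefixes:
                children.setdefault(p, set())
            for a, b in zip(prefixes[:-1], prefixes[1:]):
                children[a].add(b)
            terms.add(prefixes[-1])
        return children, terms

    ca_children, ca_terms = dag(tn_a)
    cb_children, cb_terms = dag(tn_b)
    ca = contributions_recursive(ca_children, ca_terms, delta)
    cb = contributions_recursive(cb_children, cb_terms, delta)
    shared = set(ca) & set(cb)
    if not shared:
        return 0.0
    return sum(ca[d] + cb[d] for d in shared) / (sum(ca.values()) + sum(cb.values()))


def aupr_bruteforce(scores, labels) -> float:
    """Step-wise AUPR by exhaustive evaluation at every distinct threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = labels.sum()
    pts = []
    for t in sorted(set(scores.tolist()), reverse=True):
        pred = scores >= t
        tp = int((labels[pred] == 1).sum())
        pts.append((tp / pos, tp / int(pred.sum())))
    area = 0.0
    prev_r = 0.0
    for r, p in pts:
        area += (r - prev_r) * p
        prev_r = r
    return area


def auc_pairwise(scores, labels) -> float:
    """AUC by enumerating all positive-negative pairs (ties count 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                wins += 1.0
            elif sp == sn:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def maxf_bruteforce(scores, labels):
    """Exhaustive threshold search for the F-maximizing cutoff."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = labels.sum()
    neg = labels.size - pos
    best = None
    for t in sorted(set(scores.tolist()), reverse=True):
        pred = scores >= t
        tp = int((labels[pred] == 1).sum())
        fp = int(pred.sum()) - tp
        tn = neg - fp
        sn = tp / pos
        sp = tn / neg
        acc = (tp + tn) / labels.size
        prec = tp / int(pred.sum())
        f = 2 * prec * sn / (prec + sn) if (prec + sn) > 0 else 0.0
        if best is None or f > best[3]:
            best = (sn, sp, acc, f)
    return best


def als_ridge(A, k, mu, sweeps, X0, Y0):
    """Plain L2-regularized alternating least squares (no similarity terms)."""
    X, Y = X0.copy(), Y0.copy()
    trace = []
    eye = mu * np.eye(k)
    for _ in range(sweeps):
        X = A @ Y @ np.linalg.inv(Y.T @ Y + eye)
        Y = A.T @ X @ np.linalg.inv(X.T @ X + eye)
        resid = A - X @ Y.T
        trace.append(
            0.5 * float(np.sum(resid * resid))
            + 0.5 * mu * (float(np.sum(X * X)) + float(np.sum(Y * Y)))
        )
    return X, Y, trace
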