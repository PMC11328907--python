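"""Independent, deliberately naive reference implementations.

Everything here is written from the mathematical definitions with plain
loops, sharing no code with the package, so tests can compare the
optimized implementations against an independent path.
"""

from __future__ import annotations

import numpy as np


# ---------------------------------------------------------------- graphs
def union_find_components(nodes, edges):
    """Connected components via union-find; returns frozensets."""
    parent = {n: n for n in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    groups = {}
    for n in nodes:
        groups.setdefault(find(n), set()).add(n)
    return {frozenset(g) for g in groups.values()}


# ---------------------------------------------------------------- RV / CA
def rv_direct(X_sub, X_full):
    """Escoufier RV by explicit trace-formula evaluation."""
    A = np.asarray(X_sub, dtype=float)
    B = np.asarray(X_full, dtype=float)
    A = A - A.mean(axis=0)
    B = B - B.mean(axis=0)
    S_ab = np.zeros((A.shape[1], B.shape[1]))
    for i in range(A.shape[1]):
        for j in range(B.shape[1]):
            S_ab[i, j] = float(A[:, i] @ B[:, j])
    S_aa = np.zeros((A.shape[1], A.shape[1]))
    for i in range(A.shape[1]):
        for j in range(A.shape[1]):
            S_aa[i, j] = float(A[:, i] @ A[:, j])
    S_bb = np.zeros((B.shape[1], B.shape[1]))
    for i in range(B.shape[1]):
        for j in range(B.shape[1]):
            S_bb[i, j] = float(B[:, i] @ B[:, j])
    num = np.trace(S_ab @ S_ab.T)
    den = np.sqrt(np.trace(S_aa @ S_aa) * np.trace(S_bb @ S_bb))
    return float(num / den)


def ca_coordinates_direct(N):
    """Column principal coordinates of a CA, from the definition."""
    N = np.asarray(N, dtype=float)
    n = N.sum()
    P = N / n
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = np.zeros_like(P)
    for i in range(P.shape[0]):
        for j in range(P.shape[1]):
            S[i, j] = (P[i, j] - r[i] * c[j]) / np.sqrt(r[i] * c[j])
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)
    keep = sv > 1e-12
    sv, Vt = sv[keep], Vt[keep]
    coords = np.zeros((P.shape[1], sv.size))
    for j in range(P.shape[1]):
        for k in range(sv.size):
            coords[j, k] = Vt[k, j] * sv[k] / np.sqrt(c[j])
    inertia = sv**2 / np.sum(sv**2)
    return coords, inertia


# ---------------------------------------------------------------- trees
def naive_best_split(X, R, min_leaf, n_quantiles):
    """Brute-force scan over every quantile candidate of every feature.

    Tie-break: first feature (ascending), then lowest threshold, with a
    strictly-greater-gain update rule — the documented deterministic
    contract.
    """
    X = np.asarray(X, dtype=float)
    R = np.asarray(R, dtype=float)
    n = X.shape[0]
    best = None  # (feature, threshold, gain)
    for f in range(X.shape[1]):
        qs = np.arange(1, n_quantiles + 1) / (n_quantiles + 1)
        for t in np.unique(np.quantile(X[:, f], qs)):
            left = X[:, f] <= t
            nl = int(left.sum())
            if nl < min_leaf or n - nl < min_leaf:
                continue
            sse_parent = ((R - R.mean(axis=0)) ** 2).sum()
            sse_l = ((R[left] - R[left].mean(axis=0)) ** 2).sum()
            sse_r = ((R[~left] - R[~left].mean(axis=0)) ** 2).sum()
            gain = sse_parent - sse_l - sse_r
            if best is None or gain > best[2] + 1e-15:
                best = (f, float(t), float(gain))
    if best is None or best[2] <= 1e-12:
        return None
    return best


def naive_fit_tree(X, R, min_leaf, n_quantiles, max_depth, depth=0):
    """Plain recursive multivariate regression tree (dict nodes)."""
    X = np.asarray(X, dtype=float)
    R = np.asarray(R, dtype=float)
    if depth >= max_depth or X.shape[0] < 2 * min_leaf:
        return {"leaf": R.mean(axis=0)}
    split = naive_best_split(X, R, min_leaf, n_quantiles)
    if split is None:
        return {"leaf": R.mean(axis=0)}
    f, t, gain = split
    left = X[:, f] <= t
    return {
        "f": f,
        "t": t,
        "gain": gain,
        "l": naive_fit_tree(X[left], R[left], min_leaf, n_quantiles, max_depth, depth + 1),
        "r": naive_fit_tree(X[~left], R[~left], min_leaf, n_quantiles, max_depth, depth + 1),
    }


def naive_tree_predict(node, x):
    while "leaf" not in node:
        node = node["l"] if x[node["f"]] <= node["t"] else node["r"]
    return node["leaf"]


def naive_boost(X, Y, lr, min_leaf, n_quantiles, max_depth, n_rounds):
    """Loop-based multivariate gradient boosting under squared error."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    base = Y.mean(axis=0)
    pred = np.tile(base, (X.shape[0], 1))
    trees = []
    for _ in range(n_rounds):
        R = Y - pred
        tree = naive_fit_tree(X, R, min_leaf, n_quantiles, max_depth)
        trees.append(tree)
        for i in range(X.shape[0]):
            pred[i] += lr * naive_tree_predict(tree, X[i])
    return base, trees, pred


def naive_predict(base, trees, lr, X):
    X = np.asarray(X, dtype=float)
    out = np.tile(base, (X.shape[0], 1))
    for tree in trees:
        for i in range(X.shape[0]):
            out[i] += lr * naive_tree_predict(tree, X[i])
    return out


# ---------------------------------------------------------------- stats
def mantel_r_direct(Y_obs, Y_pred):
    """Pearson r of off-diagonal correlation entries, by explicit loops."""
    A = np.corrcoef(np.asarray(Y_obs, float), rowvar=False)
    B = np.corrcoef(np.asarray(Y_pred, float), rowvar=False)
    a, b = [], []
    d = A.shape[0]
    for i in range(d):
        for j in range(i + 1, d):
            a.append(A[i, j])
            b.append(B[i, j])
    a = np.asarray(a)
    b = np.asarray(b)
    am, bm = a.mean(), b.mean()
    return float(
        np.sum((a - am) * (b - bm))
        / np.sqrt(np.sum((a - am) ** 2) * np.sum((b - bm) ** 2))
    )


def chi_square_direct(table):
    """Sum (O - E)^2 / E for a contingency table."""
    T = np.asarray(table, dtype=float)
    total = T.sum()
    chi2 = 0.0
    for i in range(T.shape[0]):
        for j in range(T.shape[1]):
            e = T[i].sum() * T[:, j].sum() / total
            chi2 += (T[i, j] - e) ** 2 / e
    return chi2
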