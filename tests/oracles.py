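"""Independent reference implementations used only to check the package.

These deliberately take different computational routes from the library:
proximal-gradient (FISTA) minimization of the penalized least-squares
objective, cophenetic distances by explicit dendrogram traversal, and
chi-square distances between row profiles by direct summation.
"""

from __future__ import annotations

import numpy as np


def lasso_objective(X, y, w, w0, alpha) -> float:
    r = y - X @ w - w0
    return float(r @ r / (2 * len(y)) + alpha * np.abs(w).sum())


def fista_lasso(X, y, alpha, n_iter=20000):
    """Long-run accelerated proximal gradient on
    1/(2n)||Xw + w0 - y||^2 + alpha ||w||_1 with unpenalized intercept
    (handled by centering)."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n = len(y)
    xm = X.mean(axis=0)
    ym = y.mean()
    Xc = X - xm
    yc = y - ym
    L = np.linalg.norm(Xc, 2) ** 2 / n  # Lipschitz constant of the gradient
    if L == 0:
        return np.zeros(X.shape[1]), ym
    w = np.zeros(X.shape[1])
    v = w.copy()
    t = 1.0
    for _ in range(n_iter):
        g = Xc.T @ (Xc @ v - yc) / n
        z = v - g / L
        w_new = np.sign(z) * np.maximum(np.abs(z) - alpha / L, 0.0)
        t_new = (1 + np.sqrt(1 + 4 * t * t)) / 2
        v = w_new + (t - 1) / t_new * (w_new - w)
        w, t = w_new, t_new
    w0 = ym - xm @ w
    return w, w0


def cophenetic_matrix_by_traversal(merges: np.ndarray, n_leaves: int) -> np.ndarray:
    """Cophenetic distances by walking the merge list: members of the two
    clusters joined at height h are at cophenetic distance h."""
    members: dict[int, list[int]] = {i: [i] for i in range(n_leaves)}
    out = np.zeros((n_leaves, n_leaves))
    for k, (a, b, h, _) in enumerate(merges):
        ma, mb = members.pop(int(a)), members.pop(int(b))
        for i in ma:
            for j in mb:
                out[i, j] = out[j, i] = h
        members[n_leaves + k] = ma + mb
    return out


def chi_square_row_distances(N: np.ndarray) -> np.ndarray:
    """Chi-square distances between row profiles of a nonnegative table,
    by direct summation."""
    N = np.asarray(N, float)
    total = N.sum()
    P = N / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    profiles = P / r[:, None]
    n = N.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            out[i, j] = np.sqrt(np.sum((profiles[i] - profiles[j]) ** 2 / c))
    return out
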