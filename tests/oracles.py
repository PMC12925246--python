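"""Independent oracles used only by the test suite.

These deliberately use the most transparent formulation available (triple
loops, generic first-order convex optimization) and share no code with the
implementations they check.
"""

from __future__ import annotations

import numpy as np


def tom_bruteforce(a: np.ndarray) -> np.ndarray:
    """Topological overlap via explicit triple loops."""
    n = a.shape[0]
    t = np.ones((n, n))
    k = [sum(a[i, u] for u in range(n) if u != i) for i in range(n)]
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l_ij = sum(a[i, u] * a[u, j] for u in range(n) if u != i and u != j)
            t[i, j] = (l_ij + a[i, j]) / (min(k[i], k[j]) + 1.0 - a[i, j])
    return t


def glasso_ista(s: np.ndarray, lam: float, max_iter: int = 100_000,
                tol: float = 1e-10) -> np.ndarray:
    """Generic proximal-gradient (ISTA) solver for the graphical lasso.

    Minimizes -log det(Theta) + tr(S Theta) + lam * ||offdiag(Theta)||_1
    over positive-definite Theta, with backtracking line search.  Intended
    for small dense problems where it converges to high precision.
    """
    p = s.shape[0]
    theta = np.linalg.inv(s + lam * np.eye(p))
    step = 1.0

    def objective(th):
        sign, logdet = np.linalg.slogdet(th)
        if sign <= 0:
            return np.inf
        return -logdet + np.trace(s @ th) + lam * (np.abs(th).sum() - np.abs(np.diag(th)).sum())

    def prox(th, t):
        out = np.sign(th) * np.maximum(np.abs(th) - t * lam, 0.0)
        np.fill_diagonal(out, np.diag(th))
        return out

    f = objective(theta)
    for _ in range(max_iter):
        grad = s - np.linalg.inv(theta)
        # backtracking on the smooth part
        while True:
            cand = prox(theta - step * grad, step)
            cand = (cand + cand.T) / 2.0
            f_cand = objective(cand)
            if np.isfinite(f_cand):
                diff = cand - theta
                smooth_bound = (f - lam * (np.abs(theta).sum() - np.abs(np.diag(theta)).sum())
                                + np.sum(grad * diff)
                                + np.sum(diff ** 2) / (2 * step)
                                + lam * (np.abs(cand).sum() - np.abs(np.diag(cand)).sum()))
                if f_cand <= smooth_bound + 1e-15:
                    break
            step *= 0.5
            if step < 1e-14:
                return theta
        if np.max(np.abs(cand - theta)) < tol:
            theta = cand
            break
        theta, f = cand, f_cand
        step *= 1.1
    return (theta + theta.T) / 2.0


def random_correlation(p: int, rng: np.random.Generator) -> np.ndarray:
    """A random well-conditioned correlation matrix."""
    a = rng.standard_normal((p, 2 * p))
    c = np.corrcoef(a)
    return (c + c.T) / 2.0
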