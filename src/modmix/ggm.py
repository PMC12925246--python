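"""Sparse Gaussian graphical model estimation per dataset.

The graphical lasso maximizes

    log det(Theta) - tr(S Theta) - lambda * sum_{i != j} |theta_ij|

over positive-definite precision matrices Theta, with the diagonal left
unpenalized.  Partial correlations follow from the precision entries as
rho_ij = -theta_ij / sqrt(theta_ii * theta_jj).  Because the input data
are standardized upstream, the empirical covariance equals the empirical
correlation matrix, which is what the solver receives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.covariance import graphical_lasso as _sk_graphical_lasso

from .io import AbundanceMatrix


@dataclass
class GlassoConfig:
    """Graphical-lasso settings.

    lam : L1 penalty on off-diagonal precision entries (default 0.25).
    max_iter : coordinate-descent sweep budget.
    tol : per-entry duality-gap tolerance; the solver stops once the total
        duality gap falls below ``tol * p**2``.  The gap of the penalized
        likelihood grows with the number of features p, so an absolute
        tolerance would be unreachably tight for wide matrices and far too
        loose for small ones; tighten tol when high-precision estimates of
        small problems are needed.
    """

    lam: float = 0.25
    max_iter: int = 100
    tol: float = 1e-4

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lam must be nonnegative")
        if self.max_iter < 1 or self.tol <= 0:
            raise ValueError("max_iter must be >=1 and tol > 0")


@dataclass
class PrecisionMatrix:
    feature_ids: list[str]
    theta: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.theta, dtype=float)
        if t.shape != (len(self.feature_ids),) * 2:
            raise ValueError("theta shape does not match feature_ids")
        if not np.allclose(t, t.T, atol=1e-8):
            raise ValueError("precision matrix is not symmetric")
        self.theta = t


@dataclass
class PartialCorrelationMatrix:
    feature_ids: list[str]
    rho: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.rho, dtype=float)
        if r.shape != (len(self.feature_ids),) * 2:
            raise ValueError("rho shape does not match feature_ids")
        if np.abs(r).max(initial=0.0) > 1 + 1e-9:
            raise ValueError("partial correlations must lie in [-1, 1]")
        if np.abs(np.diag(r)).max(initial=0.0) > 1e-12:
            raise ValueError("partial correlation diagonal must be zero")
        self.rho = r


def empirical_correlation(m: AbundanceMatrix) -> np.ndarray:
    """S = X X^T / (n-1) for a standardized features x samples matrix."""
    if np.isnan(m.values).any():
        raise ValueError("empirical_correlation requires a complete matrix")
    if m.n_samples < 3:
        raise ValueError("need at least 3 samples")
    x = m.values
    s = (x @ x.T) / (m.n_samples - 1)
    s = (s + s.T) / 2.0
    if np.abs(np.diag(s) - 1.0).max() > 1e-8:
        raise ValueError("input does not look standardized (non-unit diagonal)")
    np.fill_diagonal(s, 1.0)
    return s


def graphical_lasso(s: np.ndarray, cfg: GlassoConfig | None = None,
                    feature_ids: list[str] | None = None) -> PrecisionMatrix:
    """L1-penalized precision estimate via coordinate descent.

    Deterministic for fixed inputs; raises on non-convergence.
    """
    cfg = cfg or GlassoConfig()
    s = np.asarray(s, dtype=float)
    p = s.shape[0]
    if feature_ids is None:
        feature_ids = [f"f{i}" for i in range(p)]
    if not np.allclose(s, s.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    import warnings

    from sklearn.exceptions import ConvergenceWarning

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=ConvergenceWarning)
            _, theta = _sk_graphical_lasso(s, alpha=cfg.lam, tol=cfg.tol * p * p,
                                           max_iter=cfg.max_iter)
    except FloatingPointError as exc:  # pragma: no cover - pathological inputs
        raise RuntimeError(f"graphical lasso failed: {exc}") from exc
    theta = (theta + theta.T) / 2.0
    threshold = cfg.tol * p * p
    if _dual_gap(s, theta, cfg.lam) > threshold:
        # Coordinate descent can stall short of a tight gap; finish the
        # job with proximal-gradient steps on the primal.
        theta = _prox_polish(s, theta, cfg.lam, threshold)
    gap = _dual_gap(s, theta, cfg.lam)
    if gap > threshold:
        raise RuntimeError(f"graphical lasso did not converge: duality gap "
                           f"{gap:.3e} > {threshold:.3e}")
    return PrecisionMatrix(feature_ids, theta)


def _dual_gap(s: np.ndarray, theta: np.ndarray, lam: float) -> float:
    """Certified duality gap of the off-diagonal-penalized glasso at Theta.

    The dual feasible point is Theta^-1 projected onto the box
    |W_ij - S_ij| <= lam (off-diagonal) with W_ii = S_ii; the gap bounds
    the primal suboptimality from above.  Returns +inf when the projected
    point is not positive definite (Theta too far from the optimum).
    """
    p = s.shape[0]
    w = np.linalg.inv(theta)
    w_proj = np.clip(w, s - lam, s + lam)
    np.fill_diagonal(w_proj, np.diag(s))
    w_proj = (w_proj + w_proj.T) / 2.0
    sign, logdet = np.linalg.slogdet(w_proj)
    if sign <= 0 or np.linalg.eigvalsh(w_proj)[0] <= 0:
        # Far from the optimum the projection can lose positive
        # definiteness; fall back to the stationarity-based estimate
        # (zero at the optimum, the criterion reference solvers use).
        off = np.abs(theta).sum() - np.abs(np.diag(theta)).sum()
        return float(np.sum(s * theta) - p + lam * off)
    return glasso_objective(theta, s, lam) - float(logdet) - p


def _prox_polish(s: np.ndarray, theta: np.ndarray, lam: float, gap_tol: float,
                 max_iter: int = 20_000) -> np.ndarray:
    """Proximal-gradient refinement of a near-optimal precision estimate.

    Each step soft-thresholds the off-diagonal of a gradient step on the
    smooth part (-log det + tr(S .)), with backtracking to stay positive
    definite; stops once the duality gap falls below ``gap_tol``.
    """
    step = 1.0
    f_prev = glasso_objective(theta, s, lam)
    for _ in range(max_iter):
        if _dual_gap(s, theta, lam) <= gap_tol:
            break
        grad = s - np.linalg.inv(theta)
        while step > 1e-14:
            cand = theta - step * grad
            soft = np.sign(cand) * np.maximum(np.abs(cand) - step * lam, 0.0)
            np.fill_diagonal(soft, np.diag(cand))
            soft = (soft + soft.T) / 2.0
            f_cand = glasso_objective(soft, s, lam)
            if np.isfinite(f_cand) and f_cand <= f_prev + 1e-15:
                break
            step *= 0.5
        else:  # no acceptable step left; return best point found
            break
        theta, f_prev = soft, f_cand
        step = min(step * 1.2, 1.0)
    return theta


def glasso_objective(theta: np.ndarray, s: np.ndarray, lam: float) -> float:
    """Penalized negative log-likelihood value (lower is better)."""
    sign, logdet = np.linalg.slogdet(theta)
    if sign <= 0:
        return np.inf
    off = np.abs(theta).sum() - np.abs(np.diag(theta)).sum()
    return float(-logdet + np.trace(s @ theta) + lam * off)


def precision_to_partial_corr(theta: PrecisionMatrix) -> PartialCorrelationMatrix:
    """rho_ij = -theta_ij / sqrt(theta_ii theta_jj); diagonal stored as 0."""
    t = (theta.theta + theta.theta.T) / 2.0
    d = np.diag(t)
    if (d <= 0).any():
        bad = [theta.feature_ids[i] for i in np.flatnonzero(d <= 0)]
        raise ValueError(f"nonpositive precision diagonal for: {', '.join(bad[:10])}")
    denom = np.sqrt(np.outer(d, d))
    rho = -t / denom
    np.clip(rho, -1.0, 1.0, out=rho)
    np.fill_diagonal(rho, 0.0)
    return PartialCorrelationMatrix(list(theta.feature_ids), rho)


def estimate_ggm(
    m: AbundanceMatrix,
    cfg: GlassoConfig | None = None,
    precomputed: PartialCorrelationMatrix | None = None,
) -> PartialCorrelationMatrix:
    """Standardized matrix -> partial correlations (or pass through a
    user-supplied precomputed partial-correlation matrix)."""
    if precomputed is not None:
        return precomputed
    s = empirical_correlation(m)
    theta = graphical_lasso(s, cfg, feature_ids=list(m.feature_ids))
    return precision_to_partial_corr(theta)
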