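"""Independent oracles used by the test suite.

These deliberately avoid the package's own update/evaluation code paths:
the NIG posterior oracle integrates prior x likelihood on a dense grid,
and the AUC oracle counts concordant positive/negative pairs directly.
"""

from __future__ import annotations

import numpy as np


def nig_grid_moments(
    tau0: np.ndarray,
    lam0_inv: np.ndarray,
    alpha0: float,
    beta0: float,
    X: np.ndarray,
    y: np.ndarray,
    span: float = 8.0,
    n_omega: int = 241,
    n_u: int = 321,
) -> dict:
    """Posterior moments of (omega, sigma2) by dense grid integration.

    Integrates the unnormalized density

        p(omega, sigma2) ∝ (sigma2)^-(alpha0 + P/2 + 1)
            * exp(-[beta0 + (omega-tau0)' Lambda0 (omega-tau0)/2] / sigma2)
            * (sigma2)^(-n/2) * exp(-||y - X omega||^2 / (2 sigma2))

    on a tensor grid over omega (P <= 2) and u = log(sigma2).  The omega
    window is centered on the penalized least-squares point, which only
    locates the grid and does not feed any moment.
    """
    tau0 = np.asarray(tau0, float).ravel()
    P = tau0.size
    if P > 2:
        raise ValueError("grid oracle supports P <= 2")
    lam0 = np.linalg.inv(np.asarray(lam0_inv, float))
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float).ravel()
    n = y.size

    center = np.linalg.solve(lam0 + X.T @ X, lam0 @ tau0 + X.T @ y)
    axes = [np.linspace(c - span, c + span, n_omega) for c in center]
    if P == 1:
        omega = axes[0][:, None]
    else:
        g0, g1 = np.meshgrid(axes[0], axes[1], indexing="ij")
        omega = np.column_stack([g0.ravel(), g1.ravel()])

    d0 = omega - tau0
    quad_prior = np.einsum("ij,jk,ik->i", d0, lam0, d0)
    resid = y[None, :] - omega @ X.T
    quad_lik = np.sum(resid**2, axis=1)
    a_body = beta0 + 0.5 * quad_prior + 0.5 * quad_lik  # numerator of exp(-a/s2)

    u = np.linspace(np.log(1e-4), np.log(1e4), n_u)
    s2 = np.exp(u)
    # log density on (omega_i, u_j); +u from the ds2 = s2 du Jacobian
    k = alpha0 + P / 2.0 + n / 2.0 + 1.0
    logp = -k * u[None, :] - a_body[:, None] / s2[None, :] + u[None, :]
    logp -= logp.max()
    p = np.exp(logp)

    w_u = np.gradient(u)
    p_omega = p @ w_u  # marginal over sigma2 (up to the omega grid measure)
    z = p_omega.sum()
    mean = (p_omega[:, None] * omega).sum(axis=0) / z
    dc = omega - mean
    cov = (p_omega[:, None, None] * dc[:, :, None] * dc[:, None, :]).sum(axis=0) / z
    e_s2 = float((p @ (w_u * s2)).sum() / z)
    return {"mean": mean, "cov": cov, "e_sigma2": e_s2}


def mann_whitney_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Pairwise concordance probability that a positive case scores *lower*
    than a negative one (low symptom score = remission), ties counted 1/2."""
    scores = np.asarray(scores, float).ravel()
    labels = np.asarray(labels).astype(bool).ravel()
    pos = scores[labels]
    neg = scores[~labels]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes required")
    diff = pos[:, None] - neg[None, :]
    return float(((diff < 0).sum() + 0.5 * (diff == 0).sum()) / diff.size)
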