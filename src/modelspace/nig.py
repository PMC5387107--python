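"""Conjugate Normal–Inverse-Gamma (NIG) Bayesian linear regression.

A subject's treatment response is modeled as ``y = X w + eps`` with
``eps ~ N(0, sigma2)`` and the conjugate prior

    w | sigma2 ~ N(tau, sigma2 * Lambda^{-1}),    sigma2 ~ InvGamma(alpha, beta).

The design matrix has one row per clinic appointment,
``x_a = [b_1..b_L, m_1..m_4, 1]``: the subject's L baseline latent-factor
scores (constant across appointments), the four medication dosages in
equivalent-daily-dose units (IR-MPH, XR-MPH, DEX, ATOM), and an intercept,
so the parameter dimension is P = L + 4 + 1.

Conjugacy gives closed-form posterior updates and a Student-t posterior
predictive with ``nu = 2 * alpha`` degrees of freedom; both are exact, so
batch and one-row-at-a-time sequential updating agree to rounding error.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._exceptions import DataError

logger = logging.getLogger(__name__)

__all__ = [
    "NIGState",
    "DesignBlock",
    "PredictiveDistribution",
    "make_design",
    "nig_update",
    "posterior_predictive",
    "predictive_interval",
]

#: relative jitter added to a numerically singular precision matrix
_JITTER_REL = 1e-8
#: tolerance for symmetry / positive-semidefiniteness checks
_PSD_TOL = 1e-10


@dataclass
class NIGState:
    """Normal–Inverse-Gamma belief about a response vector and noise variance.

    Parameters
    ----------
    tau : (P,) ndarray
        Mean of the regression-coefficient belief.
    lambda_inv : (P, P) ndarray
        Symmetric PSD covariance-scale of that belief; the coefficient
        covariance is ``sigma2 * lambda_inv``.
    alpha, beta : float
        Inverse-Gamma shape and scale for the noise variance; both > 0.
    """

    tau: np.ndarray
    lambda_inv: np.ndarray
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        self.tau = np.asarray(self.tau, dtype=float).ravel()
        self.lambda_inv = np.asarray(self.lambda_inv, dtype=float)
        self.alpha = float(self.alpha)
        self.beta = float(self.beta)
        self.validate()

    @property
    def dim(self) -> int:
        return self.tau.size

    def validate(self) -> None:
        P = self.dim
        if self.lambda_inv.shape != (P, P):
            raise DataError(
                f"lambda_inv shape {self.lambda_inv.shape} does not match tau dim {P}"
            )
        if not np.all(np.isfinite(self.tau)) or not np.all(np.isfinite(self.lambda_inv)):
            raise DataError("non-finite entries in NIG state")
        asym = np.max(np.abs(self.lambda_inv - self.lambda_inv.T)) if P else 0.0
        scale = max(1.0, float(np.max(np.abs(self.lambda_inv))) if P else 1.0)
        if asym > 1e-8 * scale:
            raise DataError(f"lambda_inv is asymmetric (max deviation {asym:g})")
        eigmin = float(np.linalg.eigvalsh(self.lambda_inv)[0]) if P else 0.0
        if eigmin < -_PSD_TOL * scale:
            raise DataError(f"lambda_inv is not PSD (min eigenvalue {eigmin:g})")
        if not (self.alpha > 0 and self.beta > 0):
            raise DataError(f"alpha and beta must be positive (got {self.alpha}, {self.beta})")

    def copy(self) -> "NIGState":
        return NIGState(self.tau.copy(), self.lambda_inv.copy(), self.alpha, self.beta)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "tau": self.tau.tolist(),
            "lambda_inv": self.lambda_inv.ravel().tolist(),
            "alpha": self.alpha,
            "beta": self.beta,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NIGState":
        tau = np.asarray(d["tau"], dtype=float)
        P = tau.size
        lam = np.asarray(d["lambda_inv"], dtype=float).reshape(P, P)
        return cls(tau, lam, d["alpha"], d["beta"])

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "NIGState":
        return cls.from_dict(json.loads(s))

    def precision(self) -> np.ndarray:
        """Return Lambda = lambda_inv^{-1}, jittering if numerically singular."""
        return _robust_inv(self.lambda_inv)


@dataclass
class DesignBlock:
    """A block of appointments for one subject: design rows X and outcomes y.

    Rows are ``[baseline | dosages | 1]``; within a subject every row carries
    the same baseline block.  ``y`` holds a single symptom dimension
    (inattentiveness or hyperactivity) — one independent model per dimension.
    """

    X: np.ndarray
    y: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.X.size == 0:
            self.X = self.X.reshape(0, self.X.shape[-1] if self.X.ndim == 2 else 0)
        if self.y is None:
            self.y = np.zeros(self.X.shape[0])
        self.y = np.asarray(self.y, dtype=float).ravel()
        if self.y.size != self.X.shape[0]:
            raise DataError(
                f"X has {self.X.shape[0]} rows but y has {self.y.size} entries"
            )
        if not np.all(np.isfinite(self.X)):
            raise DataError("non-finite entries in design matrix")

    @property
    def n(self) -> int:
        return self.X.shape[0]


@dataclass
class PredictiveDistribution:
    """Student-t posterior predictive for one appointment's symptom score.

    ``y* ~ t_nu(location, scale_sq)`` with ``location = x tau``,
    ``scale_sq = (beta/alpha) (1 + x Lambda^{-1} x^T)`` and ``nu = 2 alpha``.
    """

    location: float
    scale_sq: float
    nu: float

    def __post_init__(self) -> None:
        self.location = float(self.location)
        self.scale_sq = float(self.scale_sq)
        self.nu = float(self.nu)
        if not self.scale_sq > 0:
            raise DataError(f"scale_sq must be positive (got {self.scale_sq})")
        if not self.nu > 0:
            raise DataError(f"nu must be positive (got {self.nu})")

    @property
    def scale(self) -> float:
        return float(np.sqrt(self.scale_sq))

    def interval(self, level: float) -> tuple[float, float]:
        return predictive_interval(self, level)

    def lower_bound(self, level: float) -> float:
        """One-sided lower bound: the ``1 - level`` quantile of the predictive.

        ``level`` is the probability that the truth exceeds the bound.
        """
        q = stats.t.ppf(1.0 - float(level), df=self.nu)
        return self.location + q * self.scale


def _robust_inv(M: np.ndarray) -> np.ndarray:
    """Symmetric inverse with trace-scaled jitter fallback for singular input."""
    M = np.asarray(M, dtype=float)
    P = M.shape[0]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            inv = np.linalg.inv(M)
            return 0.5 * (inv + inv.T)
    except (np.linalg.LinAlgError, Warning):
        jitter = _JITTER_REL * max(np.trace(M), P * np.finfo(float).tiny) / max(P, 1)
        jitter = max(jitter, _JITTER_REL)
        logger.warning("singular matrix: regularizing with jitter %.3e", jitter)
        inv = np.linalg.inv(M + jitter * np.eye(P))
        return 0.5 * (inv + inv.T)


def make_design(baseline: np.ndarray, dosages: np.ndarray) -> np.ndarray:
    """Assemble the n×P design matrix [baseline | dosages | 1] for one subject.

    Parameters
    ----------
    baseline : (L,) array
        Baseline latent-factor scores (constant across the subject's rows).
    dosages : (n, 4) array
        Equivalent daily doses per appointment (IR-MPH, XR-MPH, DEX, ATOM).

    Returns
    -------
    (n, L + 4 + 1) ndarray
    """
    b = np.asarray(baseline, dtype=float).ravel()
    M = np.atleast_2d(np.asarray(dosages, dtype=float))
    if M.size == 0:
        M = M.reshape(0, 4)
    if M.shape[1] != 4:
        raise DataError(f"dosage matrix must have 4 columns, got {M.shape[1]}")
    if not np.all(np.isfinite(b)) or not np.all(np.isfinite(M)):
        raise DataError("NaN or infinite values in baseline or dosages")
    n = M.shape[0]
    return np.hstack([np.tile(b, (n, 1)), M, np.ones((n, 1))])


def nig_update(state: NIGState, block: DesignBlock) -> NIGState:
    """Conjugate posterior update of an NIG state on a block of observations.

    Standard Normal–Inverse-Gamma recursion:

        Lambda_n = Lambda_0 + X'X
        tau_n    = Lambda_n^{-1} (Lambda_0 tau_0 + X'y)
        alpha_n  = alpha_0 + n/2
        beta_n   = beta_0 + (1/2) [ (y - X tau_n)'y + (tau_0 - tau_n)' Lambda_0 tau_0 ]

    (the beta update is the numerically stable rearrangement of
    ``y'y + tau_0' Lambda_0 tau_0 - tau_n' Lambda_n tau_n``).
    An empty block is the identity.
    """
    if block.n == 0:
        return state.copy()
    X, y = block.X, block.y
    if X.shape[1] != state.dim:
        raise DataError(f"design has {X.shape[1]} columns, state dimension is {state.dim}")
    lam0 = state.precision()
    lam_n = lam0 + X.T @ X
    rhs = lam0 @ state.tau + X.T @ y
    try:
        tau_n = np.linalg.solve(lam_n, rhs)
        lam_inv_n = np.linalg.inv(lam_n)
    except np.linalg.LinAlgError:
        lam_inv_n = _robust_inv(lam_n)
        tau_n = lam_inv_n @ rhs
    lam_inv_n = 0.5 * (lam_inv_n + lam_inv_n.T)
    alpha_n = state.alpha + block.n / 2.0
    beta_n = state.beta + 0.5 * (
        (y - X @ tau_n) @ y + (state.tau - tau_n) @ (lam0 @ state.tau)
    )
    if beta_n <= 0:  # exact-fit rounding; beta is positive in exact arithmetic
        logger.warning("beta underflow (%.3e); clamping", beta_n)
        beta_n = np.finfo(float).tiny ** 0.5
    # clip tiny negative eigenvalues produced by the explicit inverse
    w, V = np.linalg.eigh(lam_inv_n)
    if w[0] < 0:
        lam_inv_n = (V * np.clip(w, 0.0, None)) @ V.T
    return NIGState(tau_n, lam_inv_n, alpha_n, beta_n)


def posterior_predictive(state: NIGState, x: np.ndarray) -> PredictiveDistribution:
    """Student-t posterior predictive for a single design row ``x``."""
    x = np.asarray(x, dtype=float).ravel()
    if x.size != state.dim:
        raise DataError(f"x has {x.size} entries, state dimension is {state.dim}")
    location = float(x @ state.tau)
    scale_sq = (state.beta / state.alpha) * (1.0 + float(x @ state.lambda_inv @ x))
    return PredictiveDistribution(location, scale_sq, 2.0 * state.alpha)


def predictive_interval(dist: PredictiveDistribution, level: float) -> tuple[float, float]:
    """Central ``level`` interval of the location-scale t predictive."""
    level = float(level)
    if not 0.0 <= level < 1.0:
        raise ValueError(f"level must be in [0, 1), got {level}")
    if level == 0.0:
        return (dist.location, dist.location)
    half = stats.t.ppf(0.5 + level / 2.0, df=dist.nu) * dist.scale
    return (dist.location - half, dist.location + half)
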