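"""Virtual patient profiles: learning in the model space.

Each training subject is represented by their fitted posterior
``(tau_s, Lambda_s^{-1}, alpha_s, beta_s)`` — a point in model space.  For
a new patient only the baseline factor scores ``b*`` are known, so a
*virtual profile* (an NIG state usable as a personalized prior) is
estimated from the pool of fitted models:

* **Method 1** — linear regression from baselines to posterior
  parameters: ``Q = (B'B)^{-1} B'Y`` (Moore–Penrose least squares), with
  the covariance mapped through its half-vectorization and the
  inverse-gamma hyperparameters taken as pool averages.
* **Method 2** — Gaussian-kernel weighted averaging over the most similar
  training subjects: Euclidean baseline distances, the closest
  ``retain_fraction`` of subjects kept, weights ``w_s ∝ exp(-lambda d_s)``
  normalized to 1, and the profile taken as the weighted average of the
  retained posteriors.

Method 2 outputs are convex combinations of valid posteriors and hence
automatically valid; Method 1's linear reconstruction can leave the
covariance indefinite, so it is repaired by eigenvalue clipping.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from ._exceptions import ConfigurationError, DataError
from .nig import NIGState

logger = logging.getLogger(__name__)

__all__ = [
    "PatientModel",
    "ProfileMap",
    "KernelConfig",
    "half_vectorize",
    "reconstruct_symmetric",
    "psd_repair",
    "fit_method1",
    "apply_method1",
    "kernel_weights",
    "method2_profile",
]


@dataclass
class PatientModel:
    """A fitted training subject: baseline factors plus NIG posterior."""

    subject_id: str
    baseline: np.ndarray
    posterior: NIGState

    def __post_init__(self) -> None:
        self.baseline = np.asarray(self.baseline, float).ravel()
        self.posterior.validate()

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "baseline": self.baseline.tolist(),
            "posterior": self.posterior.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PatientModel":
        return cls(d["subject_id"], np.asarray(d["baseline"], float),
                   NIGState.from_dict(d["posterior"]))


@dataclass
class ProfileMap:
    """Method 1: least-squares maps from baseline space to model space.

    Q_tau is L×P (baseline -> posterior mean), Q_u is L×(P(P+1)/2)
    (baseline -> half-vectorized posterior covariance); alpha_star and
    beta_star are pool averages shared by all new patients.
    """

    Q_tau: np.ndarray
    Q_u: np.ndarray
    alpha_star: float
    beta_star: float

    def __post_init__(self) -> None:
        self.Q_tau = np.asarray(self.Q_tau, float)
        self.Q_u = np.asarray(self.Q_u, float)
        if not (self.alpha_star > 0 and self.beta_star > 0):
            raise ConfigurationError("alpha_star and beta_star must be positive")

    @property
    def P(self) -> int:
        return self.Q_tau.shape[1]


@dataclass(frozen=True)
class KernelConfig:
    """Method 2 kernel settings: weighting sharpness and retained fraction."""

    lam: float = 1.15
    retain_fraction: float = 0.175

    def __post_init__(self) -> None:
        if not self.lam > 0:
            raise ConfigurationError("kernel lambda must be positive")
        if not 0.0 < self.retain_fraction <= 1.0:
            raise ConfigurationError("retain_fraction must be in (0, 1]")


def half_vectorize(matrix: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Upper-triangular (row-major) half-vectorization of a symmetric matrix."""
    M = np.asarray(matrix, float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise DataError(f"expected a square matrix, got shape {M.shape}")
    scale = max(1.0, float(np.max(np.abs(M))) if M.size else 1.0)
    if np.max(np.abs(M - M.T)) > tol * scale:
        raise DataError("matrix is asymmetric beyond tolerance")
    iu = np.triu_indices(M.shape[0])
    return M[iu]


def reconstruct_symmetric(vector: np.ndarray, P: int | None = None) -> np.ndarray:
    """Inverse of :func:`half_vectorize`; exact round-trip."""
    v = np.asarray(vector, float).ravel()
    if P is None:
        P = int(round((math.isqrt(8 * v.size + 1) - 1) / 2))
    if v.size != P * (P + 1) // 2:
        raise DataError(f"vector length {v.size} does not match P = {P}")
    M = np.zeros((P, P))
    iu = np.triu_indices(P)
    M[iu] = v
    M = M + M.T - np.diag(np.diag(M))
    return M


def psd_repair(matrix: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    """Symmetrize and clip eigenvalues below ``floor`` up to ``floor``."""
    M = 0.5 * (np.asarray(matrix, float) + np.asarray(matrix, float).T)
    w, V = np.linalg.eigh(M)
    if w[0] >= floor:
        return M
    return (V * np.clip(w, floor, None)) @ V.T


def fit_method1(pool: list[PatientModel]) -> ProfileMap:
    """Fit the baseline->model-space linear maps from a pool of fitted models.

    Solves ``B Q = Y`` in the least-squares sense for Y = stacked posterior
    means and Y = stacked half-vectorized covariances; rank-deficient B is
    handled by SVD truncation (logged).  alpha_star/beta_star are the pool
    means of the subjects' inverse-gamma hyperparameters.
    """
    if len(pool) < 1:
        raise ConfigurationError("Method 1 needs a nonempty pool")
    B = np.vstack([m.baseline for m in pool])
    Y_tau = np.vstack([m.posterior.tau for m in pool])
    Y_u = np.vstack([half_vectorize(m.posterior.lambda_inv) for m in pool])
    Q_tau, _, rank, _ = np.linalg.lstsq(B, Y_tau, rcond=None)
    Q_u, _, _, _ = np.linalg.lstsq(B, Y_u, rcond=None)
    if rank < B.shape[1]:
        logger.warning(
            "baseline matrix is rank deficient (rank %d < L = %d); "
            "using the pseudo-inverse solution", rank, B.shape[1]
        )
    alpha_star = float(np.mean([m.posterior.alpha for m in pool]))
    beta_star = float(np.mean([m.posterior.beta for m in pool]))
    return ProfileMap(Q_tau, Q_u, alpha_star, beta_star)


def apply_method1(profile_map: ProfileMap, b_star: np.ndarray) -> NIGState:
    """Virtual profile for a new baseline via the fitted linear maps."""
    b = np.asarray(b_star, float).ravel()
    if b.size != profile_map.Q_tau.shape[0]:
        raise ConfigurationError(
            f"baseline length {b.size} does not match map input dim "
            f"{profile_map.Q_tau.shape[0]}"
        )
    tau = b @ profile_map.Q_tau
    lam_inv = psd_repair(reconstruct_symmetric(b @ profile_map.Q_u, profile_map.P))
    return NIGState(tau, lam_inv, profile_map.alpha_star, profile_map.beta_star)


def kernel_weights(distances: np.ndarray, lam: float) -> np.ndarray:
    """Normalized Gaussian-kernel weights ``exp(-lam d) / sum exp(-lam d')``."""
    d = np.asarray(distances, float).ravel()
    if d.size == 0:
        raise ConfigurationError("kernel_weights needs at least one distance")
    w = np.exp(-float(lam) * (d - d.min()))  # shift for numerical stability
    return w / w.sum()


def method2_profile(
    pool: list[PatientModel],
    b_star: np.ndarray,
    config: KernelConfig | None = None,
) -> NIGState:
    """Virtual profile by Gaussian-kernel weighted averaging over similar subjects.

    Euclidean distances from ``b_star`` to every pool baseline are sorted;
    the ``ceil(retain_fraction * pool size)`` nearest subjects are retained
    (ties at the boundary kept), given weights ``exp(-lambda d)`` normalized
    to sum to one, and their posteriors averaged component-wise.
    """
    if len(pool) < 1:
        raise ConfigurationError("Method 2 needs a nonempty pool")
    config = config or KernelConfig()
    b = np.asarray(b_star, float).ravel()
    d = np.array([float(np.linalg.norm(b - m.baseline)) for m in pool])
    k = max(1, math.ceil(config.retain_fraction * len(pool)))
    cutoff = np.sort(d)[k - 1]
    keep = np.flatnonzero(d <= cutoff)
    w = kernel_weights(d[keep], config.lam)
    tau = sum(wi * pool[i].posterior.tau for wi, i in zip(w, keep))
    lam_inv = sum(wi * pool[i].posterior.lambda_inv for wi, i in zip(w, keep))
    alpha = float(sum(wi * pool[i].posterior.alpha for wi, i in zip(w, keep)))
    beta = float(sum(wi * pool[i].posterior.beta for wi, i in zip(w, keep)))
    return NIGState(tau, lam_inv, alpha, beta)
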