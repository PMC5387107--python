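"""Synthetic longitudinal dose-titration cohorts.

Emulates the data structure produced by a forced-titration ADHD clinic:
each subject has L standardized baseline latent-factor scores, a course of
1–22 roughly weekly appointments during which the combined
equivalent-daily-dose (EDD) of medication ramps up stepwise over the first
~5 visits and then plateaus (with occasional switches between the four
medication types), and two continuous symptom scores per visit
(inattentiveness, hyperactivity) generated from the linear response model
``y = X omega_s + eps``.

The subject-specific response vectors ``omega_s`` are drawn around a
population mean with negative medication effects (medication lowers
symptom scores); an optional baseline-loading matrix makes ``omega_s`` an
exact linear function of the baseline factors, which is useful for
checking profile-construction fidelity.  Doses are expressed in units of
ten milligrams of IR-MPH-equivalent daily dose so that unit-scale
regression coefficients are commensurate with the sign-encoded ±1 prior.

Remission at a visit is a symptom score at or below the clinical
threshold (−0.97 inattentiveness, −0.92 hyperactivity); the default
configuration is calibrated so that roughly 14% of visits are remissions.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from ._exceptions import CalibrationError, ConfigurationError
from .nig import make_design

__all__ = [
    "DoseRamp",
    "CohortConfig",
    "Subject",
    "Cohort",
    "generate_cohort",
    "label_remission",
    "remission_prevalence",
    "calibrate_prevalence",
    "default_omega_mean",
    "default_omega_sd",
]

#: default remission thresholds (inattentiveness, hyperactivity)
REMISSION_THRESHOLDS = (-0.97, -0.92)

#: correlation between the two symptom dimensions' response vectors
_OMEGA_DIM_RHO = 0.7


@dataclass(frozen=True)
class DoseRamp:
    """Stepwise titration schedule template.

    targets: combined EDD (tens of mg IR-MPH-equivalent) per appointment;
    the last value repeats for later appointments.  Each subject scales the
    template by a factor drawn uniformly from ``subject_scale_range``.
    At each appointment after the first, the active medication switches to
    a different one of the four types with probability ``switch_prob``.
    """

    targets: tuple[float, ...] = (0.5, 1.0, 1.5, 2.25, 3.0)
    switch_prob: float = 0.1
    subject_scale_range: tuple[float, float] = (0.8, 1.2)

    def __post_init__(self) -> None:
        if len(self.targets) < 1:
            raise ConfigurationError("dose ramp needs at least one target")
        if any(t < 0 for t in self.targets):
            raise ConfigurationError("dose targets must be nonnegative")
        if not 0.0 <= self.switch_prob <= 1.0:
            raise ConfigurationError("switch_prob must be in [0, 1]")

    def target_at(self, appointment: int) -> float:
        """Combined EDD target at 1-based appointment number."""
        return self.targets[min(appointment - 1, len(self.targets) - 1)]


def default_omega_mean(n_factors: int = 14) -> np.ndarray:
    """Population mean of the response vector [factors | meds | intercept].

    Factor effects alternate in sign at magnitude 0.15 (standardized-score
    scale); medication effects are −0.5 per dose unit; the intercept of
    1.34 places untreated patients well above the remission thresholds and
    was calibrated once (via :func:`calibrate_prevalence`) so that default
    cohorts show ~14% visit-level remission.
    """
    factor_signs = np.array([+1, +1, -1, +1, -1, +1, +1, -1, +1, -1, +1, +1, -1, +1])
    signs = np.resize(factor_signs, n_factors)
    return np.concatenate([0.15 * signs, [-0.5, -0.5, -0.5, -0.5], [1.34]])


def default_omega_sd(n_factors: int = 14) -> np.ndarray:
    """Population spread of the response vector (between-subject heterogeneity)."""
    return np.concatenate([np.full(n_factors, 0.05), np.full(4, 0.1), [0.3]])


@dataclass
class CohortConfig:
    """Configuration of a synthetic titration cohort.

    omega entries are ordered [f01..fL, med_irmph, med_xrmph, med_dex,
    med_atom, intercept]; the four medication means must be <= 0
    (medication lowers symptom scores).  ``omega_baseline_map`` (P×L), if
    given, adds ``W @ b_s`` to each subject's response vector, making
    omega_s linear in the baseline.
    """

    n_subjects: int
    n_factors: int = 14
    appointment_range: tuple[int, int] = (1, 22)
    omega_population_mean: np.ndarray | None = None
    omega_population_sd: np.ndarray | None = None
    noise_sd: float = 0.5
    dose_ramp: DoseRamp = field(default_factory=DoseRamp)
    remission_thresholds: tuple[float, float] = REMISSION_THRESHOLDS
    seed: int = 0
    omega_baseline_map: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_factors < 1:
            raise ConfigurationError("n_subjects and n_factors must be positive")
        lo, hi = self.appointment_range
        if not (1 <= lo <= hi <= 22):
            raise ConfigurationError(
                f"appointment_range must satisfy 1 <= min <= max <= 22, got {lo, hi}"
            )
        if self.omega_population_mean is None:
            self.omega_population_mean = default_omega_mean(self.n_factors)
        if self.omega_population_sd is None:
            self.omega_population_sd = default_omega_sd(self.n_factors)
        self.omega_population_mean = np.asarray(self.omega_population_mean, float).ravel()
        self.omega_population_sd = np.asarray(self.omega_population_sd, float).ravel()
        P = self.P
        if self.omega_population_mean.size != P or self.omega_population_sd.size != P:
            raise ConfigurationError(
                f"omega population vectors must have length P = {P}"
            )
        if np.any(self.omega_population_sd < 0):
            raise ConfigurationError("omega_population_sd must be nonnegative")
        meds = self.omega_population_mean[self.n_factors : self.n_factors + 4]
        if np.any(meds > 0):
            raise ConfigurationError(
                "medication entries of omega_population_mean must be <= 0"
            )
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be nonnegative")
        if self.omega_baseline_map is not None:
            self.omega_baseline_map = np.asarray(self.omega_baseline_map, float)
            if self.omega_baseline_map.shape != (P, self.n_factors):
                raise ConfigurationError(
                    f"omega_baseline_map must be (P, L) = {(P, self.n_factors)}"
                )

    @property
    def P(self) -> int:
        """Parameter dimension L + 4 + 1."""
        return self.n_factors + 4 + 1


@dataclass
class Subject:
    """One simulated (or loaded) patient course.

    dosages is A×4 (EDD per medication type per appointment); outcomes is
    A×2 (inattentiveness, hyperactivity scores).  ``true_omega`` (P×2, one
    response vector per symptom dimension) is simulation ground truth and
    is absent for real data.
    """

    subject_id: str
    baseline: np.ndarray
    dosages: np.ndarray
    outcomes: np.ndarray
    true_omega: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.baseline = np.asarray(self.baseline, float).ravel()
        self.dosages = np.atleast_2d(np.asarray(self.dosages, float))
        self.outcomes = np.atleast_2d(np.asarray(self.outcomes, float))
        if self.dosages.shape[0] != self.outcomes.shape[0]:
            raise ConfigurationError(
                f"{self.subject_id}: dosage rows ({self.dosages.shape[0]}) != "
                f"outcome rows ({self.outcomes.shape[0]})"
            )
        if self.dosages.shape[0] < 1:
            raise ConfigurationError(f"{self.subject_id}: needs at least one appointment")
        if self.dosages.shape[1] != 4 or self.outcomes.shape[1] != 2:
            raise ConfigurationError(
                f"{self.subject_id}: dosages must be A×4 and outcomes A×2"
            )
        if np.any(self.dosages < 0):
            raise ConfigurationError(f"{self.subject_id}: negative dosages")
        if self.true_omega is not None:
            self.true_omega = np.asarray(self.true_omega, float)

    @property
    def n_appointments(self) -> int:
        return self.dosages.shape[0]

    def design(self) -> np.ndarray:
        """The subject's A×P design matrix [baseline | dosages | 1]."""
        return make_design(self.baseline, self.dosages)


@dataclass
class Cohort:
    """A list of subjects, plus the generating configuration when simulated.

    Cohorts loaded from disk have ``config=None``; the clinical default
    remission thresholds apply unless overridden.
    """

    subjects: list[Subject]
    config: CohortConfig | None = None
    thresholds: tuple[float, float] = REMISSION_THRESHOLDS

    @property
    def remission_thresholds(self) -> tuple[float, float]:
        if self.config is not None:
            return self.config.remission_thresholds
        return self.thresholds

    def __iter__(self) -> Iterator[Subject]:
        return iter(self.subjects)

    def __len__(self) -> int:
        return len(self.subjects)

    def __getitem__(self, i):
        return self.subjects[i]

    @property
    def n_visits(self) -> int:
        return sum(s.n_appointments for s in self.subjects)


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a seeded cohort with the configured titration structure.

    Deterministic for a fixed config: baselines are standard normal,
    response vectors are drawn around the population mean (optionally plus
    a linear baseline loading), doses follow the ramp template with
    Bernoulli medication switches, and outcomes are
    ``X omega_s + N(0, noise_sd^2)`` per symptom dimension.
    """
    rng = np.random.default_rng(config.seed)
    L, P = config.n_factors, config.P
    lo, hi = config.appointment_range
    width = len(str(config.n_subjects))
    subjects = []
    for i in range(config.n_subjects):
        baseline = rng.standard_normal(L)
        mean = config.omega_population_mean.copy()
        if config.omega_baseline_map is not None:
            mean = mean + config.omega_baseline_map @ baseline
        # correlated per-dimension deviations: the two symptom dimensions
        # respond similarly but not identically
        z_shared = rng.standard_normal(P)
        z_dim = rng.standard_normal((P, 2))
        dev = _OMEGA_DIM_RHO * z_shared[:, None] + np.sqrt(
            1.0 - _OMEGA_DIM_RHO**2
        ) * z_dim
        omega = mean[:, None] + config.omega_population_sd[:, None] * dev
        n_appt = int(rng.integers(lo, hi + 1))
        dosages = _simulate_doses(rng, config.dose_ramp, n_appt)
        X = make_design(baseline, dosages)
        noise = rng.standard_normal((n_appt, 2)) * config.noise_sd
        outcomes = X @ omega + noise
        subjects.append(
            Subject(
                subject_id=f"S{i + 1:0{width}d}",
                baseline=baseline,
                dosages=dosages,
                outcomes=outcomes,
                true_omega=omega,
            )
        )
    return Cohort(subjects, config)


def _simulate_doses(rng: np.random.Generator, ramp: DoseRamp, n_appt: int) -> np.ndarray:
    scale_lo, scale_hi = ramp.subject_scale_range
    mult = rng.uniform(scale_lo, scale_hi)
    active = 0  # IR-MPH is the first-line medication
    dosages = np.zeros((n_appt, 4))
    for a in range(1, n_appt + 1):
        if a > 1 and rng.random() < ramp.switch_prob:
            active = int(rng.choice([m for m in range(4) if m != active]))
        dosages[a - 1, active] = ramp.target_at(a) * mult
    return dosages


def label_remission(
    outcomes: np.ndarray, thresholds: Sequence[float] = REMISSION_THRESHOLDS
) -> np.ndarray:
    """Binary remission labels per visit and dimension: score <= threshold.

    The boundary is inclusive — a score exactly at the threshold counts as
    remission ("a mean item score of one or less").
    """
    outcomes = np.atleast_2d(np.asarray(outcomes, float))
    thresholds = np.asarray(thresholds, float).ravel()
    if not np.all(np.isfinite(thresholds)):
        raise ConfigurationError("remission thresholds must be finite")
    return (outcomes <= thresholds[None, :]).astype(int)


def remission_prevalence(cohort: Cohort) -> np.ndarray:
    """Visit-level remission fraction per symptom dimension."""
    labels = np.vstack(
        [label_remission(s.outcomes, cohort.remission_thresholds) for s in cohort]
    )
    return labels.mean(axis=0)


def calibrate_prevalence(
    config: CohortConfig,
    target_prevalence: float,
    n_trials: int = 20,
    bounds: tuple[float, float] = (-4.0, 4.0),
    tol: float = 0.02,
    max_iter: int = 40,
) -> CohortConfig:
    """Shift the intercept of the population response so that the simulated
    visit-level remission prevalence (averaged over dimensions and over
    ``n_trials`` seeds) is within ``tol`` of ``target_prevalence``.

    Prevalence is monotone decreasing in the intercept (a higher intercept
    raises symptom scores), so a bisection on the intercept shift suffices.
    Raises CalibrationError when the target is unreachable within bounds.
    """
    if not 0.0 < target_prevalence < 1.0:
        raise CalibrationError(
            f"target prevalence must be in (0, 1), got {target_prevalence}"
        )

    def shifted(delta: float) -> CohortConfig:
        mean = config.omega_population_mean.copy()
        mean[-1] += delta
        return dataclasses.replace(config, omega_population_mean=mean)

    def mean_prevalence(delta: float) -> float:
        cfg = shifted(delta)
        vals = []
        for t in range(n_trials):
            trial_cfg = dataclasses.replace(cfg, seed=int((cfg.seed + 1) * 1000 + t) % (2**31))
            vals.append(remission_prevalence(generate_cohort(trial_cfg)).mean())
        return float(np.mean(vals))

    lo, hi = bounds  # prevalence(lo) is the highest achievable, prevalence(hi) lowest
    p_lo, p_hi = mean_prevalence(lo), mean_prevalence(hi)
    if not (p_hi - tol <= target_prevalence <= p_lo + tol):
        raise CalibrationError(
            f"target {target_prevalence:.3f} outside achievable range "
            f"[{p_hi:.3f}, {p_lo:.3f}] for intercept shifts in {bounds}"
        )
    best_delta, best_err = 0.0, float("inf")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        p_mid = mean_prevalence(mid)
        err = abs(p_mid - target_prevalence)
        if err < best_err:
            best_delta, best_err = mid, err
        if err <= tol / 2:
            break
        if p_mid > target_prevalence:
            lo = mid  # too much remission -> raise intercept
        else:
            hi = mid
    if best_err > tol:
        raise CalibrationError(
            f"calibration did not converge: best error {best_err:.3f} > tol {tol}"
        )
    return shifted(best_delta)
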