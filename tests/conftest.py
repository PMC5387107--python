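import numpy as np
import pytest

import modelspace as ms


@pytest.fixture(scope="session")
def default_prior() -> ms.NIGState:
    """Elicited prior for the standard 19-column design."""
    return ms.build_prior(ms.default_evidence(), ms.default_parameter_names())


@pytest.fixture(scope="session")
def small_cohort() -> ms.Cohort:
    """A 40-subject default-configuration cohort, shared across tests."""
    return ms.generate_cohort(ms.CohortConfig(n_subjects=40, seed=42))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def structured_linear_cohort(
    n_subjects: int = 200, seed: int = 5
) -> tuple[ms.Cohort, ms.NIGState]:
    """Noiseless cohort whose fitted posteriors are linear in the baseline.

    Response vectors are exactly linear in b_s with effects routed through
    the IR-MPH response coefficient and the intercept (baseline and
    unused-medication coefficients structurally zero); the matching prior
    pins the structural zeros.  This is the well-specified regime for the
    linear profile map.
    """
    rng = np.random.default_rng(seed)
    L = 14
    P = L + 5
    W = np.zeros((P, L))
    W[L, :] = rng.normal(-0.15, 0.05, L)  # med response coefficient
    W[-1, :] = rng.normal(0.0, 0.3, L)  # untreated symptom level
    cfg = ms.CohortConfig(
        n_subjects=n_subjects,
        n_factors=L,
        appointment_range=(5, 15),
        omega_population_mean=np.zeros(P),
        omega_population_sd=np.zeros(P),
        noise_sd=0.0,
        dose_ramp=ms.DoseRamp(switch_prob=0.0),
        seed=seed,
        omega_baseline_map=W,
    )
    var = np.full(P, 1e-8)
    var[L] = 100.0
    var[-1] = 100.0
    prior = ms.NIGState(np.zeros(P), np.diag(var), 1.0, 1.0)
    return ms.generate_cohort(cfg), prior
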