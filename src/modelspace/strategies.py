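"""Sequential prediction regimes over a treatment course, and
patient-coherent cross-validation.

Three regimes quantify what each ingredient of the framework contributes:

* **AI** (appointment-independent): every appointment is predicted from
  the virtual patient profile alone, with no updating — as if each visit
  were the patient's first.
* **BR** (incremental Bayesian regression): appointment 1 is predicted
  from the virtual profile (identically to AI); appointment a >= 2 is
  predicted from the *elicited prior* batch-updated on appointments
  1..a−1.  The pool of fitted patients is deliberately unused after the
  first visit — this is the no-model-space benchmark.
* **BU** (incremental Bayesian update): appointment 1 as AI; the virtual
  profile is then sequentially updated with each observed outcome before
  predicting the next visit.

All three are prequential: the prediction at appointment a never uses the
outcome at appointment a or later.  Cross-validation is patient-coherent
(all of a subject's visits share one fold); pools and profile maps are
fitted on training folds only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

from ._exceptions import ConfigurationError
from .cohort import Cohort, Subject
from .nig import DesignBlock, NIGState, PredictiveDistribution, nig_update, posterior_predictive
from .profiles import (
    KernelConfig,
    PatientModel,
    apply_method1,
    fit_method1,
    method2_profile,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Strategy",
    "FoldAssignment",
    "CrossvalResult",
    "predict_course",
    "make_folds",
    "fit_pool",
    "run_crossval",
]

DIMENSION_NAMES = ("inattentiveness", "hyperactivity")


class Strategy(str, Enum):
    """Prediction regime over a subject's appointment course."""

    AI = "AI"
    BR = "BR"
    BU = "BU"


@dataclass(frozen=True)
class FoldAssignment:
    """Patient-coherent fold assignment: subject_id -> fold in 1..k."""

    mapping: dict[str, int]
    k: int
    seed: int

    def fold_of(self, subject_id: str) -> int:
        return self.mapping[subject_id]

    def validation_ids(self, fold: int) -> list[str]:
        return [s for s, f in self.mapping.items() if f == fold]

    def training_ids(self, fold: int) -> list[str]:
        return [s for s, f in self.mapping.items() if f != fold]


def make_folds(subject_ids: Sequence[str], k: int, seed: int) -> FoldAssignment:
    """Random patient-coherent folds with sizes differing by at most one."""
    ids = list(subject_ids)
    if len(set(ids)) != len(ids):
        raise ConfigurationError("duplicate subject ids")
    if not 1 <= k <= len(ids):
        raise ConfigurationError(f"k = {k} must be in [1, {len(ids)}]")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    mapping = {ids[j]: (pos % k) + 1 for pos, j in enumerate(order)}
    return FoldAssignment(mapping, k, seed)


def predict_course(
    subject: Subject,
    strategy: Strategy,
    virtual_profile: NIGState,
    elicited_prior: NIGState,
    dimension: int = 0,
) -> list[PredictiveDistribution]:
    """Predict every appointment of a subject's course under one regime.

    Returns one predictive distribution per appointment for the chosen
    symptom dimension (0 = inattentiveness, 1 = hyperactivity).
    Appointments with a missing (NaN) observed outcome are still
    predicted, but skipped when updating.
    """
    strategy = Strategy(strategy)
    X = subject.design()
    y = subject.outcomes[:, dimension]
    preds: list[PredictiveDistribution] = []
    if strategy is Strategy.AI:
        for a in range(subject.n_appointments):
            preds.append(posterior_predictive(virtual_profile, X[a]))
        return preds
    if strategy is Strategy.BU:
        state = virtual_profile
        for a in range(subject.n_appointments):
            preds.append(posterior_predictive(state, X[a]))
            if np.isfinite(y[a]):
                state = nig_update(state, DesignBlock(X[a : a + 1], y[a : a + 1]))
            else:
                logger.warning(
                    "%s: missing outcome at appointment %d; skipping update",
                    subject.subject_id, a + 1,
                )
        return preds
    # BR: first prediction from the virtual profile, then refit from the
    # elicited prior on all outcomes observed so far
    for a in range(subject.n_appointments):
        if a == 0:
            preds.append(posterior_predictive(virtual_profile, X[a]))
            continue
        seen = np.isfinite(y[:a])
        if not np.all(seen):
            logger.warning(
                "%s: missing outcomes before appointment %d; fitting on observed rows",
                subject.subject_id, a + 1,
            )
        state = nig_update(elicited_prior, DesignBlock(X[:a][seen], y[:a][seen]))
        preds.append(posterior_predictive(state, X[a]))
    return preds


def fit_pool(
    subjects: Sequence[Subject], prior: NIGState, dimension: int
) -> list[PatientModel]:
    """Fit one PatientModel per subject: batch NIG update of the elicited
    prior on all of the subject's appointments (one symptom dimension)."""
    pool = []
    for s in subjects:
        y = s.outcomes[:, dimension]
        seen = np.isfinite(y)
        posterior = nig_update(prior, DesignBlock(s.design()[seen], y[seen]))
        pool.append(PatientModel(s.subject_id, s.baseline, posterior))
    return pool


@dataclass
class CrossvalResult:
    """Per-appointment validation predictions plus the fitted fold pools.

    ``predictions`` has one row per (subject, appointment, dimension) with
    the observed score, the predictive location/scale/dof, and the fold.
    ``pools[(fold, dimension)]`` holds the training-subject models.
    """

    predictions: pd.DataFrame
    folds: FoldAssignment
    pools: dict[tuple[int, int], list[PatientModel]] = field(default_factory=dict)

    def subject_pairs(self, dimension: int) -> list[tuple[np.ndarray, np.ndarray]]:
        """Per-subject (y_true, y_hat) arrays for one dimension, for rms."""
        sub = self.predictions[self.predictions["dimension"] == dimension]
        return [
            (g["y_true"].to_numpy(), g["y_hat"].to_numpy())
            for _, g in sub.groupby("subject_id", sort=True)
        ]


def run_crossval(
    cohort: Cohort,
    prior: NIGState,
    k: int = 10,
    seed: int = 0,
    method: int = 2,
    strategy: Strategy | str = Strategy.BU,
    kernel_config: KernelConfig | None = None,
    dimensions: Sequence[int] = (0, 1),
) -> CrossvalResult:
    """Patient-coherent k-fold cross-validation of one strategy/method pair.

    For each fold, patient models are fitted on training subjects only, a
    virtual profile is built for every validation subject from the
    training pool (Method 1: linear map; Method 2: kernel averaging), and
    the course is predicted under the requested strategy.  Validation
    outcomes never influence pool fitting or profile construction.
    """
    strategy = Strategy(strategy)
    if method not in (1, 2):
        raise ConfigurationError(f"method must be 1 or 2, got {method}")
    subjects = {s.subject_id: s for s in cohort}
    folds = make_folds(sorted(subjects), k, seed)
    rows = []
    pools: dict[tuple[int, int], list[PatientModel]] = {}
    for fold in range(1, k + 1):
        train = [subjects[i] for i in sorted(folds.training_ids(fold))]
        val = [subjects[i] for i in sorted(folds.validation_ids(fold))]
        if not train:
            raise ConfigurationError(f"fold {fold} has an empty training set")
        for dim in dimensions:
            pool = fit_pool(train, prior, dim)
            pools[(fold, dim)] = pool
            profile_map = fit_method1(pool) if method == 1 else None
            for s in val:
                if method == 1:
                    profile = apply_method1(profile_map, s.baseline)
                else:
                    profile = method2_profile(pool, s.baseline, kernel_config)
                preds = predict_course(s, strategy, profile, prior, dim)
                for a, dist in enumerate(preds, start=1):
                    rows.append(
                        {
                            "subject_id": s.subject_id,
                            "appointment": a,
                            "dimension": dim,
                            "y_true": float(s.outcomes[a - 1, dim]),
                            "y_hat": dist.location,
                            "scale_sq": dist.scale_sq,
                            "nu": dist.nu,
                            "fold": fold,
                        }
                    )
    return CrossvalResult(pd.DataFrame(rows), folds, pools)
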