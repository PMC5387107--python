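"""End-to-end pipeline: simulate/load -> elicit prior -> cross-validate ->
classify remission -> metrics, plus the run manifest that makes a run
reproducible from its output directory alone.

Operating points (critical values) are selected per fold on the training
subjects' in-sample fitted predictions only, then applied unchanged to
that fold's validation predictions, so validation outcomes never tune the
classifier.  Confusion counts are pooled over folds; the ROC sweeps the
pooled validation predictions.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from ._exceptions import ConfigurationError
from .cohort import REMISSION_THRESHOLDS, Cohort
from .evidence import build_prior, default_evidence, default_parameter_names, read_evidence_csv
from .evaluate import (
    ConfusionMatrix,
    apply_operating_point,
    confusion_metrics,
    rms_error,
    roc_curve,
    select_operating_point,
)
from .io import read_cohort, write_pool, write_state
from .nig import NIGState, posterior_predictive
from .profiles import KernelConfig, PatientModel
from .strategies import (
    DIMENSION_NAMES,
    CrossvalResult,
    Strategy,
    fit_pool,
    run_crossval,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "run_pipeline",
    "evaluate_crossval",
    "training_predictions",
    "load_prior",
]


def load_prior(
    evidence_path: str | Path | None,
    n_factors: int = 14,
    alpha0: float = 1.0,
    beta0: float = 1.0,
) -> NIGState:
    """Elicited prior from an evidence CSV, or the default evidence table."""
    entries = read_evidence_csv(evidence_path) if evidence_path else default_evidence(n_factors)
    return build_prior(entries, default_parameter_names(n_factors), alpha0, beta0)


def training_predictions(
    pool: Sequence[PatientModel], subjects_by_id: dict, dimension: int
) -> pd.DataFrame:
    """In-sample predictions of each fitted training model on its own course."""
    rows = []
    for m in pool:
        s = subjects_by_id[m.subject_id]
        X = s.design()
        for a in range(s.n_appointments):
            dist = posterior_predictive(m.posterior, X[a])
            rows.append(
                {"subject_id": m.subject_id, "appointment": a + 1,
                 "y_true": float(s.outcomes[a, dimension]),
                 "y_hat": dist.location, "scale_sq": dist.scale_sq, "nu": dist.nu}
            )
    return pd.DataFrame(rows)


def evaluate_crossval(
    result: CrossvalResult,
    cohort: Cohort,
    thresholds: tuple[float, float] = REMISSION_THRESHOLDS,
    kind: str = "quantile",
) -> dict:
    """Regression and classification metrics from a cross-validation run.

    Returns a dict keyed by symptom dimension with rms, pooled confusion
    counts and derived metrics at the fold-wise training-optimal critical
    values, and the validation ROC/AUC.
    """
    subjects_by_id = {s.subject_id: s for s in cohort}
    out: dict = {}
    for dim, dim_name in enumerate(DIMENSION_NAMES):
        thr = thresholds[dim]
        preds = result.predictions[result.predictions["dimension"] == dim]
        if preds.empty:
            continue
        rms = rms_error(result.subject_pairs(dim))

        cms, ops = [], []
        val_pred_labels = []
        for fold in sorted(preds["fold"].unique()):
            pool = result.pools.get((fold, dim))
            fold_val = preds[preds["fold"] == fold]
            y_val = (fold_val["y_true"].to_numpy() <= thr).astype(int)
            if pool is None:
                continue
            train = training_predictions(pool, subjects_by_id, dim)
            y_train = (train["y_true"].to_numpy() <= thr).astype(int)
            if y_train.all() or not y_train.any():
                logger.warning("fold %s has single-class training labels; using c = 0",
                               fold)
                op = None
            else:
                op = select_operating_point(
                    train["y_hat"].to_numpy(), y_train, thr, kind=kind,
                    scale_sq=train["scale_sq"].to_numpy(), nu=train["nu"].to_numpy(),
                )
            if op is None:
                pred_labels = (fold_val["y_hat"].to_numpy() <= thr).astype(int)
            else:
                pred_labels = apply_operating_point(
                    op, fold_val["y_hat"].to_numpy(),
                    scale_sq=fold_val["scale_sq"].to_numpy(),
                    nu=fold_val["nu"].to_numpy(),
                )
                ops.append({"fold": int(fold), "critical_value": op.critical_value,
                            "kind": op.kind})
            cms.append(ConfusionMatrix.from_labels(y_val, pred_labels))
            val_pred_labels.append(pred_labels)

        pooled = ConfusionMatrix(
            tp=sum(c.tp for c in cms), fp=sum(c.fp for c in cms),
            fn=sum(c.fn for c in cms), tn=sum(c.tn for c in cms),
        )
        y_all = (preds["y_true"].to_numpy() <= thr).astype(int)
        roc = None
        if 0 < y_all.sum() < y_all.size:
            roc = roc_curve(
                preds["y_hat"].to_numpy(), y_all, thr, kind=kind,
                scale_sq=preds["scale_sq"].to_numpy(), nu=preds["nu"].to_numpy(),
            )
        out[dim_name] = {
            "rms": rms,
            "threshold": thr,
            "prevalence": float(y_all.mean()),
            "confusion": dataclasses.asdict(pooled),
            "metrics": confusion_metrics(pooled),
            "operating_points": ops,
            "auc": roc.auc if roc is not None else None,
            "roc_points": roc.points if roc is not None else None,
        }
    return out


@dataclass
class RunConfig:
    """Configuration of a full crossval + evaluation run."""

    visits: str
    baselines: str
    outdir: str
    evidence: str | None = None
    method: int = 2
    strategy: str = "BU"
    k: int = 10
    seed: int = 0
    kernel_lambda: float = 1.15
    retain_fraction: float = 0.175
    threshold_ina: float = REMISSION_THRESHOLDS[0]
    threshold_hyp: float = REMISSION_THRESHOLDS[1]
    critical_value_kind: str = "quantile"
    alpha0: float = 1.0
    beta0: float = 1.0

    def __post_init__(self) -> None:
        if self.method not in (1, 2):
            raise ConfigurationError("method must be 1 or 2")
        Strategy(self.strategy)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full pipeline and write artifacts under ``config.outdir``.

    Writes predictions.csv, metrics.json, roc_<dim>.tsv, prior.json,
    pool_<dim>.jsonl (fitted on all subjects, for future profile use) and
    manifest.json.  Deterministic for a fixed config.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = read_cohort(config.visits, config.baselines)
    L = cohort.subjects[0].baseline.size
    prior = load_prior(config.evidence, L, config.alpha0, config.beta0)
    write_state(prior, outdir / "prior.json")

    result = run_crossval(
        cohort, prior, k=config.k, seed=config.seed, method=config.method,
        strategy=config.strategy,
        kernel_config=KernelConfig(config.kernel_lambda, config.retain_fraction),
    )
    thresholds = (config.threshold_ina, config.threshold_hyp)
    preds = result.predictions.copy()
    # attach central 95% intervals for downstream plotting
    from scipy import stats as _stats

    half = _stats.t.ppf(0.975, preds["nu"]) * np.sqrt(preds["scale_sq"])
    preds["ci_low"] = preds["y_hat"] - half
    preds["ci_high"] = preds["y_hat"] + half
    preds.to_csv(outdir / "predictions.csv", index=False)

    report = evaluate_crossval(result, cohort, thresholds, config.critical_value_kind)
    for dim, dim_name in enumerate(DIMENSION_NAMES):
        if dim_name not in report:
            continue
        pts = report[dim_name].pop("roc_points", None)
        if pts:
            pd.DataFrame(pts, columns=["fpr", "tpr"]).to_csv(
                outdir / f"roc_{dim_name[:3]}.tsv", sep="\t", index=False
            )
        pool = fit_pool(cohort.subjects, prior, dim)
        write_pool(pool, outdir / f"pool_{dim_name[:3]}.jsonl")

    (outdir / "metrics.json").write_text(
        json.dumps(report, indent=1, sort_keys=True) + "\n"
    )
    manifest = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "n_subjects": len(cohort.subjects),
        "n_visits": cohort.n_visits,
        "folds": {sid: int(f) for sid, f in sorted(result.folds.mapping.items())},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return report
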