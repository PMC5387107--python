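"""Cohort table and model-state file I/O.

Cohorts travel as two CSVs: a long visits table (one row per subject ×
appointment with the four EDD dose columns and the two symptom scores)
and a wide baselines table (one row per subject with the factor scores).
NIG states serialize to JSON; patient-model pools to JSON lines.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from ._exceptions import SchemaError
from .cohort import Cohort, Subject
from .nig import NIGState
from .profiles import PatientModel

__all__ = [
    "VISIT_COLUMNS",
    "write_cohort",
    "read_cohort",
    "write_state",
    "read_state",
    "write_pool",
    "read_pool",
]

VISIT_COLUMNS = [
    "subject_id",
    "appointment",
    "dose_irmph",
    "dose_xrmph",
    "dose_dex",
    "dose_atom",
    "score_ina",
    "score_hyp",
]
_DOSE_COLUMNS = VISIT_COLUMNS[2:6]
_SCORE_COLUMNS = VISIT_COLUMNS[6:8]


def write_cohort(cohort: Cohort, outdir: str | Path) -> dict[str, Path]:
    """Write visits.csv, baselines.csv and (when ground truth exists)
    truth.csv under ``outdir``; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    L = cohort.subjects[0].baseline.size
    visit_rows, truth_rows = [], []
    base_rows = []
    for s in cohort:
        base_rows.append(
            {"subject_id": s.subject_id,
             **{f"f{i + 1:02d}": s.baseline[i] for i in range(L)}}
        )
        for a in range(s.n_appointments):
            visit_rows.append(
                dict(zip(VISIT_COLUMNS,
                         [s.subject_id, a + 1, *s.dosages[a], *s.outcomes[a]]))
            )
        if s.true_omega is not None:
            for dim in range(s.true_omega.shape[1]):
                truth_rows.append(
                    {"subject_id": s.subject_id, "dimension": dim,
                     **{f"w{j + 1:02d}": s.true_omega[j, dim]
                        for j in range(s.true_omega.shape[0])}}
                )
    paths = {
        "visits": outdir / "visits.csv",
        "baselines": outdir / "baselines.csv",
    }
    pd.DataFrame(visit_rows).to_csv(paths["visits"], index=False)
    pd.DataFrame(base_rows).to_csv(paths["baselines"], index=False)
    if truth_rows:
        paths["truth"] = outdir / "truth.csv"
        pd.DataFrame(truth_rows).to_csv(paths["truth"], index=False)
    return paths


def read_cohort(visits_path: str | Path, baselines_path: str | Path) -> Cohort:
    """Read and validate a cohort from its visits and baselines tables.

    Subjects are returned sorted by id with appointments sorted by index.
    Schema violations (missing columns, duplicate subject/appointment
    pairs, negative doses, non-contiguous appointment indices, visits for
    a subject missing from the baselines table) raise SchemaError with the
    offending row numbers (1-based, excluding the header).
    """
    visits = pd.read_csv(visits_path)
    baselines = pd.read_csv(baselines_path)

    missing = [c for c in VISIT_COLUMNS if c not in visits.columns]
    if missing:
        raise SchemaError(f"{visits_path}: missing columns {missing}")
    if "subject_id" not in baselines.columns:
        raise SchemaError(f"{baselines_path}: missing subject_id column")
    factor_cols = sorted(
        c for c in baselines.columns
        if c != "subject_id" and c.startswith("f") and c[1:].isdigit()
    )
    if not factor_cols:
        raise SchemaError(f"{baselines_path}: no factor columns (f01, f02, ...)")

    dup = visits.duplicated(subset=["subject_id", "appointment"])
    if dup.any():
        rows = (visits.index[dup] + 1).tolist()
        raise SchemaError(f"{visits_path}: duplicate (subject, appointment) rows {rows}")
    neg = (visits[_DOSE_COLUMNS] < 0).any(axis=1)
    if neg.any():
        rows = (visits.index[neg] + 1).tolist()
        raise SchemaError(f"{visits_path}: negative doses at rows {rows}")
    dup_b = baselines.duplicated(subset=["subject_id"])
    if dup_b.any():
        rows = (baselines.index[dup_b] + 1).tolist()
        raise SchemaError(f"{baselines_path}: duplicate subject rows {rows}")

    base_map = {
        str(r["subject_id"]): np.array([r[c] for c in factor_cols], float)
        for _, r in baselines.iterrows()
    }
    unknown = ~visits["subject_id"].astype(str).isin(base_map)
    if unknown.any():
        rows = (visits.index[unknown] + 1).tolist()
        raise SchemaError(
            f"{visits_path}: rows {rows} reference subjects absent from baselines"
        )

    subjects = []
    for sid, g in visits.groupby(visits["subject_id"].astype(str), sort=True):
        g = g.sort_values("appointment")
        appts = g["appointment"].to_numpy()
        if not np.array_equal(appts, np.arange(1, len(appts) + 1)):
            raise SchemaError(
                f"{visits_path}: subject {sid} appointment indices {appts.tolist()} "
                f"are not contiguous 1..{len(appts)}"
            )
        subjects.append(
            Subject(
                subject_id=sid,
                baseline=base_map[sid],
                dosages=g[_DOSE_COLUMNS].to_numpy(float),
                outcomes=g[_SCORE_COLUMNS].to_numpy(float),
            )
        )
    return Cohort(subjects, config=None)


def write_state(state: NIGState, path: str | Path) -> None:
    Path(path).write_text(json.dumps(state.to_dict(), indent=1) + "\n")


def read_state(path: str | Path) -> NIGState:
    return NIGState.from_dict(json.loads(Path(path).read_text()))


def write_pool(pool: list[PatientModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in pool:
            fh.write(json.dumps(m.to_dict()) + "\n")


def read_pool(path: str | Path) -> list[PatientModel]:
    pool = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                pool.append(PatientModel.from_dict(json.loads(line)))
    return pool
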