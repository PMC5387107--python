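"""Prior elicitation from a structured literature-evidence table.

Quantitative effect sizes from heterogeneous studies cannot be pooled
directly, so only the *direction* of each association with the symptom
score is encoded in the prior mean: −1 for effects that lower symptoms
(all four medications), +1 for positive associations.  Evidence quality
moves the prior variance: each qualifying contradicting study adds 0.5 to
the initial unit variance; otherwise each supporting study subtracts 0.1,
floored at 0.5.  Declared causal links between parameters control which
off-diagonal covariance entries may be nonzero (the sparsity pattern);
their magnitudes default to 0 and may be supplied explicitly.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._exceptions import ConfigurationError, DataError
from .nig import NIGState

__all__ = [
    "EvidenceEntry",
    "build_prior",
    "default_parameter_names",
    "default_evidence",
    "read_evidence_csv",
    "write_evidence_csv",
]

MEDICATION_COLUMNS = ("med_irmph", "med_xrmph", "med_dex", "med_atom")
INTERCEPT_COLUMN = "intercept"


@dataclass
class EvidenceEntry:
    """Appraised literature evidence for one design column.

    direction is the sign of the association with the symptom score
    (−1 = lowers symptoms, as for effective medication); counts are the
    numbers of quality-qualifying supporting / contradicting studies.
    """

    parameter_name: str
    direction: int
    n_supporting: int = 0
    n_contradicting: int = 0
    causally_linked_to: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.direction = int(self.direction)
        if self.direction not in (-1, 1):
            raise ConfigurationError(
                f"direction must be +1 or -1, got {self.direction} for "
                f"{self.parameter_name!r}"
            )
        self.n_supporting = int(self.n_supporting)
        self.n_contradicting = int(self.n_contradicting)
        if self.n_supporting < 0 or self.n_contradicting < 0:
            raise ConfigurationError("study counts must be nonnegative")
        self.causally_linked_to = tuple(self.causally_linked_to)

    @property
    def prior_variance(self) -> float:
        """Diagonal prior variance implied by the evidence-quality rules."""
        if self.n_contradicting > 0:
            return 1.0 + 0.5 * self.n_contradicting
        return max(1.0 - 0.1 * self.n_supporting, 0.5)


def default_parameter_names(n_factors: int = 14) -> list[str]:
    """Design-column names: f01..fL, four medications, intercept."""
    return (
        [f"f{i:02d}" for i in range(1, n_factors + 1)]
        + list(MEDICATION_COLUMNS)
        + [INTERCEPT_COLUMN]
    )


def build_prior(
    evidence: Iterable[EvidenceEntry],
    parameter_names: Sequence[str],
    alpha0: float = 1.0,
    beta0: float = 1.0,
    link_values: Mapping[tuple[str, str], float] | None = None,
) -> NIGState:
    """Construct the elicited NIG prior for the given design columns.

    Parameters
    ----------
    evidence : iterable of EvidenceEntry
        At most one entry per design column.  Columns without an entry get
        an uninformed default: prior mean 0, variance 1.
    parameter_names : sequence of str
        The P design-column names, fixing coordinate order
        (baseline factors, medications, intercept).
    alpha0, beta0 : float
        Inverse-Gamma hyperparameters of the noise-variance prior.
    link_values : mapping (name, name) -> float, optional
        Magnitudes for off-diagonal covariance entries.  Every supplied pair
        must be declared in some entry's ``causally_linked_to``; undeclared
        off-diagonals stay exactly 0.

    Returns
    -------
    NIGState with tau = signed unit means and diagonal-dominant covariance.
    """
    names = list(parameter_names)
    P = len(names)
    index = {name: i for i, name in enumerate(names)}
    if len(index) != P:
        raise ConfigurationError("duplicate parameter names")
    if not (alpha0 > 0 and beta0 > 0):
        raise ConfigurationError("alpha0 and beta0 must be positive")

    tau = np.zeros(P)
    variances = np.ones(P)
    declared_links: set[frozenset[str]] = set()
    seen: set[str] = set()
    for entry in evidence:
        if entry.parameter_name not in index:
            raise ConfigurationError(
                f"evidence entry {entry.parameter_name!r} is not a design column"
            )
        if entry.parameter_name in seen:
            raise ConfigurationError(
                f"duplicate evidence entry for {entry.parameter_name!r}"
            )
        seen.add(entry.parameter_name)
        i = index[entry.parameter_name]
        tau[i] = float(entry.direction)
        variances[i] = entry.prior_variance
        for other in entry.causally_linked_to:
            if other not in index:
                raise ConfigurationError(
                    f"causal link target {other!r} of {entry.parameter_name!r} "
                    "is not a design column"
                )
            declared_links.add(frozenset((entry.parameter_name, other)))

    lam_inv = np.diag(variances)
    if link_values:
        for (a, b), value in link_values.items():
            if frozenset((a, b)) not in declared_links:
                raise ConfigurationError(
                    f"off-diagonal ({a}, {b}) supplied without a declared causal link"
                )
            i, j = index[a], index[b]
            lam_inv[i, j] = lam_inv[j, i] = float(value)
        eigmin = float(np.linalg.eigvalsh(lam_inv)[0])
        if eigmin < -1e-10:
            raise DataError(
                f"supplied causal-link magnitudes make the prior covariance "
                f"indefinite (min eigenvalue {eigmin:g})"
            )
    return NIGState(tau, lam_inv, alpha0, beta0)


def default_evidence(n_factors: int = 14) -> list[EvidenceEntry]:
    """Illustrative default evidence table for the standard 19-column design.

    The four medications lower symptom scores (direction −1) with several
    supporting trials each; baseline factors carry mixed signs and sparser,
    sometimes contradicting, observational evidence.  These defaults are a
    configurable stand-in for a study-specific rapid-review table, not a
    reproduction of any particular review.
    """
    entries = [
        EvidenceEntry("med_irmph", -1, n_supporting=5),
        EvidenceEntry("med_xrmph", -1, n_supporting=4),
        EvidenceEntry("med_dex", -1, n_supporting=3),
        EvidenceEntry("med_atom", -1, n_supporting=3),
        EvidenceEntry(INTERCEPT_COLUMN, +1),
    ]
    # baseline severity-like factors associate positively with symptoms;
    # protective factors negatively; a few have contradicting literature
    factor_specs = [
        (+1, 2, 0), (+1, 1, 0), (-1, 1, 0), (+1, 0, 1), (-1, 0, 0),
        (+1, 3, 0), (+1, 0, 2), (-1, 1, 0), (+1, 2, 0), (-1, 0, 1),
        (+1, 0, 0), (+1, 1, 0), (-1, 0, 0), (+1, 1, 1),
    ]
    for i in range(1, n_factors + 1):
        direction, sup, con = factor_specs[(i - 1) % len(factor_specs)]
        entries.append(
            EvidenceEntry(f"f{i:02d}", direction, n_supporting=sup, n_contradicting=con)
        )
    return entries


def read_evidence_csv(path: str | Path) -> list[EvidenceEntry]:
    """Read an evidence table (parameter_name, direction, n_supporting,
    n_contradicting, links) where links is a semicolon-separated list."""
    entries = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            links = tuple(x for x in (row.get("links") or "").split(";") if x)
            entries.append(
                EvidenceEntry(
                    parameter_name=row["parameter_name"],
                    direction=int(row["direction"]),
                    n_supporting=int(row.get("n_supporting") or 0),
                    n_contradicting=int(row.get("n_contradicting") or 0),
                    causally_linked_to=links,
                )
            )
    return entries


def write_evidence_csv(entries: Iterable[EvidenceEntry], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["parameter_name", "direction", "n_supporting", "n_contradicting", "links"]
        )
        for e in entries:
            writer.writerow(
                [e.parameter_name, e.direction, e.n_supporting, e.n_contradicting,
                 ";".join(e.causally_linked_to)]
            )
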