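"""Posterior-likelihood abruption scoring and outlier scanning.

Each observed transition gets the -log10 of the product of its children's
plug-in conditional densities.  The resulting values are converted to
z-scores across the scanned transitions, and a transition is flagged when
its one-sided upper-tail normal p-value falls below alpha / m (m defaults
to the number of subjects).  A subject is flagged when at least one of its
transitions is flagged; the two-stage protocol rescans after excluding
previously flagged subjects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from tsdbn.cgbn_core import FittedDBN, conditional_log_density
from tsdbn.data_io import TARGET_SUFFIX, TransitionTable
from tsdbn.errors import InsufficientDataError
from tsdbn.prediction_eval import source_assignment

LOG10_E = math.log10(math.e)


@dataclass
class AbruptionRecord:
    """One scored transition."""

    subject_id: str
    target_day: int
    neglog10_likelihood: float
    z_score: float
    flagged: bool


@dataclass
class AbruptionReport:
    """All scored transitions plus the flagged-subject list."""

    records: list[AbruptionRecord]
    flagged_subjects: list[str]
    alpha: float
    m: int
    mean: float
    sd: float
    excluded_subjects: list[str] = field(default_factory=list)

    @property
    def threshold_p(self) -> float:
        return self.alpha / self.m

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": [r.subject_id for r in self.records],
                "target_day": [r.target_day for r in self.records],
                "neglog10_likelihood": [
                    r.neglog10_likelihood for r in self.records
                ],
                "z_score": [r.z_score for r in self.records],
                "flagged": [r.flagged for r in self.records],
            }
        )


def transition_log_density(
    fitted: FittedDBN, source: Mapping[str, object], target: Mapping[str, object]
) -> float:
    """Natural-log plug-in density of the t+1 values given the t values."""
    total = 0.0
    for child in fitted.children:
        total += conditional_log_density(fitted, child, target[child], source)
    return total


def sample_neglog10_likelihood(fitted: FittedDBN, pair) -> float:
    """-log10 posterior likelihood of one transition.

    ``pair`` is either a (source assignment, target assignment) tuple of
    variable mappings, or a row of a :class:`TransitionTable` frame handled
    by :func:`scan_table`.
    """
    source, target = pair
    return -transition_log_density(fitted, source, target) * LOG10_E


def neglog10_values(fitted: FittedDBN, table: TransitionTable) -> np.ndarray:
    """-log10 transition likelihood for every row of a transition table."""
    values = np.empty(table.n_pairs)
    for i, (_, row) in enumerate(table.frame.iterrows()):
        source = source_assignment(table, row)
        target = {c: row[c + TARGET_SUFFIX] for c in fitted.children}
        values[i] = sample_neglog10_likelihood(fitted, (source, target))
    return values


def flag_threshold_z(alpha: float, m: int) -> float:
    """z above which the one-sided upper-tail p-value drops below alpha/m."""
    return float(stats.norm.isf(alpha / m))


def abruption_scan(
    fitted: FittedDBN,
    table: TransitionTable,
    alpha: float = 0.05,
    m: int | None = None,
    exclusions: Sequence[str] = (),
) -> AbruptionReport:
    """Flag statistically unlikely transitions and their host subjects.

    z-scores use the mean and standard deviation of the included
    transitions' -log10 likelihoods; a record is flagged when its one-sided
    upper-tail normal p-value is below ``alpha / m``.  ``m`` defaults to the
    number of included subjects.  ``exclusions`` removes subjects before the
    distribution is formed (second pass of the two-stage protocol).
    """
    keep = ~table.frame["subject_id"].astype(str).isin(set(map(str, exclusions)))
    sub = table.subset(keep.to_numpy())
    if sub.n_pairs == 0:
        raise InsufficientDataError("no transitions left after exclusions")
    if m is None:
        m = int(sub.frame["subject_id"].nunique())
    values = neglog10_values(fitted, sub)
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if len(values) > 1 else 0.0
    if sd == 0.0:
        raise InsufficientDataError(
            "degenerate distribution: zero variance across transitions"
        )
    z = (values - mean) / sd
    p = stats.norm.sf(z)
    flagged = p < alpha / m
    records = [
        AbruptionRecord(
            subject_id=str(row["subject_id"]),
            target_day=int(row["target_day"]),
            neglog10_likelihood=float(values[i]),
            z_score=float(z[i]),
            flagged=bool(flagged[i]),
        )
        for i, (_, row) in enumerate(sub.frame.iterrows())
    ]
    flagged_subjects = sorted({r.subject_id for r in records if r.flagged})
    return AbruptionReport(
        records=records,
        flagged_subjects=flagged_subjects,
        alpha=alpha,
        m=m,
        mean=mean,
        sd=sd,
        excluded_subjects=list(map(str, exclusions)),
    )


def two_stage_scan(
    fitted: FittedDBN,
    table: TransitionTable,
    alpha: float = 0.05,
    m: int | None = None,
) -> tuple[AbruptionReport, AbruptionReport]:
    """First scan, then rescan with the flagged subjects excluded."""
    first = abruption_scan(fitted, table, alpha=alpha, m=m)
    second = abruption_scan(
        fitted, table, alpha=alpha, m=m, exclusions=first.flagged_subjects
    )
    return first, second
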