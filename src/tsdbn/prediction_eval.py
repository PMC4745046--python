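"""One-step prediction, composition normalization and evaluation protocols.

Prediction uses the CLG conditional expectation for continuous children and
the argmax of the Dirichlet-multinomial predictive for discrete children.
Predicted taxa are clipped to zero and renormalized to a composition over
the selected taxa; mean absolute error is computed on that composition
against the observed composition renormalized over the same taxa.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from tsdbn.cgbn_core import (
    DBNStructure,
    FittedDBN,
    PriorHyperparameters,
    conditional_mean,
    fit_parameters,
)
from tsdbn.data_io import (
    SOURCE_SUFFIX,
    TARGET_SUFFIX,
    CohortTable,
    TransitionTable,
    build_transition_table,
)
from tsdbn.errors import IncompleteEvidenceError, InsufficientDataError
from tsdbn.structure_search import hill_climb

logger = logging.getLogger(__name__)


@dataclass
class PredictionRecord:
    """One predicted transition with its composition error."""

    subject_id: str
    target_day: int
    gap_days: int
    predicted: dict[str, float]
    observed: dict[str, float]
    mae: float


def predict_next(
    fitted: FittedDBN, source: Mapping[str, object]
) -> dict[str, object]:
    """Raw predicted value per child node from a slice-t assignment.

    Continuous children get alpha(u) + beta(u).v; discrete children get the
    most probable state of the predictive distribution.
    """
    out: dict[str, object] = {}
    for child in fitted.children:
        spec = fitted.structure.node(child)
        if spec.kind == "continuous":
            out[child] = conditional_mean(fitted, child, source)
        else:
            probs = fitted.discrete_params[child].predictive(source)
            out[child] = max(sorted(probs), key=lambda s: probs[s])
    return out


def normalize_prediction(
    raw: Mapping[str, float], taxa: Sequence[str]
) -> dict[str, float]:
    """Clip negatives to zero and renormalize over the selected taxa.

    If everything is <= 0 the uniform profile is returned (and a warning
    logged), so downstream consumers always see a valid composition.
    """
    if not taxa:
        raise ValueError("taxa must be nonempty")
    vals = np.array([max(float(raw.get(t, 0.0)), 0.0) for t in taxa])
    total = vals.sum()
    if total <= 0:
        logger.warning("all predicted values <= 0; returning uniform profile")
        vals = np.full(len(taxa), 1.0 / len(taxa))
    else:
        vals = vals / total
    return dict(zip(taxa, vals))


def _observed_composition(
    table: TransitionTable, row: pd.Series, taxa: Sequence[str]
) -> dict[str, float]:
    vals = np.array([float(row[t + TARGET_SUFFIX]) for t in taxa])
    total = vals.sum()
    if total <= 0:
        vals = np.full(len(taxa), 1.0 / len(taxa))
    else:
        vals = vals / total
    return dict(zip(taxa, vals))


def source_assignment(table: TransitionTable, row: pd.Series) -> dict[str, object]:
    """Slice-t variable assignment for one transition row."""
    out: dict[str, object] = {}
    for name in table.taxa + list(table.continuous_covariates):
        out[name] = float(row[name + SOURCE_SUFFIX])
    for name in table.discrete_covariates:
        out[name] = str(row[name + SOURCE_SUFFIX])
    return out


def predict_transitions(
    fitted: FittedDBN, table: TransitionTable, taxa: Sequence[str]
) -> list[PredictionRecord]:
    """Predict every transition of a table; MAE over the selected taxa."""
    records = []
    for _, row in table.frame.iterrows():
        raw = predict_next(fitted, source_assignment(table, row))
        predicted = normalize_prediction(
            {t: raw[t] for t in taxa if t in raw}, taxa
        )
        observed = _observed_composition(table, row, taxa)
        mae = float(
            np.mean([abs(predicted[t] - observed[t]) for t in taxa])
        )
        records.append(
            PredictionRecord(
                subject_id=str(row["subject_id"]),
                target_day=int(row["target_day"]),
                gap_days=int(row["gap_days"]),
                predicted=predicted,
                observed=observed,
                mae=mae,
            )
        )
    return records


def records_frame(records: Sequence[PredictionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "target_day": [r.target_day for r in records],
            "gap_days": [r.gap_days for r in records],
            "mae": [r.mae for r in records],
        }
    )


def per_subject_mae(records: Sequence[PredictionRecord]) -> pd.Series:
    """Mean of per-sample MAE within each subject."""
    frame = records_frame(records)
    return frame.groupby("subject_id")["mae"].mean()


def evaluate_loso(
    cohort: CohortTable,
    priors: PriorHyperparameters,
    structure: DBNStructure | None = None,
    taxa: Sequence[str] | None = None,
    relearn_structure: bool = False,
) -> tuple[pd.Series, list[PredictionRecord]]:
    """Leave-one-subject-out evaluation.

    For each held-out subject the CLG parameters are refit on the remaining
    subjects' transitions (structure fixed from the all-data search unless
    ``relearn_structure``); every non-first sample of the held-out subject
    is then predicted from its predecessor.  Returns (per-subject mean MAE,
    all prediction records).  Subjects with fewer than two samples
    contribute no predictions and are dropped with a logged notice.
    """
    subjects = cohort.subject_ids
    if len(subjects) < 2:
        raise InsufficientDataError("leave-one-subject-out needs >= 2 subjects")
    table = build_transition_table(cohort)
    if structure is None:
        structure, _ = hill_climb(table, priors)
    if taxa is None:
        from tsdbn.data_io import select_taxa

        taxa = select_taxa(cohort, structure, min_fraction=0.01)

    all_records: list[PredictionRecord] = []
    subj_col = table.frame["subject_id"].to_numpy()
    for subject in subjects:
        test_mask = subj_col == subject
        if not test_mask.any():
            logger.info("subject %s has < 2 samples; skipped", subject)
            continue
        train = table.subset(~test_mask)
        test = table.subset(test_mask)
        fold_structure = structure
        if relearn_structure:
            fold_structure, _ = hill_climb(train, priors)
        fitted = fit_parameters(fold_structure, train, priors)
        all_records.extend(predict_transitions(fitted, test, taxa))
    return per_subject_mae(all_records), all_records


def assign_folds(
    subjects: Sequence[str], k: int, seed: int = 0
) -> dict[str, int]:
    """Reproducible subject-level fold assignment."""
    rng = np.random.default_rng(seed)
    order = list(subjects)
    rng.shuffle(order)
    return {s: i % k for i, s in enumerate(order)}


def _kfold_errors(
    cohort: CohortTable,
    priors: PriorHyperparameters,
    folds: Mapping[str, int],
    k: int,
    exclude_parents: Sequence[str],
    taxa: Sequence[str] | None,
) -> pd.Series:
    from tsdbn.data_io import select_taxa
    from tsdbn.structure_search import default_nodes

    table = build_transition_table(cohort)
    nodes = default_nodes(
        table.taxa, table.continuous_covariates, table.discrete_covariates
    )
    parents = [
        n.name
        for n in nodes
        if n.slice_role in ("both", "t_only") and n.name not in set(exclude_parents)
    ]
    per_subject: list[pd.Series] = []
    subj_col = table.frame["subject_id"].to_numpy()
    for fold in range(k):
        test_subjects = [s for s, f in folds.items() if f == fold]
        test_mask = np.isin(subj_col, test_subjects)
        train = table.subset(~test_mask)
        test = table.subset(test_mask)
        structure, _ = hill_climb(train, priors, nodes=nodes, candidate_parents=parents)
        fold_taxa = (
            list(taxa)
            if taxa is not None
            else select_taxa(cohort, structure, min_fraction=0.01)
        )
        fitted = fit_parameters(structure, train, priors)
        records = predict_transitions(fitted, test, fold_taxa)
        per_subject.append(per_subject_mae(records))
    return pd.concat(per_subject).sort_index()


def evaluate_kfold(
    cohort: CohortTable,
    priors: PriorHyperparameters,
    k: int = 5,
    variable_sets: tuple[Sequence[str], Sequence[str]] | None = None,
    taxa: Sequence[str] | None = None,
    seed: int = 0,
) -> dict:
    """k-fold CV over subjects comparing two candidate-parent variable sets.

    ``variable_sets`` gives, per arm, the covariates to EXCLUDE from the
    candidate parents (taxa always stay).  Structure and parameters are
    relearned per fold per arm; per-subject held-out errors are compared
    with a two-tailed paired t-test.
    """
    subjects = cohort.subject_ids
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(subjects):
        raise InsufficientDataError("more folds than subjects")
    if variable_sets is None:
        variable_sets = ((), ())
    folds = assign_folds(subjects, k, seed)
    errors_a = _kfold_errors(cohort, priors, folds, k, variable_sets[0], taxa)
    errors_b = _kfold_errors(cohort, priors, folds, k, variable_sets[1], taxa)
    joined = pd.DataFrame({"a": errors_a, "b": errors_b}).dropna()
    if joined["a"].equals(joined["b"]):
        t_stat, p_value = 0.0, 1.0
    else:
        t_stat, p_value = stats.ttest_rel(joined["a"], joined["b"])
    return {
        "per_subject_a": errors_a,
        "per_subject_b": errors_b,
        "mean_a": float(errors_a.mean()),
        "mean_b": float(errors_b.mean()),
        "t_statistic": float(t_stat),
        "p_value": float(p_value),
        "folds": folds,
    }


def compare_error_sets(
    errors_a: Sequence[float],
    errors_b: Sequence[float],
    mode: str = "paired-by-subject",
    exclusions: Sequence[int] | None = None,
    threshold: float | None = None,
) -> dict:
    """Two-tailed t-test between two error collections.

    paired-by-subject: paired t-test on per-subject differences after
    dropping the excluded indices.  grouped-by-threshold: split ``errors_a``
    at ``threshold`` (default: mean of ``errors_b`` as the reference model)
    and two-sample-test ``errors_b`` between the two groups.
    """
    a = np.asarray(errors_a, dtype=float)
    b = np.asarray(errors_b, dtype=float)
    if mode == "paired-by-subject":
        if len(a) != len(b):
            raise ValueError("paired mode requires equal-length inputs")
        keep = np.ones(len(a), dtype=bool)
        if exclusions:
            keep[list(exclusions)] = False
        a, b = a[keep], b[keep]
        if len(a) < 3:
            raise InsufficientDataError("fewer than 3 usable pairs")
        if np.array_equal(a, b):
            return {"t_statistic": 0.0, "p_value": 1.0, "n": len(a)}
        t_stat, p_value = stats.ttest_rel(a, b)
        return {"t_statistic": float(t_stat), "p_value": float(p_value), "n": len(a)}
    if mode == "grouped-by-threshold":
        if threshold is None:
            threshold = float(np.mean(b))
        low = b[a <= threshold]
        high = b[a > threshold]
        if len(low) < 2 or len(high) < 2:
            raise InsufficientDataError("one threshold group is (nearly) empty")
        t_stat, p_value = stats.ttest_ind(low, high)
        return {
            "t_statistic": float(t_stat),
            "p_value": float(p_value),
            "n_low": int(len(low)),
            "n_high": int(len(high)),
            "threshold": float(threshold),
        }
    raise ValueError(f"unknown mode {mode!r}")


def error_vs_gap(records: Sequence[PredictionRecord]) -> dict:
    """Median split on gap_days: are small-gap samples easier to predict?"""
    frame = records_frame(records)
    median_gap = float(frame["gap_days"].median())
    split = median_gap
    if (frame["gap_days"] > split).sum() < 2 and frame["gap_days"].nunique() > 1:
        # median equals the largest gap (e.g. gaps in {1, 2}); fall back to
        # the mean so both groups are populated
        split = float(frame["gap_days"].mean())
    small = frame.loc[frame["gap_days"] <= split, "mae"].to_numpy()
    large = frame.loc[frame["gap_days"] > split, "mae"].to_numpy()
    if len(small) < 2 or len(large) < 2:
        raise InsufficientDataError("one gap group is (nearly) empty")
    median_gap = split
    t_stat, p_value = stats.ttest_ind(small, large)
    return {
        "t_statistic": float(t_stat),
        "p_value": float(p_value),
        "median_gap": median_gap,
        "mean_mae_small_gap": float(small.mean()),
        "mean_mae_large_gap": float(large.mean()),
    }
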