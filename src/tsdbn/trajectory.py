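"""Iterative forward prediction and the six-scenario convergence suite.

Each step feeds the previous step's normalized composition back into the
one-step predictor.  Clock covariates (day of life, post-conceptional age)
advance by ``delta_t`` days per step under the default policy; antibiotics
and discrete covariates are held at their initial values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from tsdbn.cgbn_core import FittedDBN
from tsdbn.errors import IncompleteEvidenceError
from tsdbn.prediction_eval import normalize_prediction, predict_next

#: Covariates advanced by the clock under the advance-clocks policy, with the
#: per-day increment in their native unit (post-conceptional age is in weeks).
CLOCK_RATES = {"day_of_life": 1.0, "postconceptional_age": 1.0 / 7.0}


@dataclass(frozen=True)
class TrajectoryConfig:
    """Number of steps, days per step, and covariate handling."""

    steps: int = 20
    delta_t: float = 2.0
    covariate_policy: str = "advance-clocks"  # or "hold-constant"

    def __post_init__(self) -> None:
        if self.steps < 1 or self.delta_t <= 0:
            raise ValueError("require steps >= 1 and delta_t > 0")
        if self.covariate_policy not in ("advance-clocks", "hold-constant"):
            raise ValueError(f"bad covariate_policy {self.covariate_policy!r}")


@dataclass(frozen=True)
class Scenario:
    """Named initial composition plus initial covariate values."""

    name: str
    initial_profile: Mapping[str, float]
    initial_covariates: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = float(sum(self.initial_profile.values()))
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"initial profile sums to {total}, not 1")


DEFAULT_SCENARIO_COVARIATES: dict[str, object] = {
    "day_of_life": 5.0,
    "gestational_age_at_birth": 28.0,
    "postconceptional_age": 28.0 + 5.0 / 7.0,
    "antibiotics": 0.0,
    "open_room": "closed",
}


def iterative_predict(
    fitted: FittedDBN,
    initial: Scenario,
    config: TrajectoryConfig,
    taxa: Sequence[str] | None = None,
) -> list[dict[str, float]]:
    """Iterate the one-step predictor from an initial state.

    Step 1 equals a single predict-and-normalize call on the initial state;
    each later step feeds the previous normalized composition back in.
    Returns one composition per step.
    """
    if taxa is None:
        taxa = [
            c
            for c in fitted.children
            if fitted.structure.node(c).kind == "continuous"
        ]
    state: dict[str, object] = dict(initial.initial_covariates)
    for t in taxa:
        state[t] = float(initial.initial_profile.get(t, 0.0))
    needed = _required_parents(fitted)
    missing = [v for v in needed if v not in state]
    if missing:
        raise IncompleteEvidenceError(
            f"initial state missing variable(s): {', '.join(sorted(missing))}"
        )

    profiles: list[dict[str, float]] = []
    for _ in range(config.steps):
        raw = predict_next(fitted, state)
        profile = normalize_prediction({t: raw.get(t, 0.0) for t in taxa}, taxa)
        profiles.append(profile)
        state.update(profile)
        for child, value in raw.items():
            if child not in profile:  # discrete children fed forward as-is
                state[child] = value
        if config.covariate_policy == "advance-clocks":
            for cov, per_day in CLOCK_RATES.items():
                if cov in state:
                    state[cov] = float(state[cov]) + per_day * config.delta_t
    return profiles


def _required_parents(fitted: FittedDBN) -> set[str]:
    needed: set[str] = set()
    for parents in fitted.structure.parent_sets.values():
        needed.update(parents)
    return needed


def max_pairwise_l1(profiles: Sequence[Mapping[str, float]]) -> float:
    """Maximum pairwise L1 distance between compositions."""
    keys = sorted({k for p in profiles for k in p})
    mat = np.array([[p.get(k, 0.0) for k in keys] for p in profiles])
    best = 0.0
    for i in range(len(mat)):
        for j in range(i + 1, len(mat)):
            best = max(best, float(np.abs(mat[i] - mat[j]).sum()))
    return best


def scenario_suite(
    fitted: FittedDBN,
    scenarios: Sequence[Scenario],
    config: TrajectoryConfig,
    taxa: Sequence[str] | None = None,
) -> dict:
    """Run every scenario and tabulate per-step divergence.

    The convergence metric at step s is the maximum pairwise L1 distance
    between the scenarios' compositions at that step.
    """
    if len(scenarios) < 2:
        raise ValueError("need at least 2 scenarios")
    trajectories = {
        s.name: iterative_predict(fitted, s, config, taxa) for s in scenarios
    }
    metric = [
        max_pairwise_l1([trajectories[s.name][step] for s in scenarios])
        for step in range(config.steps)
    ]
    table = pd.DataFrame(
        {"step": np.arange(1, config.steps + 1), "max_pairwise_l1": metric}
    )
    return {"trajectories": trajectories, "convergence": table}


def default_scenarios(
    taxa: Sequence[str],
    dominant: Sequence[str] = ("Bacilli", "Clostridia", "Gammaproteobacteria"),
    trace: float = 0.01,
    covariates: Mapping[str, object] | None = None,
) -> list[Scenario]:
    """The six standard synthetic initial conditions.

    1) even split of the three dominant taxa; 2) the same plus a trace of
    every rare taxon; 3-5) condition 2 minus one dominant taxon each; 6) an
    even split over the rare taxa only.
    """
    covariates = dict(covariates or DEFAULT_SCENARIO_COVARIATES)
    dominant = [t for t in dominant if t in taxa]
    rare = [t for t in taxa if t not in dominant]

    def build(name: str, weights: Mapping[str, float]) -> Scenario:
        total = sum(weights.values())
        profile = {t: weights.get(t, 0.0) / total for t in taxa}
        return Scenario(name, profile, covariates)

    scenarios = [
        build("even-dominant", {t: 1.0 for t in dominant}),
        build(
            "even-dominant-plus-rares",
            {**{t: 1.0 for t in dominant}, **{t: trace for t in rare}},
        ),
    ]
    for drop in dominant:
        weights = {t: 1.0 for t in dominant if t != drop}
        weights.update({t: trace for t in rare})
        scenarios.append(build(f"no-{drop.lower()}", weights))
    if rare:
        scenarios.append(build("even-rares", {t: 1.0 for t in rare}))
    return scenarios


def iterative_subject_errors(
    fitted: FittedDBN,
    table,
    taxa: Sequence[str],
) -> pd.Series:
    """Per-subject mean MAE when only each subject's first sample is real.

    For every subject the predictor starts from the first observed sample
    and thereafter feeds its own normalized predictions back in; clinical
    covariates follow their observed values (the clocks come from the
    data).  Comparable to one-step per-subject MAE from the same table.
    """
    from tsdbn.data_io import TARGET_SUFFIX
    from tsdbn.prediction_eval import source_assignment

    maes: dict[str, list[float]] = {}
    for subject, group in table.frame.groupby("subject_id", sort=True):
        state: dict[str, object] | None = None
        errs = []
        for _, row in group.iterrows():
            observed_source = source_assignment(table, row)
            if state is None:
                state = dict(observed_source)
            else:
                # keep observed covariates, replace taxa with fed-back preds
                for cov in list(table.continuous_covariates) + list(
                    table.discrete_covariates
                ):
                    state[cov] = observed_source[cov]
            raw = predict_next(fitted, state)
            profile = normalize_prediction({t: raw.get(t, 0.0) for t in taxa}, taxa)
            observed = np.array([float(row[t + TARGET_SUFFIX]) for t in taxa])
            total = observed.sum()
            observed = (
                observed / total if total > 0 else np.full(len(taxa), 1 / len(taxa))
            )
            errs.append(
                float(
                    np.mean(
                        [abs(profile[t] - o) for t, o in zip(taxa, observed)]
                    )
                )
            )
            state.update(profile)
        maes[str(subject)] = errs
    return pd.Series(
        {s: float(np.mean(e)) for s, e in maes.items() if e}, name="mae"
    ).sort_index()


def trajectories_long_frame(result: dict) -> pd.DataFrame:
    """Long-format (scenario, step, taxon, abundance) table."""
    rows = []
    for name, profiles in result["trajectories"].items():
        for step, profile in enumerate(profiles, start=1):
            for taxon, value in profile.items():
                rows.append(
                    {"scenario": name, "step": step, "taxon": taxon, "abundance": value}
                )
    return pd.DataFrame(rows)
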