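"""Synthetic cohorts from a known ground-truth two-slice CLG model.

The default truth model reproduces the qualitative succession of a preterm
infant gut cohort: Bacilli dominate early, Gammaproteobacteria flourish
transiently, and Clostridia rise with post-conceptional age, with eleven
rare taxa at trace abundance.  Latent compositions evolve by a linear map
plus Gaussian residuals, are clipped to the simplex, and are observed
through multinomial read counts at a per-sample sequencing depth.

A separate planted vector-autoregression generator provides clean (non-
compositional) benchmarks for structure and parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from tsdbn.data_io import (
    CONTINUOUS_COVARIATES,
    DISCRETE_COVARIATES,
    SOURCE_SUFFIX,
    TARGET_SUFFIX,
    CohortTable,
    TransitionTable,
)

#: The fourteen taxa of the default model.
DEFAULT_TAXA = [
    "Actinobacteria",
    "Alphaproteobacteria",
    "Bacilli",
    "Bacteroidia",
    "Betaproteobacteria",
    "Clostridia",
    "Cyanobacteria",
    "Epsilonproteobacteria",
    "Erysipelotrichi",
    "Flavobacteria",
    "Fusobacteria",
    "Gammaproteobacteria",
    "Holophagae",
    "unclassified",
]

DOMINANT_TAXA = ("Bacilli", "Clostridia", "Gammaproteobacteria")

#: Post-conceptional age (weeks) is mapped to a unitless clock via
#: (pca - AGE_OFFSET) / AGE_SCALE before entering the truth model.
AGE_OFFSET = 24.0
AGE_SCALE = 10.0


@dataclass
class GroundTruthSpec:
    """Planted transition model: intercepts, parent weights, residual sigma.

    ``weights[child]`` maps taxon parents (at t) to coefficients;
    ``age_weights[child]`` is the coefficient on the normalized
    post-conceptional-age clock.
    """

    taxa: list[str] = field(default_factory=lambda: list(DEFAULT_TAXA))
    dominant: tuple[str, ...] = DOMINANT_TAXA
    intercepts: dict[str, float] = field(default_factory=dict)
    weights: dict[str, dict[str, float]] = field(default_factory=dict)
    age_weights: dict[str, float] = field(default_factory=dict)
    sigmas: dict[str, float] = field(default_factory=dict)
    abruptions: list[tuple[int, int, str]] = field(default_factory=list)
    allow_unstable: bool = False

    def taxa_matrix(self) -> np.ndarray:
        """Taxa-block linear map B with B[i, j] = weight of taxon j on taxon i."""
        idx = {t: i for i, t in enumerate(self.taxa)}
        B = np.zeros((len(self.taxa), len(self.taxa)))
        for child, ws in self.weights.items():
            for parent, w in ws.items():
                if parent in idx:
                    B[idx[child], idx[parent]] = w
        return B

    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.taxa_matrix()))))

    def validate(self) -> None:
        for t in self.taxa:
            if self.sigmas.get(t, 0.0) <= 0:
                raise ValueError(f"residual sigma for {t!r} must be > 0")
        rho = self.spectral_radius()
        if rho >= 1.0 and not self.allow_unstable:
            raise ValueError(
                f"unstable truth model (spectral radius {rho:.3f} >= 1); "
                "set allow_unstable=True to override"
            )

    def true_edges(self, threshold: float = 0.0) -> set[tuple[str, str]]:
        edges = {
            (p, c)
            for c, ws in self.weights.items()
            for p, w in ws.items()
            if abs(w) > threshold
        }
        edges |= {
            ("postconceptional_age", c)
            for c, w in self.age_weights.items()
            if abs(w) > threshold
        }
        return edges


def default_ground_truth() -> GroundTruthSpec:
    """Succession-patterned stable truth model over the 14 default taxa."""
    taxa = list(DEFAULT_TAXA)
    rare = [t for t in taxa if t not in DOMINANT_TAXA]
    intercepts = {t: 0.003 for t in rare}
    weights: dict[str, dict[str, float]] = {t: {t: 0.30} for t in rare}
    sigmas = {t: 0.004 for t in rare}
    intercepts["unclassified"] = 0.008
    sigmas["unclassified"] = 0.006

    intercepts["Bacilli"] = 0.06
    weights["Bacilli"] = {"Bacilli": 0.55, "Clostridia": -0.25}
    sigmas["Bacilli"] = 0.04

    intercepts["Gammaproteobacteria"] = 0.05
    weights["Gammaproteobacteria"] = {"Gammaproteobacteria": 0.55, "Bacilli": 0.30}
    sigmas["Gammaproteobacteria"] = 0.05

    intercepts["Clostridia"] = 0.02
    weights["Clostridia"] = {"Clostridia": 0.80}
    sigmas["Clostridia"] = 0.04

    age_weights = {"Clostridia": 0.10}

    spec = GroundTruthSpec(
        taxa=taxa,
        intercepts=intercepts,
        weights=weights,
        age_weights=age_weights,
        sigmas=sigmas,
    )
    spec.validate()
    return spec


@dataclass
class CohortSpec:
    """Study-design knobs for the simulated cohort."""

    n_subjects: int = 58
    samples_per_subject: tuple[int, int] = (13, 19)  # inclusive range
    gap_days: tuple[int, ...] = (1, 2)
    read_depth_median: float = 7000.0
    read_depth_log_sigma: float = 0.30
    seed: int = 0

    #: Dirichlet weights for the initial composition (Bacilli-dominated).
    initial_alpha: dict[str, float] = field(
        default_factory=lambda: {
            "Bacilli": 10.0,
            "Gammaproteobacteria": 4.0,
            "Clostridia": 1.0,
            "unclassified": 0.5,
        }
    )
    initial_alpha_rare: float = 0.2


def _clip_renormalize(values: np.ndarray) -> np.ndarray:
    clipped = np.clip(values, 0.0, None)
    total = clipped.sum()
    if total <= 0:
        return np.full(len(values), 1.0 / len(values))
    return clipped / total


def latent_step(
    truth: GroundTruthSpec,
    composition: np.ndarray,
    pca_weeks: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One transition of the latent dynamics; returns (raw, composition)."""
    idx = {t: i for i, t in enumerate(truth.taxa)}
    age_norm = (pca_weeks - AGE_OFFSET) / AGE_SCALE
    raw = np.empty(len(truth.taxa))
    for t in truth.taxa:
        mean = truth.intercepts.get(t, 0.0)
        for parent, w in truth.weights.get(t, {}).items():
            mean += w * composition[idx[parent]]
        mean += truth.age_weights.get(t, 0.0) * age_norm
        raw[idx[t]] = mean + rng.normal(0.0, truth.sigmas[t])
    return raw, _clip_renormalize(raw)


def simulate_cohort(
    truth: GroundTruthSpec,
    spec: CohortSpec,
    seed: int | None = None,
) -> tuple[CohortTable, pd.DataFrame]:
    """Simulate a cohort; returns (cohort table, latent-state archive).

    The archive has one row per sample with the pre-clip latent values
    (``latent_raw:<taxon>``) and the latent composition
    (``latent:<taxon>``) actually observed through multinomial counting.
    """
    truth.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    taxa = truth.taxa
    k = len(taxa)
    alpha = np.array(
        [
            spec.initial_alpha.get(t, spec.initial_alpha_rare)
            for t in taxa
        ]
    )
    lo, hi = spec.samples_per_subject
    mu_depth = float(np.log(spec.read_depth_median))

    pad = max(2, len(str(spec.n_subjects)))
    rows = []
    latent_rows = []
    for s in range(spec.n_subjects):
        subject = f"S{s + 1:0{pad}d}"
        n_samples = int(rng.integers(lo, hi + 1))
        gest = float(rng.uniform(24.0, 32.0))
        day = int(rng.integers(3, 9))
        antibiotics = float(rng.beta(2.0, 5.0))
        room = "open" if rng.random() < 0.5 else "closed"
        comp = rng.dirichlet(alpha)
        raw = comp.copy()
        for j in range(n_samples):
            if j > 0:
                gap = int(rng.choice(spec.gap_days))
                day += gap
                raw, comp = latent_step(truth, comp, gest + day / 7.0, rng)
            pca = gest + day / 7.0
            depth = int(
                max(
                    100,
                    round(rng.lognormal(mu_depth, spec.read_depth_log_sigma)),
                )
            )
            counts = rng.multinomial(depth, comp)
            row = {
                "subject_id": subject,
                "day_of_life": day,
                "gestational_age_at_birth": round(gest, 2),
                "postconceptional_age": round(pca, 3),
                "antibiotics": round(antibiotics, 4),
                "open_room": room,
            }
            row.update({t: int(c) for t, c in zip(taxa, counts)})
            rows.append(row)
            latent = {"subject_id": subject, "day_of_life": day}
            latent.update({f"latent_raw:{t}": raw[i] for i, t in enumerate(taxa)})
            latent.update({f"latent:{t}": comp[i] for i, t in enumerate(taxa)})
            latent_rows.append(latent)

    frame = pd.DataFrame(rows)
    cohort = CohortTable(frame, taxa=list(taxa))
    archive = pd.DataFrame(latent_rows)
    for subject, step, mode in truth.abruptions:
        cohort = inject_abruption(cohort, f"S{subject:0{pad}d}", step, mode)
    return cohort, archive


def inject_abruption(
    cohort: CohortTable,
    subject_id: str,
    step: int,
    mode: str = "replace-with-unclassified",
    rng: np.random.Generator | None = None,
) -> CohortTable:
    """Replace one sample's composition with an extreme event.

    ``step`` indexes the subject's samples in day order (0-based).  Modes:
    ``replace-with-unclassified`` and ``replace-with-rare-taxon`` put the
    whole read depth on a single taxon; ``shuffle-composition`` permutes the
    sample's counts across taxa.  All other samples are untouched, and the
    injection is recorded in ``cohort.provenance``.
    """
    frame = cohort.frame.copy()
    subject_rows = frame.index[frame["subject_id"] == subject_id]
    if len(subject_rows) == 0:
        raise KeyError(f"unknown subject {subject_id!r}")
    if not 0 <= step < len(subject_rows):
        raise KeyError(f"subject {subject_id!r} has no sample index {step}")
    row = subject_rows[step]
    depth = int(frame.loc[row, cohort.taxa].sum())
    if mode == "replace-with-unclassified":
        target = "unclassified"
        frame.loc[row, cohort.taxa] = 0
        frame.loc[row, target] = depth
    elif mode == "replace-with-rare-taxon":
        target = "Bacteroidia" if "Bacteroidia" in cohort.taxa else cohort.taxa[0]
        frame.loc[row, cohort.taxa] = 0
        frame.loc[row, target] = depth
    elif mode == "shuffle-composition":
        rng = np.random.default_rng(0) if rng is None else rng
        counts = frame.loc[row, cohort.taxa].to_numpy()
        frame.loc[row, cohort.taxa] = rng.permutation(counts)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    out = CohortTable(frame, taxa=list(cohort.taxa))
    out.provenance = list(getattr(cohort, "provenance", [])) + [
        {"subject_id": subject_id, "step": step, "mode": mode}
    ]
    return out


def truth_to_fitted(truth: GroundTruthSpec):
    """Wrap the planted coefficients as a fitted model (no learning).

    The age clock (pca - offset)/scale is folded into the coefficient on
    post-conceptional age and the intercept, so the fitted model conditions
    on the raw covariate.
    """
    from tsdbn.cgbn_core import (
        CLGFamilyParameters,
        DBNStructure,
        FittedDBN,
        NodeSpec,
        PriorHyperparameters,
    )

    nodes = [NodeSpec(t, "continuous", "both") for t in truth.taxa]
    nodes.append(NodeSpec("postconceptional_age", "continuous", "t_only"))
    parent_sets: dict[str, tuple[str, ...]] = {}
    cont_params: dict[str, CLGFamilyParameters] = {}
    for child in truth.taxa:
        parents = sorted(truth.weights.get(child, {}))
        age_w = truth.age_weights.get(child, 0.0)
        if age_w:
            parents = sorted(parents + ["postconceptional_age"])
        parent_sets[child] = tuple(parents)
        alpha = truth.intercepts.get(child, 0.0) - age_w * AGE_OFFSET / AGE_SCALE
        beta = []
        for p in parents:
            if p == "postconceptional_age":
                beta.append(age_w / AGE_SCALE)
            else:
                beta.append(truth.weights[child][p])
        cont_params[child] = CLGFamilyParameters(
            continuous_parents=parents,
            discrete_parents=[],
            by_config={
                (): {
                    "alpha": alpha,
                    "beta": np.asarray(beta, dtype=float),
                    "sigma2": truth.sigmas[child] ** 2,
                    "n": 0,
                }
            },
        )
    max_parents = max((len(p) for p in parent_sets.values()), default=1)
    structure = DBNStructure(nodes, parent_sets, max_parents=max(max_parents, 3))
    priors = PriorHyperparameters(nu=10.0, sigma2=1.0, max_parents=max(max_parents, 3))
    return FittedDBN(structure, cont_params, {}, priors, 0.0)


# ---------------------------------------------------------------------------
# Planted vector-autoregression benchmarks (non-compositional)
# ---------------------------------------------------------------------------


def simulate_planted_var(
    n_nodes: int = 12,
    n_subjects: int = 58,
    samples_per_subject: int = 15,
    effect: float = 0.6,
    second_effect: float = 0.5,
    p_second_parent: float = 0.3,
    seed: int = 0,
) -> tuple[TransitionTable, set[tuple[str, str]], dict[str, dict[str, float]]]:
    """Stable planted first-order VAR with standardized effects >= 0.5.

    Each child gets one parent with coefficient ``+-effect`` and, with
    probability ``p_second_parent``, a second with ``+-second_effect``.
    Residual variances keep the stationary scale near 1, so coefficients
    are (approximately) standardized effects.  Returns the transition
    table, the planted edge set, and the coefficient map.
    """
    rng = np.random.default_rng(seed)
    names = [f"V{i + 1:02d}" for i in range(n_nodes)]
    while True:
        B = np.zeros((n_nodes, n_nodes))
        for i in range(n_nodes):
            parents = rng.choice(n_nodes, size=1, replace=False)
            B[i, parents[0]] = effect * (1 if rng.random() < 0.5 else -1)
            if rng.random() < p_second_parent:
                others = [j for j in range(n_nodes) if j != parents[0]]
                j = int(rng.choice(others))
                B[i, j] = second_effect * (1 if rng.random() < 0.5 else -1)
        if np.max(np.abs(np.linalg.eigvals(B))) < 0.95:
            break
    sigma = np.sqrt(np.maximum(0.15, 1.0 - (B**2).sum(axis=1)))

    rows = []
    for s in range(n_subjects):
        x = rng.normal(0.0, 1.0, size=n_nodes)
        day = 0
        for j in range(samples_per_subject - 1):
            nxt = B @ x + rng.normal(0.0, sigma)
            day += 1
            row = {"subject_id": f"S{s + 1:02d}", "gap_days": 1, "target_day": day}
            for i, name in enumerate(names):
                row[name + SOURCE_SUFFIX] = x[i]
                row[name + TARGET_SUFFIX] = nxt[i]
            rows.append(row)
            x = nxt
    table = TransitionTable(
        pd.DataFrame(rows),
        taxa=names,
        continuous_covariates=[],
        discrete_covariates=[],
    )
    edges = {
        (names[j], names[i])
        for i in range(n_nodes)
        for j in range(n_nodes)
        if B[i, j] != 0.0
    }
    coefficients = {
        names[i]: {names[j]: float(B[i, j]) for j in range(n_nodes) if B[i, j] != 0.0}
        for i in range(n_nodes)
    }
    return table, edges, coefficients
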