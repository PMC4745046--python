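"""Conditional-Gaussian Bayesian scoring, fitting and density evaluation.

Each continuous child at slice t+1 is a Gaussian regression on its
continuous parents at slice t, with intercept, coefficients and residual
variance indexed by the configuration of its discrete parents.  Discrete
children carry Dirichlet-multinomial families and may have only discrete
parents.

Conjugate prior (normal-inverse-gamma), with nu the prior equivalent sample
size and sigma2_0 the prior assumed variance:

    sigma^2             ~ InvGamma(nu / 2, nu * sigma2_0 / 2)
    (alpha, beta) | s2  ~ Normal(0, (s2 / nu) * I)

which yields a closed-form marginal likelihood per discrete-parent
configuration; configurations are scored independently and summed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import gammaln

from tsdbn.data_io import TransitionTable
from tsdbn.errors import IncompleteEvidenceError, StructureError

LOG_2PI = math.log(2.0 * math.pi)

#: Key used for the single (empty) configuration when a child has no
#: discrete parents.
NO_CONFIG: tuple = ()


@dataclass(frozen=True)
class NodeSpec:
    """A model variable: continuous or discrete, and where it appears.

    ``slice_role`` is ``t_only`` for exogenous covariates observed at t,
    ``both`` for taxa that act as parents at t and children at t+1, and
    ``t1_only`` for pure outcome nodes.
    """

    name: str
    kind: str  # {"continuous", "discrete"}
    slice_role: str = "both"  # {"t_only", "both", "t1_only"}

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "discrete"):
            raise ValueError(f"bad kind {self.kind!r}")
        if self.slice_role not in ("t_only", "both", "t1_only"):
            raise ValueError(f"bad slice_role {self.slice_role!r}")


@dataclass(frozen=True)
class PriorHyperparameters:
    """Prior equivalent sample size, assumed variance and parent cap.

    The sparse regime is (nu=10, sigma2=1, max_parents=3); the dense regime
    is (nu=50, sigma2=1, max_parents=5).
    """

    nu: float = 10.0
    sigma2: float = 1.0
    max_parents: int = 3
    dirichlet_alpha_total: float | None = None

    def __post_init__(self) -> None:
        if self.nu <= 0 or self.sigma2 <= 0 or self.max_parents < 1:
            raise ValueError("require nu > 0, sigma2 > 0, max_parents >= 1")

    @property
    def alpha_total(self) -> float:
        return self.nu if self.dirichlet_alpha_total is None else float(
            self.dirichlet_alpha_total
        )


SPARSE_PRIORS = PriorHyperparameters(nu=10.0, sigma2=1.0, max_parents=3)
DENSE_PRIORS = PriorHyperparameters(nu=50.0, sigma2=1.0, max_parents=5)


@dataclass
class DBNStructure:
    """Directed two-slice graph: parents at slice t, children at slice t+1."""

    nodes: list[NodeSpec]
    parent_sets: dict[str, tuple[str, ...]] = field(default_factory=dict)
    max_parents: int = 3

    def __post_init__(self) -> None:
        self._by_name = {n.name: n for n in self.nodes}
        for child, parents in list(self.parent_sets.items()):
            self.parent_sets[child] = tuple(sorted(parents))
            self.validate_family(child, self.parent_sets[child])

    def node(self, name: str) -> NodeSpec:
        return self._by_name[name]

    @property
    def children(self) -> list[str]:
        return sorted(self.parent_sets)

    def validate_family(self, child: str, parents: Sequence[str]) -> None:
        if child not in self._by_name:
            raise StructureError(f"unknown child {child!r}")
        if len(parents) > self.max_parents:
            raise StructureError(
                f"{child!r} has {len(parents)} parents (max {self.max_parents})"
            )
        child_spec = self._by_name[child]
        for p in parents:
            if p not in self._by_name:
                raise StructureError(f"unknown parent {p!r}")
            if self._by_name[p].slice_role == "t1_only":
                raise StructureError(f"{p!r} cannot act as a slice-t parent")
            if child_spec.kind == "discrete" and self._by_name[p].kind != "discrete":
                raise StructureError(
                    f"discrete child {child!r} may have only discrete parents"
                )
        if child_spec.slice_role == "t_only":
            raise StructureError(f"{child!r} is exogenous and cannot be a child")

    def split_parents(self, child: str) -> tuple[list[str], list[str]]:
        """(continuous parents, discrete parents) in sorted order."""
        cont, disc = [], []
        for p in self.parent_sets.get(child, ()):
            (cont if self._by_name[p].kind == "continuous" else disc).append(p)
        return cont, disc

    @property
    def edges(self) -> list[tuple[str, str]]:
        return sorted(
            (p, c) for c, parents in self.parent_sets.items() for p in parents
        )

    def with_edge(self, parent: str, child: str) -> "DBNStructure":
        new = dict(self.parent_sets)
        new[child] = tuple(sorted(set(new.get(child, ())) | {parent}))
        return DBNStructure(self.nodes, new, self.max_parents)

    def without_edge(self, parent: str, child: str) -> "DBNStructure":
        if parent not in self.parent_sets.get(child, ()):
            raise StructureError(f"edge {parent!r}->{child!r} not in structure")
        new = dict(self.parent_sets)
        new[child] = tuple(p for p in new[child] if p != parent)
        return DBNStructure(self.nodes, new, self.max_parents)

    def to_json_dict(self) -> dict:
        return {
            "nodes": [
                {"name": n.name, "kind": n.kind, "slice_role": n.slice_role}
                for n in self.nodes
            ],
            "parent_sets": {c: list(p) for c, p in sorted(self.parent_sets.items())},
            "max_parents": self.max_parents,
        }

    @classmethod
    def from_json_dict(cls, d: Mapping) -> "DBNStructure":
        nodes = [NodeSpec(**n) for n in d["nodes"]]
        parents = {c: tuple(p) for c, p in d["parent_sets"].items()}
        return cls(nodes, parents, int(d["max_parents"]))

    def to_edge_frame(self):
        import pandas as pd

        return pd.DataFrame(self.edges, columns=["parent", "child"])

    def to_dot(self) -> str:
        lines = ["digraph dbn {", "  rankdir=LR;"]
        for n in self.nodes:
            shape = "ellipse" if n.kind == "continuous" else "box"
            lines.append(f'  "{n.name}" [shape={shape}];')
        for p, c in self.edges:
            lines.append(f'  "{p}" -> "{c}";')
        lines.append("}")
        return "\n".join(lines)

    def to_graphml(self, path: str | Path) -> None:
        import networkx as nx

        g = nx.DiGraph()
        for n in self.nodes:
            g.add_node(n.name, kind=n.kind, slice_role=n.slice_role)
        g.add_edges_from(self.edges)
        nx.write_graphml(g, path)


# ---------------------------------------------------------------------------
# Family scoring
# ---------------------------------------------------------------------------


def _config_codes(
    labels: Sequence[np.ndarray],
) -> tuple[np.ndarray, list[tuple]]:
    """Row-wise discrete-parent configurations as integer codes.

    Returns (codes, configs) with configs[codes[i]] the i-th row's tuple of
    parent states; configs are sorted lexicographically.
    """
    cols = [np.asarray(lab).astype(str) for lab in labels]
    n = len(cols[0])
    tuples = [tuple(c[i] for c in cols) for i in range(n)]
    configs = sorted(set(tuples))
    index = {cfg: i for i, cfg in enumerate(configs)}
    codes = np.array([index[t] for t in tuples], dtype=int)
    return codes, configs


def _nig_log_evidence(y: np.ndarray, X: np.ndarray, nu: float, sigma2: float) -> float:
    """Closed-form log marginal likelihood of one Gaussian regression family.

    ``X`` excludes the intercept column; it is added here.
    """
    n = len(y)
    if n == 0:
        return 0.0
    Xd = np.column_stack([np.ones(n), X]) if X.size else np.ones((n, 1))
    d = Xd.shape[1]
    a0 = nu / 2.0
    b0 = nu * sigma2 / 2.0
    Vn_inv = nu * np.eye(d) + Xd.T @ Xd
    Xty = Xd.T @ y
    wn = np.linalg.solve(Vn_inv, Xty)
    an = a0 + n / 2.0
    bn = b0 + 0.5 * (float(y @ y) - float(wn @ Vn_inv @ wn))
    # numerical floor: the quadratic form is >= 0 analytically
    bn = max(bn, 1e-300)
    sign, logdet_Vn_inv = np.linalg.slogdet(Vn_inv)
    return float(
        -0.5 * n * LOG_2PI
        + 0.5 * (d * math.log(nu) - logdet_Vn_inv)
        + a0 * math.log(b0)
        - an * math.log(bn)
        + gammaln(an)
        - gammaln(a0)
    )


def family_log_score_continuous(
    child_values: np.ndarray,
    continuous_parent_matrix: np.ndarray | None,
    discrete_parent_labels: Sequence[np.ndarray] | None,
    priors: PriorHyperparameters,
) -> float:
    """Log marginal likelihood of a continuous child given its parents.

    Rows are partitioned by the discrete-parent configuration; each block is
    scored with the conjugate normal-inverse-gamma evidence and the block
    scores are summed.  Zero rows return 0 (empty-product convention).
    """
    y = np.asarray(child_values, dtype=float)
    n = len(y)
    if n == 0:
        return 0.0
    if continuous_parent_matrix is None:
        X = np.empty((n, 0))
    else:
        X = np.asarray(continuous_parent_matrix, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[0] != n:
            raise ValueError("parent matrix rows != child length")
    if not discrete_parent_labels:
        return _nig_log_evidence(y, X, priors.nu, priors.sigma2)
    codes, configs = _config_codes(discrete_parent_labels)
    total = 0.0
    for code in range(len(configs)):
        mask = codes == code
        total += _nig_log_evidence(y[mask], X[mask], priors.nu, priors.sigma2)
    return total


def family_log_score_discrete(
    child_labels: np.ndarray,
    discrete_parent_labels: Sequence[np.ndarray] | None,
    priors: PriorHyperparameters,
    states: Sequence[str] | None = None,
) -> float:
    """Dirichlet-multinomial log evidence of a discrete child.

    The prior mass ``alpha_total`` is spread uniformly over
    (#configurations x #states) cells; configurations are scored
    independently and summed.
    """
    z = np.asarray(child_labels).astype(str)
    n = len(z)
    if n == 0:
        return 0.0
    if states is None:
        states = sorted(set(z.tolist()))
    else:
        states = [str(s) for s in states]
        states = sorted(set(states) | set(z.tolist()))
    k = len(states)
    if discrete_parent_labels:
        codes, configs = _config_codes(discrete_parent_labels)
    else:
        codes = np.zeros(n, dtype=int)
        configs = [NO_CONFIG]
    alpha_cell = priors.alpha_total / (len(configs) * k)
    total = 0.0
    for code in range(len(configs)):
        zc = z[codes == code]
        n_u = len(zc)
        a_u = alpha_cell * k
        total += gammaln(a_u) - gammaln(a_u + n_u)
        for s in states:
            n_uz = int((zc == s).sum())
            total += gammaln(alpha_cell + n_uz) - gammaln(alpha_cell)
    return float(total)


def _family_arrays(
    structure: DBNStructure, table: TransitionTable, child: str
) -> tuple[np.ndarray, np.ndarray, list[np.ndarray]]:
    cont, disc = structure.split_parents(child)
    y = table.target_values(child)
    X = (
        np.column_stack([table.source_values(p) for p in cont])
        if cont
        else np.empty((len(y), 0))
    )
    labels = [table.source_values(p) for p in disc]
    return y, X, labels


def family_log_score(
    structure: DBNStructure,
    table: TransitionTable,
    child: str,
    priors: PriorHyperparameters,
) -> float:
    """Score one child's family against the transition table."""
    spec = structure.node(child)
    y, X, labels = _family_arrays(structure, table, child)
    if spec.kind == "continuous":
        return family_log_score_continuous(y, X, labels, priors)
    return family_log_score_discrete(y, labels or None, priors)


def network_log_score(
    structure: DBNStructure,
    table: TransitionTable,
    priors: PriorHyperparameters,
) -> float:
    """Decomposable network score: sum of family scores over all children."""
    return float(
        sum(family_log_score(structure, table, c, priors) for c in structure.children)
    )


# ---------------------------------------------------------------------------
# Parameter fitting and densities
# ---------------------------------------------------------------------------


@dataclass
class CLGFamilyParameters:
    """Per-configuration intercept, coefficients and residual variance."""

    continuous_parents: list[str]
    discrete_parents: list[str]
    by_config: dict[tuple, dict]  # config -> {alpha, beta, sigma2, n}

    def config_for(self, assignment: Mapping[str, object]) -> tuple:
        if not self.discrete_parents:
            return NO_CONFIG
        try:
            key = tuple(str(assignment[p]) for p in self.discrete_parents)
        except KeyError as e:  # pragma: no cover - guarded by callers
            raise IncompleteEvidenceError(f"missing discrete parent {e}") from e
        return key

    def params_for(self, assignment: Mapping[str, object], prior_sigma2: float):
        key = self.config_for(assignment)
        if key in self.by_config:
            return self.by_config[key]
        # unseen configuration: prior-only fallback
        return {
            "alpha": 0.0,
            "beta": np.zeros(len(self.continuous_parents)),
            "sigma2": prior_sigma2,
            "n": 0,
        }


@dataclass
class DirichletFamilyCounts:
    """Per-configuration prior masses and observed counts for each state."""

    discrete_parents: list[str]
    states: list[str]
    alpha_cell: float
    counts: dict[tuple, dict[str, int]]  # config -> state -> n

    def config_for(self, assignment: Mapping[str, object]) -> tuple:
        if not self.discrete_parents:
            return NO_CONFIG
        try:
            return tuple(str(assignment[p]) for p in self.discrete_parents)
        except KeyError as e:
            raise IncompleteEvidenceError(f"missing discrete parent {e}") from e

    def predictive(self, assignment: Mapping[str, object]) -> dict[str, float]:
        cfg = self.config_for(assignment)
        n_by_state = self.counts.get(cfg, {})
        weights = {
            s: self.alpha_cell + n_by_state.get(s, 0) for s in self.states
        }
        total = sum(weights.values())
        return {s: w / total for s, w in weights.items()}


@dataclass
class FittedDBN:
    """Structure plus posterior-mean CLG parameters and Dirichlet counts."""

    structure: DBNStructure
    continuous_params: dict[str, CLGFamilyParameters]
    discrete_params: dict[str, DirichletFamilyCounts]
    priors: PriorHyperparameters
    log_score: float

    @property
    def children(self) -> list[str]:
        return self.structure.children

    def to_json_dict(self) -> dict:
        cont = {}
        for child, fam in self.continuous_params.items():
            cont[child] = {
                "continuous_parents": fam.continuous_parents,
                "discrete_parents": fam.discrete_parents,
                "by_config": [
                    {
                        "config": list(cfg),
                        "alpha": p["alpha"],
                        "beta": list(np.asarray(p["beta"], dtype=float)),
                        "sigma2": p["sigma2"],
                        "n": p["n"],
                    }
                    for cfg, p in sorted(fam.by_config.items())
                ],
            }
        disc = {}
        for child, fam in self.discrete_params.items():
            disc[child] = {
                "discrete_parents": fam.discrete_parents,
                "states": fam.states,
                "alpha_cell": fam.alpha_cell,
                "counts": [
                    {"config": list(cfg), "n": dict(n)}
                    for cfg, n in sorted(fam.counts.items())
                ],
            }
        return {
            "structure": self.structure.to_json_dict(),
            "continuous_params": cont,
            "discrete_params": disc,
            "priors": {
                "nu": self.priors.nu,
                "sigma2": self.priors.sigma2,
                "max_parents": self.priors.max_parents,
                "dirichlet_alpha_total": self.priors.dirichlet_alpha_total,
            },
            "log_score": self.log_score,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json_dict(), indent=2))

    @classmethod
    def from_json_dict(cls, d: Mapping) -> "FittedDBN":
        structure = DBNStructure.from_json_dict(d["structure"])
        cont = {}
        for child, fam in d["continuous_params"].items():
            cont[child] = CLGFamilyParameters(
                continuous_parents=list(fam["continuous_parents"]),
                discrete_parents=list(fam["discrete_parents"]),
                by_config={
                    tuple(p["config"]): {
                        "alpha": p["alpha"],
                        "beta": np.asarray(p["beta"], dtype=float),
                        "sigma2": p["sigma2"],
                        "n": p["n"],
                    }
                    for p in fam["by_config"]
                },
            )
        disc = {}
        for child, fam in d["discrete_params"].items():
            disc[child] = DirichletFamilyCounts(
                discrete_parents=list(fam["discrete_parents"]),
                states=list(fam["states"]),
                alpha_cell=fam["alpha_cell"],
                counts={
                    tuple(c["config"]): {k: int(v) for k, v in c["n"].items()}
                    for c in fam["counts"]
                },
            )
        pr = d["priors"]
        priors = PriorHyperparameters(
            nu=pr["nu"],
            sigma2=pr["sigma2"],
            max_parents=pr["max_parents"],
            dirichlet_alpha_total=pr["dirichlet_alpha_total"],
        )
        return cls(structure, cont, disc, priors, float(d["log_score"]))

    @classmethod
    def from_json(cls, path: str | Path) -> "FittedDBN":
        return cls.from_json_dict(json.loads(Path(path).read_text()))


def _fit_continuous_family(
    y: np.ndarray,
    X: np.ndarray,
    labels: list[np.ndarray],
    cont_parents: list[str],
    disc_parents: list[str],
    priors: PriorHyperparameters,
) -> CLGFamilyParameters:
    nu, sigma2 = priors.nu, priors.sigma2

    def fit_block(yb: np.ndarray, Xb: np.ndarray) -> dict:
        n = len(yb)
        if n == 0:
            return {
                "alpha": 0.0,
                "beta": np.zeros(len(cont_parents)),
                "sigma2": sigma2,
                "n": 0,
            }
        Xd = np.column_stack([np.ones(n), Xb]) if Xb.size else np.ones((n, 1))
        d = Xd.shape[1]
        Vn_inv = nu * np.eye(d) + Xd.T @ Xd
        wn = np.linalg.solve(Vn_inv, Xd.T @ yb)
        an = nu / 2.0 + n / 2.0
        bn = nu * sigma2 / 2.0 + 0.5 * (float(yb @ yb) - float(wn @ Vn_inv @ wn))
        bn = max(bn, 1e-300)
        # posterior mean of sigma^2 (inverse-gamma); an > 1 whenever nu + n > 2
        s2 = bn / (an - 1.0) if an > 1.0 else bn / an
        return {
            "alpha": float(wn[0]),
            "beta": np.asarray(wn[1:], dtype=float),
            "sigma2": float(s2),
            "n": int(n),
        }

    by_config: dict[tuple, dict] = {}
    if not disc_parents:
        by_config[NO_CONFIG] = fit_block(y, X)
    else:
        codes, configs = _config_codes(labels)
        for code, cfg in enumerate(configs):
            mask = codes == code
            by_config[cfg] = fit_block(y[mask], X[mask])
    return CLGFamilyParameters(
        continuous_parents=list(cont_parents),
        discrete_parents=list(disc_parents),
        by_config=by_config,
    )


def _fit_discrete_family(
    z: np.ndarray,
    labels: list[np.ndarray],
    disc_parents: list[str],
    priors: PriorHyperparameters,
    states: Sequence[str] | None = None,
) -> DirichletFamilyCounts:
    z = np.asarray(z).astype(str)
    if states is None:
        states = sorted(set(z.tolist()))
    states = sorted(set(str(s) for s in states) | set(z.tolist()))
    if disc_parents:
        codes, configs = _config_codes(labels)
    else:
        codes = np.zeros(len(z), dtype=int)
        configs = [NO_CONFIG]
    alpha_cell = priors.alpha_total / (max(len(configs), 1) * max(len(states), 1))
    counts: dict[tuple, dict[str, int]] = {}
    for code, cfg in enumerate(configs):
        zc = z[codes == code]
        counts[cfg] = {s: int((zc == s).sum()) for s in states}
    return DirichletFamilyCounts(
        discrete_parents=list(disc_parents),
        states=list(states),
        alpha_cell=float(alpha_cell),
        counts=counts,
    )


def fit_parameters(
    structure: DBNStructure,
    table: TransitionTable,
    priors: PriorHyperparameters,
) -> FittedDBN:
    """Fit posterior-mean CLG parameters and Dirichlet counts per child."""
    cont_params: dict[str, CLGFamilyParameters] = {}
    disc_params: dict[str, DirichletFamilyCounts] = {}
    for child in structure.children:
        spec = structure.node(child)
        cont, disc = structure.split_parents(child)
        y, X, labels = _family_arrays(structure, table, child)
        if spec.kind == "continuous":
            cont_params[child] = _fit_continuous_family(
                y, X, labels, cont, disc, priors
            )
        else:
            disc_params[child] = _fit_discrete_family(y, labels, disc, priors)
    score = network_log_score(structure, table, priors)
    return FittedDBN(structure, cont_params, disc_params, priors, score)


def conditional_mean(
    fitted: FittedDBN, child: str, parent_values: Mapping[str, object]
) -> float:
    """CLG conditional mean alpha(u) + beta(u) . v for a continuous child."""
    fam = fitted.continuous_params[child]
    params = fam.params_for(parent_values, fitted.priors.sigma2)
    try:
        v = np.array(
            [float(parent_values[p]) for p in fam.continuous_parents], dtype=float
        )
    except KeyError as e:
        raise IncompleteEvidenceError(f"missing continuous parent {e}") from e
    return float(params["alpha"] + params["beta"] @ v)


def conditional_log_density(
    fitted: FittedDBN,
    child: str,
    child_value,
    parent_values: Mapping[str, object],
) -> float:
    """Plug-in log density of one child's observed value at t+1.

    Continuous children: Normal(alpha(u) + beta(u).v, sigma2(u)).  Discrete
    children: the Dirichlet-multinomial predictive probability of the
    observed state.
    """
    spec = fitted.structure.node(child)
    if spec.kind == "continuous":
        fam = fitted.continuous_params[child]
        params = fam.params_for(parent_values, fitted.priors.sigma2)
        mu = conditional_mean(fitted, child, parent_values)
        s2 = params["sigma2"]
        return float(
            -0.5 * LOG_2PI - 0.5 * math.log(s2) - (float(child_value) - mu) ** 2 / (2 * s2)
        )
    fam = fitted.discrete_params[child]
    probs = fam.predictive(parent_values)
    state = str(child_value)
    p = probs.get(state)
    if p is None:
        # state unseen in training: treat as an extra category carrying only
        # prior mass, renormalizing the predictive accordingly
        cfg = fam.config_for(parent_values)
        n_by_state = fam.counts.get(cfg, {})
        denom = (len(fam.states) + 1) * fam.alpha_cell + sum(n_by_state.values())
        p = fam.alpha_cell / denom
    return float(math.log(p))


def discrete_predictive(
    fitted: FittedDBN, child: str, parent_config: Mapping[str, object]
) -> dict[str, float]:
    """Predictive distribution over a discrete child's states."""
    return fitted.discrete_params[child].predictive(parent_config)
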