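"""Greedy hill-climbing search over two-slice structures.

Starting from the empty network, the search repeatedly applies the single
edge addition or deletion with the largest score gain until no move improves
the decomposable network score.  Ties are broken deterministically: delete
before add, then lexicographic (parent, child).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from tsdbn.cgbn_core import (
    DBNStructure,
    NodeSpec,
    PriorHyperparameters,
    family_log_score,
)
from tsdbn.data_io import TransitionTable
from tsdbn.errors import StructureError

logger = logging.getLogger(__name__)

#: Minimum score gain for a move to be accepted.
IMPROVEMENT_TOLERANCE = 1e-9


@dataclass(frozen=True)
class SearchMove:
    """One candidate move: add or delete a (parent at t -> child at t+1) edge."""

    kind: str  # {"add", "delete"}
    edge: tuple[str, str]
    delta_score: float


@dataclass(frozen=True)
class EdgeReport:
    """Edge with its natural-log Bayes factor (score with vs. without it)."""

    edge: tuple[str, str]
    ln_bayes_factor: float


def default_nodes(
    taxa: Sequence[str],
    continuous_covariates: Sequence[str],
    discrete_covariates: Sequence[str],
    covariates_as_children: bool = False,
) -> list[NodeSpec]:
    """Node specs for the standard model: taxa are children, covariates
    default to exogenous clock variables observed at slice t only."""
    nodes = [NodeSpec(t, "continuous", "both") for t in taxa]
    cov_role = "both" if covariates_as_children else "t_only"
    nodes += [NodeSpec(c, "continuous", "t_only") for c in continuous_covariates]
    nodes += [NodeSpec(c, "discrete", cov_role) for c in discrete_covariates]
    return nodes


def _family_scorer(table: TransitionTable, priors: PriorHyperparameters):
    """Memoized family score keyed by (child, parent tuple)."""
    cache: dict[tuple, float] = {}

    def score(structure: DBNStructure, child: str) -> float:
        key = (child, structure.parent_sets.get(child, ()))
        if key not in cache:
            cache[key] = family_log_score(structure, table, child, priors)
        return cache[key]

    return score


def hill_climb(
    table: TransitionTable,
    priors: PriorHyperparameters,
    nodes: Sequence[NodeSpec] | None = None,
    candidate_children: Sequence[str] | None = None,
    candidate_parents: Sequence[str] | None = None,
) -> tuple[DBNStructure, list[float]]:
    """Greedy add/delete search; returns (structure, score trajectory).

    ``nodes`` defaults to the standard taxa + covariate layout of ``table``.
    Children default to every node with a modeled t+1 value; parents default
    to every node observable at slice t.  The returned structure is a local
    optimum: no single add or delete improves the score by more than
    :data:`IMPROVEMENT_TOLERANCE`.
    """
    if nodes is None:
        nodes = default_nodes(
            table.taxa, table.continuous_covariates, table.discrete_covariates
        )
    by_name = {n.name: n for n in nodes}
    if candidate_children is None:
        candidate_children = [
            n.name
            for n in nodes
            if n.slice_role in ("both", "t1_only") and table.has_target(n.name)
        ]
    if candidate_parents is None:
        candidate_parents = [
            n.name for n in nodes if n.slice_role in ("both", "t_only")
        ]
    if not candidate_children or not candidate_parents:
        raise ValueError("candidate children and parents must be nonempty")

    structure = DBNStructure(
        list(nodes),
        {c: () for c in sorted(candidate_children)},
        max_parents=priors.max_parents,
    )
    scorer = _family_scorer(table, priors)
    family_scores = {c: scorer(structure, c) for c in structure.children}
    trajectory = [sum(family_scores.values())]

    while True:
        best: SearchMove | None = None
        for child in sorted(candidate_children):
            parents = structure.parent_sets[child]
            current = family_scores[child]
            # deletions first so equal-delta ties prefer delete
            for parent in parents:
                cand = structure.without_edge(parent, child)
                delta = scorer(cand, child) - current
                move = SearchMove("delete", (parent, child), delta)
                if _better(move, best):
                    best = move
            if len(parents) < priors.max_parents:
                for parent in sorted(candidate_parents):
                    if parent in parents:
                        continue
                    if (
                        by_name[child].kind == "discrete"
                        and by_name[parent].kind != "discrete"
                    ):
                        continue
                    cand = structure.with_edge(parent, child)
                    delta = scorer(cand, child) - current
                    move = SearchMove("add", (parent, child), delta)
                    if _better(move, best):
                        best = move
        if best is None or best.delta_score <= IMPROVEMENT_TOLERANCE:
            break
        parent, child = best.edge
        if best.kind == "add":
            structure = structure.with_edge(parent, child)
        else:
            structure = structure.without_edge(parent, child)
        family_scores[child] = scorer(structure, child)
        trajectory.append(sum(family_scores.values()))
        logger.debug(
            "%s %s -> %s (delta %.6g, score %.6g)",
            best.kind,
            parent,
            child,
            best.delta_score,
            trajectory[-1],
        )
    return structure, trajectory


def _better(move: SearchMove, best: SearchMove | None) -> bool:
    if best is None:
        return True
    if move.delta_score != best.delta_score:
        return move.delta_score > best.delta_score
    # ties: delete beats add, then lexicographic (parent, child)
    rank = {"delete": 0, "add": 1}
    return (rank[move.kind], move.edge) < (rank[best.kind], best.edge)


def edge_bayes_factor(
    structure: DBNStructure,
    edge: tuple[str, str],
    table: TransitionTable,
    priors: PriorHyperparameters,
) -> float:
    """Natural-log Bayes factor of one retained edge.

    network score with the edge minus the score with that single edge
    removed; only the affected child's family is recomputed.
    """
    parent, child = edge
    if parent not in structure.parent_sets.get(child, ()):
        raise StructureError(f"edge {parent!r}->{child!r} not in structure")
    with_edge = family_log_score(structure, table, child, priors)
    without = family_log_score(
        structure.without_edge(parent, child), table, child, priors
    )
    return float(with_edge - without)


def edge_report(
    structure: DBNStructure,
    table: TransitionTable,
    priors: PriorHyperparameters,
) -> list[EdgeReport]:
    """Bayes factor for every edge of the structure, in sorted edge order."""
    return [
        EdgeReport(edge, edge_bayes_factor(structure, edge, table, priors))
        for edge in structure.edges
    ]
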