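import math

import numpy as np
import pytest
from scipy.special import gammaln

from tsdbn.cgbn_core import (
    DBNStructure,
    NodeSpec,
    PriorHyperparameters,
    conditional_log_density,
    discrete_predictive,
    family_log_score,
    family_log_score_continuous,
    family_log_score_discrete,
    fit_parameters,
    network_log_score,
)
from tsdbn.data_io import TransitionTable
from tsdbn.errors import StructureError
from tsdbn.synthetic_data import simulate_planted_var

import oracles

PRIORS = PriorHyperparameters(nu=10.0, sigma2=1.0, max_parents=3)


def make_table(data: dict, taxa, disc=()):
    import pandas as pd

    frame = pd.DataFrame(data)
    frame["subject_id"] = "S1"
    frame["gap_days"] = 1
    frame["target_day"] = range(len(frame))
    return TransitionTable(
        frame,
        taxa=list(taxa),
        continuous_covariates=[],
        discrete_covariates=list(disc),
    )


class TestContinuousFamilyScore:
    def test_empty_is_zero(self):
        assert family_log_score_continuous(np.array([]), None, None, PRIORS) == 0.0

    def test_matches_quadrature_printed_vector(self):
        # n=5 toy vector with one continuous parent
        y = np.array([0.12, -0.54, 1.33, 0.20, -0.88])
        x = np.array([0.5, -0.2, 1.1, 0.0, -0.9])
        ours = family_log_score_continuous(y, x[:, None], None, PRIORS)
        oracle = oracles.nig_log_evidence_quadrature(y, x[:, None], 10.0, 1.0)
        assert ours == pytest.approx(oracle, rel=1e-4)

    def test_row_permutation_invariant(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=8)
        X = rng.normal(size=(8, 2))
        perm = rng.permutation(8)
        a = family_log_score_continuous(y, X, None, PRIORS)
        b = family_log_score_continuous(y[perm], X[perm], None, PRIORS)
        assert a == pytest.approx(b, rel=1e-12)

    def test_discrete_parent_partitions_and_sums(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=10)
        X = rng.normal(size=(10, 1))
        labels = np.array(["a"] * 4 + ["b"] * 6)
        whole = family_log_score_continuous(y, X, [labels], PRIORS)
        parts = family_log_score_continuous(
            y[:4], X[:4], None, PRIORS
        ) + family_log_score_continuous(y[4:], X[4:], None, PRIORS)
        assert whole == pytest.approx(parts, rel=1e-12)

    def test_prequential_identity(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            n = int(rng.integers(2, 9))
            p = int(rng.integers(0, 3))
            y = rng.normal(size=n)
            X = rng.normal(size=(n, p))
            ours = family_log_score_continuous(y, X, None, PRIORS)
            preq = oracles.prequential_log_evidence(y, X, 10.0, 1.0)
            assert ours == pytest.approx(preq, rel=1e-9)

    def test_collinear_parents_finite(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=6)
        X = np.column_stack([x, x])  # perfectly collinear
        y = rng.normal(size=6)
        score = family_log_score_continuous(y, X, None, PRIORS)
        assert np.isfinite(score)

    def test_noise_parent_penalized(self):
        # pure-noise data: adding a parent should usually lower the score
        rng = np.random.default_rng(4)
        worse = 0
        n_rep = 20
        for _ in range(n_rep):
            y = rng.normal(size=200)
            x = rng.normal(size=(200, 1))
            without = family_log_score_continuous(y, None, None, PRIORS)
            with_parent = family_log_score_continuous(y, x, None, PRIORS)
            worse += with_parent < without
        assert worse >= 0.9 * n_rep


class TestDiscreteFamilyScore:
    def test_empty_is_zero(self):
        assert family_log_score_discrete(np.array([]), None, PRIORS) == 0.0

    def test_printed_gamma_identity(self):
        # binary child, counts (3, 1), total prior mass 1 (0.5 per state):
        # evidence = G(1)/G(5) * G(3.5)/G(0.5) * G(1.5)/G(0.5)
        labels = np.array(["x", "x", "x", "y"])
        priors = PriorHyperparameters(nu=10.0, dirichlet_alpha_total=1.0)
        ours = family_log_score_discrete(labels, None, priors)
        expected = (
            gammaln(1.0)
            - gammaln(5.0)
            + gammaln(3.5)
            - gammaln(0.5)
            + gammaln(1.5)
            - gammaln(0.5)
        )
        assert ours == pytest.approx(float(expected), rel=1e-12)

    def test_matches_direct_oracle_with_parent(self):
        child = np.array(["a", "a", "b", "b", "a", "b", "b"])
        parent = np.array(["p", "q", "p", "q", "p", "q", "q"])
        priors = PriorHyperparameters(nu=10.0, dirichlet_alpha_total=2.0)
        ours = family_log_score_discrete(child, [parent], priors)
        # 2 configs x 2 states -> 0.5 prior mass per cell
        expected = oracles.dirichlet_multinomial_log_evidence(
            {"a": 2, "b": 1}, {"a": 0.5, "b": 0.5}
        ) + oracles.dirichlet_multinomial_log_evidence(
            {"a": 1, "b": 3}, {"a": 0.5, "b": 0.5}
        )
        assert ours == pytest.approx(expected, rel=1e-12)

    def test_relabeling_invariant(self):
        labels = np.array(["u", "v", "u", "u", "w"])
        relabeled = np.array(["1", "2", "1", "1", "3"])
        a = family_log_score_discrete(labels, None, PRIORS)
        b = family_log_score_discrete(relabeled, None, PRIORS)
        assert a == pytest.approx(b, rel=1e-12)


class TestNetworkScore:
    def _nodes(self):
        return [
            NodeSpec("A", "continuous", "both"),
            NodeSpec("B", "continuous", "both"),
            NodeSpec("C", "continuous", "both"),
        ]

    def _table(self, n=30, seed=0):
        rng = np.random.default_rng(seed)
        data = {}
        for name in "ABC":
            data[name + ":t"] = rng.normal(size=n)
            data[name + ":t1"] = rng.normal(size=n)
        return make_table(data, taxa=["A", "B", "C"])

    def test_decomposability(self):
        table = self._table()
        structure = DBNStructure(
            self._nodes(), {"A": ("B",), "B": (), "C": ("A", "C")}, 3
        )
        total = network_log_score(structure, table, PRIORS)
        parts = sum(
            family_log_score(structure, table, c, PRIORS) for c in "ABC"
        )
        assert total == pytest.approx(parts, rel=1e-12)

    def test_edge_addition_changes_only_that_family(self):
        table = self._table()
        base = DBNStructure(self._nodes(), {"A": (), "B": (), "C": ()}, 3)
        with_edge = base.with_edge("B", "A")
        for child in "BC":
            assert family_log_score(base, table, child, PRIORS) == pytest.approx(
                family_log_score(with_edge, table, child, PRIORS)
            )
        assert family_log_score(base, table, "A", PRIORS) != family_log_score(
            with_edge, table, "A", PRIORS
        )

    def test_brute_force_resummation(self):
        table = self._table(seed=5)
        structure = DBNStructure(self._nodes(), {"A": ("A",), "B": ("A", "C"), "C": ()}, 3)
        expected = 0.0
        for child in "ABC":
            cont, _ = structure.split_parents(child)
            y = table.target_values(child)
            X = (
                np.column_stack([table.source_values(p) for p in cont])
                if cont
                else None
            )
            expected += family_log_score_continuous(y, X, None, PRIORS)
        assert network_log_score(structure, table, PRIORS) == pytest.approx(expected)

    def test_discrete_child_with_continuous_parent_rejected(self):
        nodes = self._nodes() + [NodeSpec("D", "discrete", "both")]
        with pytest.raises(StructureError):
            DBNStructure(nodes, {"D": ("A",)}, 3)

    def test_max_parents_enforced(self):
        with pytest.raises(StructureError):
            DBNStructure(self._nodes(), {"A": ("A", "B", "C")}, 2)


class TestFitParameters:
    def test_parent_free_posterior_mean(self):
        rng = np.random.default_rng(6)
        y = rng.normal(2.0, 0.5, size=2000)
        table = make_table({"A:t": np.zeros(2000), "A:t1": y}, taxa=["A"])
        structure = DBNStructure([NodeSpec("A", "continuous", "both")], {"A": ()}, 3)
        fitted = fit_parameters(structure, table, PRIORS)
        params = fitted.continuous_params["A"].by_config[()]
        # textbook conjugate update
        n, nu = len(y), 10.0
        expected_alpha = y.sum() / (nu + n)
        assert params["alpha"] == pytest.approx(expected_alpha, rel=1e-9)
        an = nu / 2 + n / 2
        bn = nu / 2 + 0.5 * (y @ y - (y.sum() ** 2) / (nu + n))
        assert params["sigma2"] == pytest.approx(bn / (an - 1), rel=1e-9)
        assert params["alpha"] == pytest.approx(y.mean(), rel=1e-2)

    def test_parameter_recovery_single_parent(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=1000)
        y = 2.0 * x + rng.normal(0, 0.1, size=1000)
        table = make_table(
            {"X:t": x, "X:t1": rng.normal(size=1000), "Y:t": y, "Y:t1": y},
            taxa=["X", "Y"],
        )
        nodes = [NodeSpec("X", "continuous", "both"), NodeSpec("Y", "continuous", "both")]
        structure = DBNStructure(nodes, {"Y": ("X",), "X": ()}, 3)
        fitted = fit_parameters(structure, table, PRIORS)
        beta = fitted.continuous_params["Y"].by_config[()]["beta"][0]
        assert 1.9 <= beta <= 2.1

    def test_empty_configuration_prior_fallback(self):
        y = np.array([0.5, 0.7])
        table = make_table(
            {"A:t": [0.1, 0.2], "A:t1": y, "R:t": ["u", "u"]},
            taxa=["A"],
            disc=["R"],
        )
        nodes = [
            NodeSpec("A", "continuous", "both"),
            NodeSpec("R", "discrete", "t_only"),
        ]
        structure = DBNStructure(nodes, {"A": ("R",)}, 3)
        fitted = fit_parameters(structure, table, PRIORS)
        fam = fitted.continuous_params["A"]
        unseen = fam.params_for({"R": "never-seen"}, PRIORS.sigma2)
        assert unseen["alpha"] == 0.0
        assert unseen["sigma2"] == PRIORS.sigma2
        assert unseen["n"] == 0

    def test_json_roundtrip(self):
        from tsdbn.cgbn_core import FittedDBN

        rng = np.random.default_rng(8)
        table = make_table(
            {"A:t": rng.normal(size=20), "A:t1": rng.normal(size=20)}, taxa=["A"]
        )
        structure = DBNStructure([NodeSpec("A", "continuous", "both")], {"A": ("A",)}, 3)
        fitted = fit_parameters(structure, table, PRIORS)
        again = FittedDBN.from_json_dict(fitted.to_json_dict())
        assert again.structure.edges == fitted.structure.edges
        p0 = fitted.continuous_params["A"].by_config[()]
        p1 = again.continuous_params["A"].by_config[()]
        assert p1["alpha"] == pytest.approx(p0["alpha"])
        assert p1["sigma2"] == pytest.approx(p0["sigma2"])


class TestDensitiesAndPredictive:
    def _fitted_single(self, alpha=0.0, beta=1.0, sigma2=1.0):
        from tsdbn.cgbn_core import CLGFamilyParameters, FittedDBN

        nodes = [NodeSpec("X", "continuous", "t_only"), NodeSpec("Y", "continuous", "both")]
        structure = DBNStructure(nodes, {"Y": ("X",)}, 3)
        params = CLGFamilyParameters(
            continuous_parents=["X"],
            discrete_parents=[],
            by_config={(): {"alpha": alpha, "beta": np.array([beta]), "sigma2": sigma2, "n": 10}},
        )
        return FittedDBN(structure, {"Y": params}, {}, PRIORS, 0.0)

    def test_density_at_mode_standard_normal(self):
        fitted = self._fitted_single(alpha=0.3, beta=0.5, sigma2=1.0)
        value = 0.3 + 0.5 * 0.4
        ld = conditional_log_density(fitted, "Y", value, {"X": 0.4})
        assert ld == pytest.approx(-0.5 * math.log(2 * math.pi))

    def test_density_three_sigma(self):
        sigma2 = 0.25
        fitted = self._fitted_single(alpha=0.0, beta=0.0, sigma2=sigma2)
        value = 3.0 * math.sqrt(sigma2)
        ld = conditional_log_density(fitted, "Y", value, {"X": 0.0})
        assert ld == pytest.approx(-0.5 * math.log(2 * math.pi * sigma2) - 4.5)

    def test_missing_parent_raises(self):
        from tsdbn.errors import IncompleteEvidenceError

        fitted = self._fitted_single()
        with pytest.raises(IncompleteEvidenceError):
            conditional_log_density(fitted, "Y", 0.0, {})

    def _fitted_discrete(self):
        from tsdbn.cgbn_core import DirichletFamilyCounts, FittedDBN

        nodes = [NodeSpec("D", "discrete", "both")]
        structure = DBNStructure(nodes, {"D": ()}, 3)
        fam = DirichletFamilyCounts(
            discrete_parents=[],
            states=["a", "b"],
            alpha_cell=0.5,
            counts={(): {"a": 3, "b": 1}},
        )
        return FittedDBN(structure, {}, {"D": fam}, PRIORS, 0.0)

    def test_dirichlet_predictive_mean(self):
        fitted = self._fitted_discrete()
        ld = conditional_log_density(fitted, "D", "a", {})
        assert ld == pytest.approx(math.log(3.5 / 5.0))

    def test_predictive_counts_31_symmetric_prior(self):
        fitted = self._fitted_discrete()
        probs = discrete_predictive(fitted, "D", {})
        assert probs["a"] == pytest.approx(0.7)
        assert probs["b"] == pytest.approx(0.3)

    def test_predictive_no_data_uniform(self):
        from tsdbn.cgbn_core import DirichletFamilyCounts, FittedDBN

        nodes = [NodeSpec("D", "discrete", "both")]
        structure = DBNStructure(nodes, {"D": ()}, 3)
        fam = DirichletFamilyCounts(
            discrete_parents=[], states=["a", "b"], alpha_cell=0.5, counts={}
        )
        fitted = FittedDBN(structure, {}, {"D": fam}, PRIORS, 0.0)
        probs = discrete_predictive(fitted, "D", {})
        assert probs == {"a": 0.5, "b": 0.5}

    def test_predictive_sums_to_one_random_counts(self):
        from tsdbn.cgbn_core import DirichletFamilyCounts, FittedDBN

        rng = np.random.default_rng(9)
        counts = {s: int(c) for s, c in zip("abcd", rng.integers(0, 30, 4))}
        nodes = [NodeSpec("D", "discrete", "both")]
        structure = DBNStructure(nodes, {"D": ()}, 3)
        fam = DirichletFamilyCounts(
            discrete_parents=[], states=list("abcd"), alpha_cell=0.25,
            counts={(): counts},
        )
        fitted = FittedDBN(structure, {}, {"D": fam}, PRIORS, 0.0)
        probs = discrete_predictive(fitted, "D", {})
        assert sum(probs.values()) == pytest.approx(1.0)


class TestPlantedVarFit:
    def test_planted_coefficients_recovered(self):
        table, edges, coefficients = simulate_planted_var(
            n_nodes=6, n_subjects=40, samples_per_subject=20, seed=5
        )
        nodes = [NodeSpec(t, "continuous", "both") for t in table.taxa]
        parent_sets = {
            child: tuple(sorted(coefficients[child])) for child in table.taxa
        }
        structure = DBNStructure(nodes, parent_sets, 3)
        fitted = fit_parameters(structure, table, PRIORS)
        for child, true in coefficients.items():
            fam = fitted.continuous_params[child]
            params = fam.by_config[()]
            y = table.target_values(child)
            X = np.column_stack(
                [table.source_values(p) for p in fam.continuous_parents]
            )
            _, se = oracles.ols_coefficients(y, X)
            for j, parent in enumerate(fam.continuous_parents):
                assert abs(params["beta"][j] - true[parent]) < 3 * se[j + 1]
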