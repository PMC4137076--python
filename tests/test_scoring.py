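"""Path probabilities, indication renormalization and the decision rule."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from _oracles import double_loop_mixture
from phenolda import (
    DecisionCriteria,
    LDAConfig,
    LDAModel,
    PhenomeMatrix,
    indication_probabilities,
    phenotype_probabilities,
    random_chance,
    rank_and_decide,
)
from phenolda.scoring import mixture_scores


def _model(theta, phi):
    theta = np.asarray(theta, float)
    phi = np.asarray(phi, float)
    return LDAModel(
        theta=theta,
        phi=phi,
        config=LDAConfig(n_topics=phi.shape[0]),
        drug_ids=[f"d{i}" for i in range(theta.shape[0])],
        vocabulary=[f"t{j}" for j in range(phi.shape[1])],
    )


def _matrix(n_drugs, n_se, n_ind, ones=()):
    X = np.zeros((n_drugs, n_se + n_ind), dtype=np.uint8)
    for i, j in ones:
        X[i, j] = 1
    is_ind = np.array([False] * n_se + [True] * n_ind)
    return PhenomeMatrix(
        [f"d{i}" for i in range(n_drugs)],
        [f"t{j}" for j in range(n_se + n_ind)],
        is_ind,
        X,
    )


class TestPhenotypeProbabilities:
    def test_hand_computed_dot_product(self):
        # p(ph1|d) = 0.6*0.7 + 0.4*0.2 = 0.50
        model = _model([[0.6, 0.4]], [[0.7, 0.3], [0.2, 0.8]])
        p = phenotype_probabilities(model)
        assert p.values[0, 0] == pytest.approx(0.50)

    def test_single_topic_rows_equal_phi(self):
        phi = np.array([[0.2, 0.3, 0.5]])
        model = _model([[1.0], [1.0]], phi)
        p = phenotype_probabilities(model)
        assert np.array_equal(p.values, np.vstack([phi[0], phi[0]]))

    def test_equals_double_loop_oracle_exactly(self, rng):
        for _ in range(100):
            M = rng.integers(1, 11)
            K = rng.integers(1, 6)
            N = rng.integers(1, 21)
            theta = rng.dirichlet(np.ones(K), size=M)
            phi = rng.dirichlet(np.ones(N), size=K)
            ours = phenotype_probabilities(_model(theta, phi)).values
            oracle = double_loop_mixture(theta, phi)
            assert np.array_equal(ours, oracle)

    @given(
        hnp.arrays(np.float64, (5, 3), elements=st.floats(0.01, 1.0)),
        hnp.arrays(np.float64, (3, 7), elements=st.floats(0.01, 1.0)),
    )
    def test_normalized_rows_stay_normalized(self, th, ph):
        th = th / th.sum(axis=1, keepdims=True)
        ph = ph / ph.sum(axis=1, keepdims=True)
        out = mixture_scores(th, ph)
        assert np.allclose(out.sum(axis=1), 1.0)
        assert (out >= 0).all()

    def test_dimension_mismatch_errors(self):
        with pytest.raises(ValueError, match="mismatch"):
            mixture_scores(np.ones((2, 3)), np.ones((2, 4)))


class TestIndicationProbabilities:
    def test_hand_renormalization(self):
        # raw indication probabilities (0.02, 0.02, 0.01) -> (0.4, 0.4, 0.2)
        m = _matrix(1, 1, 3)
        model = _model([[1.0]], [[0.95, 0.02, 0.02, 0.01]])
        pid = indication_probabilities(phenotype_probabilities(model), m)
        assert np.allclose(pid.values[0], [0.4, 0.4, 0.2])

    def test_single_indication_column_gives_probability_one(self):
        m = _matrix(2, 2, 1)
        model = _model([[1.0], [1.0]], [[0.5, 0.3, 0.2]])
        pid = indication_probabilities(phenotype_probabilities(model), m)
        assert np.allclose(pid.values, 1.0)

    def test_rows_sum_to_one(self, rng):
        m = _matrix(4, 3, 5)
        theta = rng.dirichlet(np.ones(2), size=4)
        phi = rng.dirichlet(np.ones(8), size=2)
        pid = indication_probabilities(phenotype_probabilities(_model(theta, phi)), m)
        assert np.allclose(pid.values.sum(axis=1), 1.0, atol=1e-9)

    def test_renormalization_preserves_within_drug_order(self, rng):
        m = _matrix(3, 2, 6)
        theta = rng.dirichlet(np.ones(3), size=3)
        phi = rng.dirichlet(np.ones(8), size=3)
        pphd = phenotype_probabilities(_model(theta, phi))
        pid = indication_probabilities(pphd, m)
        raw = pphd.values[:, m.indication_columns]
        for d in range(3):
            assert np.array_equal(np.argsort(-raw[d]), np.argsort(-pid.values[d]))

    def test_zero_mass_row_flagged_and_excluded(self):
        m = _matrix(2, 1, 2)
        phi = np.array([[1.0, 0.0, 0.0]])  # all mass on the side effect
        model = _model([[1.0], [1.0]], phi)
        with pytest.warns(UserWarning, match="zero indication-column mass"):
            pid = indication_probabilities(phenotype_probabilities(model), m)
        assert pid.excluded_drugs == ["d0", "d1"]
        with pytest.raises(ValueError, match="excluded"):
            pid.drug_row("d0")


class TestRandomChance:
    def test_sider_scale_counts_round_to_0_005(self):
        assert round(random_chance(12066, 996, 2276), 3) == 0.005

    def test_saturated_matrix(self):
        assert random_chance(1, 1, 1) == 1.0

    def test_matches_brute_force_cell_count(self):
        m = _matrix(2, 0, 5, ones=[(0, 0), (0, 3), (1, 1)])
        frac = m.X[:, m.is_indication].mean()
        q = random_chance(m.n_known_pairs, m.n_drugs, m.n_indications)
        assert q == pytest.approx(frac) == 0.3

    def test_invariant_under_row_and_column_permutation(self, rng):
        ones = [(0, 1), (1, 3), (2, 2), (2, 4)]
        m = _matrix(3, 0, 5, ones=ones)
        q = random_chance(m.n_known_pairs, m.n_drugs, m.n_indications)
        perm_rows = rng.permutation(3)
        perm_cols = rng.permutation(5)
        m2 = PhenomeMatrix(
            [m.drugs[i] for i in perm_rows],
            [m.phenotypes[j] for j in perm_cols],
            m.is_indication[perm_cols],
            m.X[np.ix_(perm_rows, perm_cols)],
        )
        assert random_chance(m2.n_known_pairs, m2.n_drugs, m2.n_indications) == q

    @pytest.mark.parametrize("args", [(0, 5, 5), (3, 0, 5), (30, 2, 5)])
    def test_degenerate_counts_rejected(self, args):
        with pytest.raises(ValueError):
            random_chance(*args)


class TestRankAndDecide:
    def _pid(self, probs, matrix):
        model = _model(
            np.ones((matrix.n_drugs, 1)),
            np.concatenate([np.zeros(matrix.n_side_effects), probs])[None, :],
        )
        return indication_probabilities(phenotype_probabilities(model), matrix)

    def test_stable_tie_break_follows_column_order(self):
        m = _matrix(1, 0, 4)
        pid = self._pid(np.array([0.3, 0.3, 0.2, 0.2]), m)
        crit = DecisionCriteria(q=0.01, n_known_pairs=1, per_drug_is={"d0": 2})
        preds = rank_and_decide(pid, crit, "d0")
        assert [p.rank for p in preds] == [1, 2, 3, 4]
        assert sorted(p.rank for p in preds) == [1, 2, 3, 4]

    def test_zero_indication_drug_uses_default_is_13(self):
        crit = DecisionCriteria(q=0.005, n_known_pairs=10, per_drug_is={"d0": 0})
        assert crit.indication_space("d0") == 13
        assert crit.indication_space("unseen") == 13

    def test_both_criteria_on_three_indication_toy(self):
        m = _matrix(1, 0, 3)
        pid = self._pid(np.array([0.5, 0.004, 0.496]), m)
        crit = DecisionCriteria(q=0.005, n_known_pairs=1, per_drug_is={"d0": 2})
        preds = rank_and_decide(pid, crit, "d0")
        by_term = {p.indication: p for p in preds}
        assert by_term["t0"].above_chance and by_term["t0"].within_is
        assert by_term["t2"].above_chance and by_term["t2"].within_is
        assert not by_term["t1"].above_chance

    def test_boundary_probability_rejected_strictly(self):
        m = _matrix(1, 0, 2)
        pid = self._pid(np.array([0.5, 0.5]), m)
        crit = DecisionCriteria(q=0.5, n_known_pairs=1, per_drug_is={"d0": 1})
        preds = rank_and_decide(pid, crit, "d0")
        assert not any(p.above_chance for p in preds)

    def test_unknown_drug_errors(self):
        m = _matrix(1, 0, 2)
        pid = self._pid(np.array([0.6, 0.4]), m)
        crit = DecisionCriteria(q=0.1, n_known_pairs=1, per_drug_is={})
        with pytest.raises(KeyError):
            rank_and_decide(pid, crit, "nope")


class TestDecisionCriteriaConstruction:
    def test_from_matrix_counts(self):
        m = _matrix(2, 1, 3, ones=[(0, 1), (0, 2), (1, 3), (0, 0)])
        crit = DecisionCriteria.from_matrix(m)
        assert crit.n_known_pairs == 3
        assert crit.q == pytest.approx(3 / 6)
        assert crit.per_drug_is == {"d0": 2, "d1": 1}

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            DecisionCriteria(q=0.0, n_known_pairs=1, per_drug_is={})
        with pytest.raises(ValueError):
            DecisionCriteria(q=0.1, n_known_pairs=1, per_drug_is={}, default_is=0)
        with pytest.raises(ValueError):
            DecisionCriteria(q=0.1, n_known_pairs=1, per_drug_is={"d": -1})
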