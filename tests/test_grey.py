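import numpy as np
import pytest

from fermsense import BatchDataset
from fermsense.grey import (
    GreyConfig,
    coefficient_matrix,
    entropy_weights,
    gate_degrees,
    grey_coefficients,
    grey_degree,
    initial_centroid,
    sample_correlation_matrix,
    select_aux_variables,
    weighted_centroid,
)

CFG = GreyConfig()


def naive_degree(ref, comp, rho=0.5):
    """Spreadsheet-style re-computation of the centred-square grey degree."""
    ref, comp = np.asarray(ref, float), np.asarray(comp, float)
    c0 = (ref - ref.mean()) ** 2
    ci = (comp - comp.mean()) ** 2
    delta = np.abs(c0 - ci)
    if delta.max() <= 0:
        return 1.0
    s = (delta.min() + rho * delta.max()) / (delta + rho * delta.max())
    return float(s.mean())


class TestCoefficients:
    def test_identical_rows_give_ones(self):
        x = np.array([1.0, 2.0, 3.0])
        np.testing.assert_allclose(grey_coefficients(x, x[None, :], CFG), 1.0)

    def test_sign_blindness_of_centred_squares(self):
        # reversed sequence has identical centred squares -> all deltas zero
        s = grey_coefficients(np.array([1.0, 2.0, 3.0]),
                              np.array([[3.0, 2.0, 1.0]]), CFG)
        np.testing.assert_allclose(s, 1.0)

    def test_bounds(self, rng):
        for _ in range(50):
            ref = rng.normal(size=6)
            comps = rng.normal(size=(4, 6))
            s = grey_coefficients(ref, comps, CFG)
            assert (s > 0).all() and (s <= 1 + 1e-12).all()

    def test_empty_comps_rejected(self):
        with pytest.raises(ValueError):
            grey_coefficients(np.ones(3), np.empty((0, 3)), CFG)


class TestDegree:
    def test_self_degree_is_one(self, rng):
        x = rng.normal(size=8)
        assert grey_degree(x, x, CFG) == 1.0

    def test_degree_is_mean_of_coefficients(self, rng):
        ref, comp = rng.normal(size=5), rng.normal(size=5)
        s = grey_coefficients(ref, comp[None, :], CFG)
        phi = grey_degree(ref, comp, CFG)
        assert s.min() - 1e-12 <= phi <= s.max() + 1e-12
        assert phi == pytest.approx(s.mean())

    def test_matches_hand_oracle(self, rng):
        for _ in range(30):
            ref, comp = rng.normal(size=7), rng.normal(size=7)
            assert grey_degree(ref, comp, CFG) == pytest.approx(
                naive_degree(ref, comp), abs=1e-10)


class TestSampleMatrix:
    def test_identical_rows_all_ones(self):
        rows = np.tile(np.array([1.0, 2.0, 4.0]), (4, 1))
        np.testing.assert_allclose(sample_correlation_matrix(rows, CFG), 1.0)

    def test_unit_diagonal(self, rng):
        rows = rng.normal(size=(6, 5))
        phi = sample_correlation_matrix(rows, CFG)
        np.testing.assert_allclose(np.diag(phi), 1.0)

    def test_matches_pairwise_loop(self, rng):
        rows = rng.normal(size=(8, 4))
        phi = sample_correlation_matrix(rows, CFG)
        for i in range(8):
            for j in range(8):
                if i != j:
                    assert phi[i, j] == pytest.approx(
                        naive_degree(rows[i], rows[j]), abs=1e-12)


class TestInitialCentroid:
    def test_two_rows_tie_returns_first(self, rng):
        rows = rng.normal(size=(2, 4))
        phi = sample_correlation_matrix(rows, CFG)
        assert initial_centroid(phi) == 0

    def test_cluster_plus_outlier(self, rng):
        base = np.array([1.0, 5.0, 2.0, 8.0])
        rows = np.vstack([base + 0.01 * rng.normal(size=4) for _ in range(6)]
                         + [np.array([50.0, -3.0, 20.0, 0.0])])
        phi = sample_correlation_matrix(rows, CFG)
        assert initial_centroid(phi) < 6  # the outlier is never the centroid

    def test_permutation_equivariance(self, rng):
        rows = rng.normal(size=(7, 5))
        phi = sample_correlation_matrix(rows, CFG)
        c = initial_centroid(phi)
        perm = rng.permutation(7)
        phi_p = sample_correlation_matrix(rows[perm], CFG)
        # guard against exact ties which permute unpredictably
        off = (phi.sum(axis=1) - 1) / 6
        if np.sum(np.isclose(off, off.max())) == 1:
            assert perm[initial_centroid(phi_p)] == c


class TestEntropyWeights:
    def test_weights_sum_to_one(self, rng):
        psi = rng.uniform(0.1, 1.0, size=(10, 4))
        w = entropy_weights(psi)
        assert w.sum() == pytest.approx(1.0, abs=1e-10)

    def test_constant_column_gets_zero_weight(self):
        psi = np.column_stack([np.full(5, 0.7), np.linspace(0.1, 0.9, 5)])
        w = entropy_weights(psi)
        assert w[0] == pytest.approx(0.0, abs=1e-10)
        assert w[1] == pytest.approx(1.0, abs=1e-10)

    def test_two_by_two_hand_case(self):
        psi = np.array([[0.9, 0.5], [0.1, 0.5]])
        w = entropy_weights(psi)
        assert w[0] > w[1]

    def test_uniform_fallback(self):
        psi = np.ones((4, 3))
        np.testing.assert_allclose(entropy_weights(psi), 1 / 3)


class TestWeightedCentroid:
    def test_composition_and_identity(self, rng):
        rows = rng.uniform(size=(10, 4))
        wc = weighted_centroid(rows, CFG)
        np.testing.assert_allclose(wc.z_weighted, wc.weights * wc.z_star, atol=1e-14)
        psi = coefficient_matrix(rows, wc.center_row_index, CFG)
        np.testing.assert_allclose(wc.weights, entropy_weights(psi), atol=1e-14)

    def test_uniform_weights_divide_by_d(self):
        rows = np.tile(np.array([2.0, 4.0, 6.0]), (5, 1))  # identical rows
        wc = weighted_centroid(rows, CFG)
        np.testing.assert_allclose(wc.z_weighted, wc.z_star / 3.0)

    def test_centroid_row_has_unit_coefficients(self, rng):
        rows = rng.uniform(size=(6, 4))
        wc = weighted_centroid(rows, CFG)
        psi = coefficient_matrix(rows, wc.center_row_index, CFG)
        assert (psi > 0).all() and (psi <= 1 + 1e-12).all()
        np.testing.assert_allclose(psi[wc.center_row_index], 1.0)

    def test_deterministic(self, rng):
        rows = rng.uniform(size=(9, 3))
        a, b = weighted_centroid(rows, CFG), weighted_centroid(rows, CFG)
        np.testing.assert_array_equal(a.z_weighted, b.z_weighted)


class TestGateDegrees:
    def test_sample_equal_to_z_star_scores_one(self, rng):
        rows = rng.uniform(size=(8, 4))
        wc = weighted_centroid(rows, CFG)
        other = weighted_centroid(rng.uniform(2.0, 3.0, size=(8, 4)), CFG)
        W = np.vstack([wc.weights, other.weights])
        Z = np.vstack([wc.z_weighted, other.z_weighted])
        om = gate_degrees(wc.z_star[None, :], W, Z, CFG)
        assert om[0, 0] == pytest.approx(1.0)
        assert om[0, 0] >= om[0, 1]


class TestVariableSelection:
    def _ds(self, aux, names, y):
        n = len(y)
        return BatchDataset(batch_id=np.ones(n, int), time_index=np.arange(n),
                            aux=aux, targets=np.asarray(y)[:, None],
                            aux_names=names, target_names=("y",))

    def test_identical_column_always_selected(self, rng):
        y = rng.uniform(size=30)
        aux = np.column_stack([y, rng.uniform(size=30)])
        ds = self._ds(aux, ("same", "noise"), y)
        selected, degrees = select_aux_variables(ds, "y", 0.7, CFG)
        assert "same" in selected
        assert degrees["same"] == pytest.approx(1.0)

    def test_impossible_threshold_falls_back_to_best(self, rng):
        y = rng.uniform(size=30)
        aux = rng.uniform(size=(30, 3))
        ds = self._ds(aux, ("a", "b", "c"), y)
        selected, degrees = select_aux_variables(ds, "y", 1.0, CFG)
        assert len(selected) == 1
        assert degrees[selected[0]] == max(degrees.values())

    def test_default_threshold_in_contract(self, rng):
        y = rng.uniform(size=20)
        ds = self._ds(y[:, None].copy(), ("a",), y)
        with pytest.raises(ValueError):
            select_aux_variables(ds, "y", 0.0, CFG)
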