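"""Core coupling statistics: CGE, CEC, C_sa and their normalizations."""

import numpy as np
import pytest
from scipy import stats

from genefc.coupling import (
    build_coupling_tensor,
    compute_cge,
    compute_cge_vector,
    compute_csa,
    compute_global_cec,
    normalize_connectivity,
    normalize_expression,
)


def _zscore(x):
    return (x - x.mean()) / x.std(ddof=0)


class TestNormalizeExpression:
    def test_column_zscores_population_sd(self):
        raw = np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 9.0]])
        expr = normalize_expression(raw, mode="literal")
        np.testing.assert_allclose(
            expr.values[:, 0], [-1.22474487, 0.0, 1.22474487], atol=1e-8
        )
        assert np.allclose(expr.values.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(expr.values.std(axis=0, ddof=0), 1, atol=1e-12)

    def test_pearson_mode_unit_row_second_moment(self, rng):
        raw = rng.standard_normal((10, 40))
        expr = normalize_expression(raw)
        np.testing.assert_allclose((expr.values**2).mean(axis=1), 1.0, atol=1e-12)

    def test_literal_mode_idempotent(self, rng):
        raw = rng.standard_normal((12, 30))
        once = normalize_expression(raw, mode="literal")
        twice = normalize_expression(once.values, mode="literal")
        np.testing.assert_allclose(once.values, twice.values, atol=1e-10)

    def test_pearson_mode_preserves_row_standardization(self, rng):
        # the row step perturbs exact column z-scores (the two constraints
        # cannot hold simultaneously); re-normalizing keeps rows standardized
        raw = rng.standard_normal((12, 200))
        once = normalize_expression(raw)
        twice = normalize_expression(once.values)
        np.testing.assert_allclose((twice.values**2).mean(axis=1), 1.0, atol=1e-12)
        rms = np.sqrt(((twice.values - once.values) ** 2).mean())
        assert rms < 5 / np.sqrt(200)  # drift shrinks with the gene count

    def test_constant_column_error_names_gene(self):
        raw = np.array([[1.0, 2.0], [1.0, 3.0], [1.0, 4.0]])
        with pytest.raises(ValueError, match="flatgene"):
            normalize_expression(raw, gene_ids=["flatgene", "ok"])


class TestCGE:
    def test_identical_profiles(self, rng):
        raw = rng.standard_normal((6, 25))
        raw[1] = raw[0]
        expr = normalize_expression(raw)
        assert compute_cge(expr, 0, 1) == pytest.approx(1.0, abs=1e-10)

    def test_negated_profile(self, rng):
        raw = rng.standard_normal((6, 25))
        raw[2] = -raw[0]
        # negation survives column z-scoring only if columns stay zero-mean;
        # construct an antisymmetric pair directly in normalized space
        expr = normalize_expression(raw)
        vals = expr.values.copy()
        vals[2] = -vals[0]
        expr.values = vals
        assert compute_cge(expr, 0, 2) == pytest.approx(-1.0, abs=1e-10)

    def test_equals_pearson_oracle(self, rng):
        raw = rng.standard_normal((8, 50))
        expr = normalize_expression(raw)
        zs = _zscore_cols(raw)  # CGE is the Pearson r of column-z-scored profiles
        for i, j in [(0, 1), (2, 5), (3, 7)]:
            oracle = stats.pearsonr(zs[i], zs[j]).statistic
            assert compute_cge(expr, i, j) == pytest.approx(oracle, abs=1e-10)

    def test_self_connection_error(self, small_dataset):
        with pytest.raises(ValueError, match="self-connection"):
            compute_cge(small_dataset.expression, 3, 3)

    def test_symmetry_and_bounds(self, rng):
        raw = rng.standard_normal((9, 30))
        expr = normalize_expression(raw)
        vec = compute_cge_vector(expr)
        assert np.all(np.abs(vec.raw) <= 1 + 1e-12)
        for i, j in [(0, 5), (2, 7)]:
            assert compute_cge(expr, i, j) == pytest.approx(
                compute_cge(expr, j, i), abs=1e-14
            )


def _zscore_cols(x):
    return (x - x.mean(0)) / x.std(0, ddof=0)


class TestNormalizeConnectivity:
    def test_rows_mean_zero_unit_variance(self, rng):
        raw = rng.uniform(-0.8, 0.8, size=(5, 15))
        conn = normalize_connectivity(raw, n_regions=_regions_for(15))
        np.testing.assert_allclose(conn.values.mean(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(conn.values.std(axis=1, ddof=0), 1, atol=1e-12)

    def test_identical_rows_stay_identical(self, rng):
        row = rng.uniform(-0.5, 0.5, size=15)
        conn = normalize_connectivity(
            np.vstack([row, row]), n_regions=_regions_for(15)
        )
        np.testing.assert_array_equal(conn.values[0], conn.values[1])

    def test_fisher_then_zscore_hand_computed(self):
        row = np.array([0.1, 0.2, 0.3, 0.4, 0.0, -0.1])
        z = np.arctanh(row)
        expected = (z - z.mean()) / z.std(ddof=0)
        conn = normalize_connectivity(row[None, :], n_regions=4)
        np.testing.assert_allclose(conn.values[0], expected, atol=1e-10)

    def test_fisher_divergence_error(self):
        raw = np.array([[0.1, 1.0, 0.3, 0.2, 0.1, 0.0]])
        with pytest.raises(ValueError, match="Fisher"):
            normalize_connectivity(raw, n_regions=4)

    def test_fisher_flag_disabled(self):
        raw = np.array([[3.0, -2.0, 5.0, 0.0, 1.0, 2.0]])
        conn = normalize_connectivity(raw, n_regions=4, fisher=False)
        np.testing.assert_allclose(conn.values[0], _zscore(raw[0]), atol=1e-12)


def _regions_for(s):
    r = int((1 + np.sqrt(1 + 8 * s)) / 2)
    assert r * (r - 1) // 2 == s
    return r


class TestGlobalCEC:
    def test_identical_vectors(self, rng):
        fc = _zscore(rng.standard_normal(50))
        assert compute_global_cec(fc, fc) == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_vectors(self):
        n = 64
        fc = _zscore(np.resize([1.0, 1.0, -1.0, -1.0], n))
        cge = _zscore(np.resize([1.0, -1.0], n))
        assert compute_global_cec(fc, cge) == pytest.approx(0.0, abs=1e-12)

    def test_equals_pearson_oracle(self, rng):
        x = _zscore(rng.standard_normal(200))
        y = _zscore(rng.standard_normal(200))
        oracle = stats.pearsonr(x, y).statistic
        assert compute_global_cec(x, y) == pytest.approx(oracle, abs=1e-10)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            compute_global_cec(np.zeros(5), np.zeros(6))


class TestCouplingTensor:
    def test_csa_arithmetic(self):
        assert compute_csa(2.0, 1.0, 0.5, 1.0) == 1.0
        assert compute_csa(3.0, -2.0, 0.0, 5.0) == 0.0

    def test_tensor_matches_hand_computed_products(self, rng):
        raw_e = rng.standard_normal((3, 2))
        expr = normalize_expression(raw_e)
        raw_c = rng.standard_normal((1, 3))
        conn = normalize_connectivity(raw_c, n_regions=3, fisher=False)
        tensor = build_coupling_tensor(expr, conn)
        cge = compute_cge_vector(expr)
        pairs = [(0, 1), (0, 2), (1, 2)]
        for a in range(2):
            for s, (i, j) in enumerate(pairs):
                expected = compute_csa(
                    conn.values[0, s],
                    cge.zscored[s],
                    expr.values[i, a],
                    expr.values[j, a],
                )
                assert tensor.values[a, s, 0] == pytest.approx(expected, abs=1e-12)

    def test_gene_average_identity(self, small_dataset):
        """Mean over genes of C_sa equals (FC_s * CGE_s^norm) * CGE_s^raw."""
        expr, conn = small_dataset.expression, small_dataset.connectivity
        tensor = build_coupling_tensor(expr, conn)
        cge = compute_cge_vector(expr)
        for h in (0, 3):
            lhs = tensor.values[:, :, h].mean(axis=0)
            rhs = conn.values[h] * cge.zscored * cge.raw
            np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_population_average_of_identical_subjects(self, rng):
        raw_e = rng.standard_normal((4, 3))
        expr = normalize_expression(raw_e)
        row = rng.standard_normal(6)
        conn = normalize_connectivity(np.vstack([row, row]), 4, fisher=False)
        tensor = build_coupling_tensor(expr, conn)
        np.testing.assert_allclose(
            tensor.population_average, tensor.values[:, :, 0], atol=1e-12
        )

    def test_averaging_order_independent(self, small_dataset):
        tensor = build_coupling_tensor(
            small_dataset.expression, small_dataset.connectivity
        )
        by_subject_first = tensor.values.mean(axis=2).mean(axis=1)
        by_connection_first = tensor.values.mean(axis=1).mean(axis=1)
        np.testing.assert_allclose(by_subject_first, by_connection_first, atol=1e-12)
        np.testing.assert_allclose(tensor.gene_means, by_subject_first, atol=1e-12)

    def test_region_mismatch_error(self, rng):
        expr = normalize_expression(rng.standard_normal((4, 3)))
        conn = normalize_connectivity(rng.standard_normal((2, 10)), 5, fisher=False)
        with pytest.raises(ValueError, match="region mismatch"):
            build_coupling_tensor(expr, conn)
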