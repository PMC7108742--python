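import numpy as np
import pandas as pd
import pytest

from markerpipe.io_meta import ExpressionMatrix, SampleMetadata, ValidationError
from markerpipe.preprocess import (cpm, filter_low_counts, impute_missing,
                                   normalize_continuous, quantile_normalize,
                                   tmm_factors, voom_transform)


def _matrix(values, datatype="array"):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix([f"v{i}" for i in range(values.shape[0])],
                            [f"s{j}" for j in range(values.shape[1])],
                            values, datatype)


class TestImputation:
    def test_lls_exact_linear_dependence(self, rng):
        # v3 = 2*v1 - v2 exactly, so the LS fit recovers the missing cell
        v1 = rng.normal(size=8)
        v2 = rng.normal(size=8)
        v3 = 2 * v1 - v2
        V = np.vstack([v1, v2, v3])
        expected = V[2, 0]
        V[2, 0] = np.nan
        out, n_imp = impute_missing(_matrix(V), method="lls", k=2)
        assert n_imp == 1
        assert abs(out.values[2, 0] - expected) <= 1e-8

    def test_lls_exact_recovery_many_targets(self, rng):
        # every incomplete variable is an exact combination of 3 complete ones
        base = rng.normal(size=(3, 12))
        coefs = rng.normal(size=(6, 3))
        targets = coefs @ base
        V = np.vstack([base, targets])
        truth = V.copy()
        for i in range(3, 9):
            V[i, rng.integers(12)] = np.nan
        out, _ = impute_missing(_matrix(V), method="lls", k=3)
        assert np.nanmax(np.abs(out.values - truth)) <= 1e-6

    def test_knn_identical_neighbor(self):
        V = np.array([[1.0, 2.0, 3.0], [1.0, 2.0, np.nan], [9.0, 9.0, 9.0],
                      [4.0, 5.0, 6.0]])
        out, _ = impute_missing(_matrix(V), method="knn", k=1)
        assert out.values[1, 2] == 3.0

    @pytest.mark.parametrize("method", ["lls", "knn"])
    def test_observed_cells_never_altered(self, rng, method):
        V = rng.normal(size=(10, 8))
        mask = rng.random(V.shape) < 0.1
        mask[:, 0] = False     # keep every variable partly observed
        Vm = np.where(mask, np.nan, V)
        out, _ = impute_missing(_matrix(Vm), method=method, k=3)
        assert np.array_equal(out.values[~mask], V[~mask])

    def test_fully_missing_variable_errors(self):
        V = np.array([[1.0, 2.0], [np.nan, np.nan]])
        with pytest.raises(ValidationError, match="v1"):
            impute_missing(_matrix(V), method="lls", k=1)

    def test_too_few_neighbors_falls_back_to_mean(self, rng):
        V = rng.normal(size=(2, 6))
        V[1, 0] = np.nan
        with pytest.warns(UserWarning, match="variable-mean"):
            out, _ = impute_missing(_matrix(V), method="lls", k=5)
        assert out.values[1, 0] == pytest.approx(np.nanmean(V[1]))


class TestLowCountFilter:
    def _meta(self, groups):
        return SampleMetadata(
            pd.DataFrame({"group": groups},
                         index=pd.Index([f"s{j}" for j in range(len(groups))],
                                        name="sample_id")),
            "group")

    def test_cpm_rule_at_group_boundary(self):
        # groups of sizes 3 and 5 -> m = 3; library size 1e6 so count == CPM
        groups = ["a"] * 3 + ["b"] * 5
        n = 8
        V = np.full((3, n), 0.0)
        V[0] = 1e6 / 3          # filler keeping library sizes at ~1e6
        V[1, :3] = 2.0          # CPM ~2 in exactly 3 samples -> retained
        V[2, :2] = 2.0          # CPM ~2 in only 2 samples -> removed
        X = _matrix(np.round(V), "seq")
        kept, removed = filter_low_counts(X, self._meta(groups))
        assert "v1" in kept.variable_ids
        assert "v2" in removed

    def test_all_zero_removed_and_high_retained(self):
        V = np.zeros((2, 4))
        V[1] = 500.0
        X = _matrix(V, "seq")
        kept, removed = filter_low_counts(X, self._meta(["a", "a", "b", "b"]))
        assert removed == ["v0"]
        assert kept.variable_ids == ["v1"]

    def test_empty_result_errors(self):
        V = np.ones((1, 4)) * 0.0
        with pytest.raises(ValidationError, match="threshold"):
            filter_low_counts(_matrix(V, "seq"), self._meta(["a", "a", "b", "b"]))


class TestTMM:
    def test_identical_columns_unit_factors(self, rng):
        col = rng.poisson(40, 100).astype(float) + 1
        X = _matrix(np.column_stack([col, col]), "seq")
        assert np.allclose(tmm_factors(X), [1.0, 1.0])

    def test_pure_depth_scaling_unit_factors(self, rng):
        col = rng.poisson(40, 200).astype(float) + 1
        X = _matrix(np.column_stack([col, 3 * col]), "seq")
        assert np.allclose(tmm_factors(X), [1.0, 1.0], atol=1e-10)

    def test_geometric_mean_anchoring(self, rng):
        counts = rng.poisson(30, size=(300, 5)).astype(float)
        counts[:50, 2] *= 4    # genuine composition change
        f = tmm_factors(_matrix(counts, "seq"))
        assert np.prod(f) == pytest.approx(1.0, abs=1e-8)

    def test_column_scaling_invariance(self, rng):
        counts = rng.poisson(30, size=(300, 4)).astype(float) + 1
        f1 = tmm_factors(_matrix(counts, "seq"))
        counts2 = counts.copy()
        counts2[:, 1] *= 7.0
        f2 = tmm_factors(_matrix(counts2, "seq"))
        assert np.allclose(f1, f2, atol=1e-10)

    def test_disjoint_support_errors(self):
        V = np.array([[5.0, 0.0], [0.0, 5.0]])
        with pytest.raises(ValidationError, match="no positive variables"):
            tmm_factors(_matrix(V, "seq"))


class TestVoom:
    def test_closed_form_logcpm_zero(self, rng):
        counts = rng.poisson(100, size=(40, 4)).astype(float)
        counts[0, 0] = 0
        X = _matrix(counts, "seq")
        lib = counts.sum(axis=0)
        factors = np.ones(4)
        factors[0] = 499999.0 / lib[0]   # effective library size 499,999
        res = voom_transform(X, factors, np.ones((4, 1)))
        assert res.logcpm[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_flat_trend_gives_equal_weights(self):
        # equal library sizes + constant counts per variable: zero residual sd
        counts = np.tile(np.arange(1, 31, dtype=float)[:, None] * 10, (1, 4))
        X = _matrix(counts, "seq")
        res = voom_transform(X, np.ones(4), np.ones((4, 1)))
        assert np.all(res.weights > 0) and np.all(np.isfinite(res.weights))
        assert np.allclose(res.weights, res.weights[0, 0])

    def test_weights_follow_inverse_fourth_power_of_trend(self, rng):
        counts = rng.poisson(rng.uniform(5, 500, size=(60, 1)),
                             size=(60, 6)).astype(float)
        X = _matrix(counts, "seq")
        design = np.ones((6, 1))
        res = voom_transform(X, np.ones(6), design)
        fitted = (res.logcpm @ np.linalg.pinv(design).T) @ design.T
        expected = np.interp(fitted, res.trend_x, res.trend_y) ** -4
        assert np.allclose(res.weights, expected)
        assert np.all(res.weights > 0)

    def test_rank_deficient_design_errors(self, rng):
        counts = rng.poisson(50, size=(10, 3)).astype(float)
        with pytest.raises(ValidationError):
            voom_transform(_matrix(counts, "seq"), np.ones(3),
                           np.ones((3, 3)))


class TestNormalizeContinuous:
    def test_logit_half_is_zero(self):
        X = _matrix([[0.5, 0.5]], "ms")
        out = normalize_continuous(X, transform="logit", center="none")
        assert np.allclose(out.values, 0.0)

    def test_logit_out_of_range_names_cell(self):
        X = _matrix([[0.5, 1.5]], "ms")
        with pytest.raises(ValidationError, match="'v0'.*'s1'"):
            normalize_continuous(X, transform="logit", center="none")

    def test_log_nonpositive_requires_offset(self):
        X = _matrix([[0.0, 2.0]], "ms")
        with pytest.raises(ValidationError, match="offset"):
            normalize_continuous(X, transform="log2", center="none")
        out = normalize_continuous(X, transform="log2", center="none", offset=True)
        assert out.values[0, 0] == 0.0

    def test_quantile_hand_example(self):
        X = _matrix([[2.0, 4.0], [6.0, 8.0]], "array")
        out = normalize_continuous(X, transform="none", center="quantile")
        assert np.allclose(out.values, [[3.0, 3.0], [7.0, 7.0]])

    def test_median_centering(self):
        X = _matrix(np.array([[1.0], [2.0], [9.0]]), "array")
        out = normalize_continuous(X, transform="none", center="median")
        assert np.allclose(out.values[:, 0], [-1.0, 0.0, 7.0])

    def test_quantile_columns_share_sorted_values(self, rng):
        V = rng.normal(size=(50, 6))
        Q = quantile_normalize(V)
        ref = np.sort(Q[:, 0])
        for j in range(1, 6):
            assert np.allclose(np.sort(Q[:, j]), ref)

    def test_quantile_tie_rule(self):
        # tied block in column 0 takes the mean of the spanned reference values
        V = np.array([[1.0, 10.0], [1.0, 20.0], [5.0, 30.0]])
        Q = quantile_normalize(V)
        ref = np.sort(V, axis=0).mean(axis=1)       # (5.5, 10.5, 17.5)
        assert Q[0, 0] == Q[1, 0] == pytest.approx(ref[:2].mean())
        assert Q[2, 0] == pytest.approx(ref[2])
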