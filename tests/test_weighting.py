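"""AHP mapping, entropy weights, fusion, and cohort aggregation."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lagerscale import (
    PairwiseMatrix,
    ValidationError,
    WeightVector,
    aggregate_cohorts,
    ahp_weights_from_values,
    cohort_coefficients,
    consistency_ratio,
    entropy_weights,
    fuse_weights,
    minmax_to_saaty,
)


def _vec(values, **kw):
    return WeightVector(weights=pd.Series(values, dtype=float), **kw)


class TestSaatyMapping:
    def test_endpoints(self):
        m = minmax_to_saaty(pd.Series({"a": 1.0, "b": 5.0}))
        assert m.values.tolist() == [1.0, 9.0]

    def test_linear_interior(self):
        m = minmax_to_saaty(pd.Series({"a": 2.0, "b": 3.0, "c": 4.0}))
        assert m.values.tolist() == [1.0, 5.0, 9.0]

    def test_degenerate_equal_means_map_to_five(self):
        with pytest.warns(UserWarning, match="mid-scale"):
            m = minmax_to_saaty(pd.Series({"a": 3.7, "b": 3.7, "c": 3.7}))
        assert m.values.tolist() == [5.0, 5.0, 5.0]

    def test_order_preserved(self):
        means = pd.Series({"a": 3.9, "b": 3.6, "c": 3.8})
        m = minmax_to_saaty(means)
        assert m.values.rank().tolist() == means.rank().tolist()

    def test_single_attribute_rejected(self):
        with pytest.raises(ValidationError):
            minmax_to_saaty(pd.Series({"a": 3.0}))


class TestAhpWeights:
    def test_proportional_to_values(self):
        m = minmax_to_saaty(pd.Series({"a": 5.0, "b": 1.0, "c": 1.0, "d": 1.0}))
        w, matrix = ahp_weights_from_values(m)
        assert w.weights.tolist() == pytest.approx([0.75, 1 / 12, 1 / 12, 1 / 12])
        assert consistency_ratio(matrix) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_under_symmetry(self):
        with pytest.warns(UserWarning):
            m = minmax_to_saaty(pd.Series({k: 3.0 for k in "abcd"}))
        w, _ = ahp_weights_from_values(m)
        assert w.weights.tolist() == pytest.approx([0.25] * 4)

    def test_monotone_in_means(self):
        means = pd.Series({"a": 3.9, "b": 3.6, "c": 3.75, "d": 3.8})
        w, _ = ahp_weights_from_values(minmax_to_saaty(means))
        order_means = means.sort_values(ascending=False).index.tolist()
        order_w = w.weights.sort_values(ascending=False).index.tolist()
        assert order_means == order_w

    def test_matrix_entries_clipped_to_saaty_band(self):
        m = minmax_to_saaty(pd.Series({"a": 1.0, "b": 5.0}))
        _, matrix = ahp_weights_from_values(m)
        assert matrix.matrix.max() <= 9.0
        assert matrix.matrix.min() >= 1 / 9.0


class TestConsistencyRatio:
    def test_perturbation_breaks_consistency(self):
        v = np.array([2.0, 3.0, 5.0])
        a = np.outer(v, 1 / v)
        a[0, 1] *= 2.0
        a[1, 0] = 1 / a[0, 1]
        cr = consistency_ratio(PairwiseMatrix(matrix=a, labels=("a", "b", "c")))
        assert cr > 0

    def test_lambda_max_matches_power_iteration(self):
        rng = np.random.default_rng(4)
        upper = rng.uniform(1 / 9, 9, size=6)
        a = np.eye(4)
        idx = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        for (i, j), v in zip(idx, upper):
            a[i, j] = v
            a[j, i] = 1 / v
        # independent principal-eigenvalue oracle: power iteration
        x = np.ones(4)
        for _ in range(2000):
            y = a @ x
            x = y / np.linalg.norm(y)
        lam_oracle = float(x @ a @ x)
        cr = consistency_ratio(PairwiseMatrix(matrix=a, labels=tuple("abcd")))
        ci_oracle = (lam_oracle - 4) / 3
        assert cr == pytest.approx(ci_oracle / 0.90, abs=1e-8)

    def test_non_reciprocal_rejected(self):
        a = np.array([[1.0, 2.0], [0.4, 1.0]])
        with pytest.raises(ValidationError):
            PairwiseMatrix(matrix=a, labels=("a", "b"))

    def test_order_two_consistent(self):
        m = PairwiseMatrix(matrix=np.array([[1.0, 3.0], [1 / 3, 1.0]]),
                           labels=("a", "b"))
        assert consistency_ratio(m) == 0.0


class TestEntropyWeights:
    def test_constant_column_gets_zero_weight(self):
        x = pd.DataFrame({"varying": [1, 2, 4], "flat": [2, 2, 2]})
        w = entropy_weights(x)
        assert w["flat"] == 0.0
        assert w["varying"] == pytest.approx(1.0)

    def test_hand_computed_oracle(self):
        # [[1,2],[1,2],[4,2]]: col 1 p=(1/6,1/6,2/3) -> e=0.78975, d=0.21025;
        # col 2 constant -> e=1, d=0; weights (1, 0)
        x = pd.DataFrame({"a": [1, 1, 4], "b": [2, 2, 2]})
        w = entropy_weights(x)
        assert w.weights.tolist() == pytest.approx([1.0, 0.0], abs=1e-12)

    def test_all_constant_falls_back_to_uniform(self):
        x = pd.DataFrame({"a": [3, 3, 3], "b": [2, 2, 2]})
        with pytest.warns(UserWarning, match="uniform"):
            w = entropy_weights(x)
        assert w.weights.tolist() == pytest.approx([0.5, 0.5])

    def test_negative_rating_rejected(self):
        with pytest.raises(ValidationError):
            entropy_weights(pd.DataFrame({"a": [-1, 2], "b": [1, 2]}))

    @settings(max_examples=60, derandomize=True)
    @given(
        st.lists(
            st.lists(st.integers(min_value=1, max_value=5), min_size=4, max_size=4),
            min_size=5,
            max_size=5,
        )
    )
    def test_matches_direct_formula_oracle(self, rows):
        x = pd.DataFrame(rows, columns=list("abcd"), dtype=float)
        arr = x.to_numpy()
        p = arr / arr.sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(p > 0, p * np.log(p), 0.0)
        e = -plogp.sum(axis=0) / np.log(5)
        d = 1 - e
        d = np.where(np.abs(d) < 1e-12, 0.0, d)
        if d.sum() == 0:
            with pytest.warns(UserWarning):
                w = entropy_weights(x)
            expected = np.full(4, 0.25)
        else:
            w = entropy_weights(x)
            expected = d / d.sum()
        assert np.allclose(w.weights.to_numpy(), expected, atol=1e-10)

    def test_invariant_to_column_rescaling(self):
        x = pd.DataFrame({"a": [1.0, 2, 4], "b": [2.0, 3, 5]})
        w1 = entropy_weights(x)
        x2 = x.copy()
        x2["a"] = x2["a"] * 10.0
        w2 = entropy_weights(x2)
        assert np.allclose(w1.weights, w2.weights, atol=1e-12)


class TestFusion:
    def test_low_cohort_drinking_sensation(self):
        """0.7 x 65.32 + 0.3 x 25.19 = 53.28 (published low-frequency value)."""
        subj = _vec({"drinking_sensation": 0.6532, "rest": 0.3468})
        obj = _vec({"drinking_sensation": 0.2519, "rest": 0.7481})
        fused = fuse_weights(subj, obj, alpha=0.7)
        assert fused["drinking_sensation"] == pytest.approx(0.5328, abs=5e-5)

    def test_high_cohort_aroma(self):
        """0.7 x 49.49 + 0.3 x 24.76 = 42.07 (published high-frequency value)."""
        subj = _vec({"aroma": 0.4949, "rest": 0.5051})
        obj = _vec({"aroma": 0.2476, "rest": 0.7524})
        fused = fuse_weights(subj, obj)
        assert fused["aroma"] == pytest.approx(0.4207, abs=5e-5)

    def test_fixed_point(self):
        w = _vec({"a": 0.3, "b": 0.7})
        fused = fuse_weights(w, w)
        assert np.allclose(fused.weights, w.weights)

    def test_mismatched_attributes_rejected(self):
        with pytest.raises(ValidationError):
            fuse_weights(_vec({"a": 0.5, "b": 0.5}), _vec({"a": 0.5, "c": 0.5}))

    def test_output_is_convex_combination(self):
        a = _vec({"x": 0.9, "y": 0.1})
        b = _vec({"x": 0.2, "y": 0.8})
        fused = fuse_weights(a, b, alpha=0.4)
        for attr in ("x", "y"):
            lo = min(a[attr], b[attr])
            hi = max(a[attr], b[attr])
            assert lo <= fused[attr] <= hi


class TestCohortCoefficients:
    def test_unit_sizes(self):
        c = cohort_coefficients({"low": 2, "mid": 6, "high": 14},
                                {"low": 1, "mid": 1, "high": 1})
        assert c.coefficients.tolist() == pytest.approx([1 / 11, 3 / 11, 7 / 11])

    def test_share_derived_sizes_match_published(self):
        c = cohort_coefficients({"low": 2, "mid": 6, "high": 14},
                                {"low": 708, "mid": 781, "high": 348})
        published = {"low": 0.1285, "mid": 0.4269, "high": 0.4446}
        for k, v in published.items():
            assert c.coefficients[k] == pytest.approx(v, abs=1e-3)

    def test_normalization_exact(self):
        c = cohort_coefficients({"a": 3.3, "b": 1.7}, {"a": 17, "b": 29})
        assert c.coefficients.sum() == pytest.approx(1.0, abs=1e-12)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValidationError):
            cohort_coefficients({"a": 2, "b": 6}, {"a": 0, "b": 10})


def _coeffs():
    return cohort_coefficients(
        {"low": 2, "mid": 6, "high": 14}, {"low": 708, "mid": 781, "high": 348}
    )


class TestAggregation:
    def _published_coeffs(self):
        from lagerscale.published import published_coefficients

        return published_coefficients()

    def test_drinking_sensation_comprehensive(self):
        """Published cohort AHP shares 65.32/38.59/13.61 with the printed
        coefficients reproduce the comprehensive 30.92."""
        vecs = {
            "low": _vec({"d": 0.6532, "r": 0.3468}, cohort="low"),
            "mid": _vec({"d": 0.3859, "r": 0.6141}, cohort="mid"),
            "high": _vec({"d": 0.1361, "r": 0.8639}, cohort="high"),
        }
        agg = aggregate_cohorts(vecs, self._published_coeffs())
        assert agg["d"] == pytest.approx(0.3092, abs=5e-5)

    def test_aroma_comprehensive(self):
        vecs = {
            "low": _vec({"a": 0.0726, "r": 0.9274}, cohort="low"),
            "mid": _vec({"a": 0.0429, "r": 0.9571}, cohort="mid"),
            "high": _vec({"a": 0.4949, "r": 0.5051}, cohort="high"),
        }
        agg = aggregate_cohorts(vecs, self._published_coeffs())
        assert agg["a"] == pytest.approx(0.2477, abs=5e-5)

    def test_identical_vectors_fixed_point(self):
        w = {"x": 0.2, "y": 0.5, "z": 0.3}
        vecs = {c: _vec(w, cohort=c) for c in ("low", "mid", "high")}
        agg = aggregate_cohorts(vecs, _coeffs())
        assert np.allclose(agg.weights, list(w.values()))

    def test_layer_mixing_rejected(self):
        vecs = {
            "low": _vec({"x": 1.0}, layer="ahp", cohort="low"),
            "mid": _vec({"x": 1.0}, layer="ewm", cohort="mid"),
            "high": _vec({"x": 1.0}, layer="ahp", cohort="high"),
        }
        with pytest.raises(ValidationError, match="layers"):
            aggregate_cohorts(vecs, _coeffs())

    def test_result_bounded_by_inputs(self):
        vecs = {
            "low": _vec({"x": 0.9, "y": 0.1}, cohort="low"),
            "mid": _vec({"x": 0.5, "y": 0.5}, cohort="mid"),
            "high": _vec({"x": 0.2, "y": 0.8}, cohort="high"),
        }
        agg = aggregate_cohorts(vecs, _coeffs())
        assert 0.2 <= agg["x"] <= 0.9
        assert 0.1 <= agg["y"] <= 0.8
        assert agg.weights.sum() == pytest.approx(1.0, abs=1e-9)
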