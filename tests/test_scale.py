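"""Scale construction: merging, exclusions, top-k, standardization,
integerization."""
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lagerscale import (
    AttributeHierarchy,
    ValidationError,
    WeightVector,
    apply_exclusions,
    build_scale,
    integerize,
    integrate_and_globalize,
    merge_attributes,
    top_k_local_normalize,
)
from lagerscale.published import (
    FINAL_SCALE_WEIGHTS,
    comprehensive_dimension_vector,
    comprehensive_sub_vectors,
)


def _vec(values, **kw):
    kw.setdefault("normalized", abs(sum(values.values()) - 1.0) < 1e-9)
    return WeightVector(weights=pd.Series(values, dtype=float), **kw)


class TestMerge:
    def test_hop_floral_sum(self):
        """Published aroma weights: hop 4.83% + floral 20.02% -> 24.85%."""
        w = _vec({"hop": 0.0483, "floral": 0.2002, "malt": 0.2588})
        merged = merge_attributes(w, {"hop_flower": ("hop", "floral")})
        assert merged["hop_flower"] == pytest.approx(0.2485)
        assert merged["malt"] == pytest.approx(0.2588)

    def test_fruit_fermentation_sum(self):
        w = _vec({"fruit": 0.1035, "fermentation": 0.2031})
        merged = merge_attributes(
            w, {"fruity_fermentation": ("fruit", "fermentation")}
        )
        assert merged["fruity_fermentation"] == pytest.approx(0.3066)

    def test_empty_map_is_identity(self):
        w = _vec({"a": 0.4, "b": 0.6})
        merged = merge_attributes(w, {})
        assert merged.weights.equals(w.weights)

    def test_missing_source_rejected(self):
        w = _vec({"a": 0.4, "b": 0.6})
        with pytest.raises(ValidationError, match="absent"):
            merge_attributes(w, {"m": ("a", "zz")})

    def test_weight_conserved(self):
        w = _vec({"a": 0.25, "b": 0.3, "c": 0.45})
        merged = merge_attributes(w, {"ab": ("a", "b")})
        assert merged.weights.sum() == pytest.approx(w.weights.sum())


class TestExclusions:
    def test_removal_without_renormalization(self):
        """Dropping alcohol warmth (15.45%) leaves the others untouched."""
        w = _vec({"alcohol_warmth": 0.1545, "smoothness": 0.1283,
                  "persistence": 0.1553})
        out = apply_exclusions(w, ["alcohol_warmth"])
        assert "alcohol_warmth" not in out.weights.index
        assert out["smoothness"] == pytest.approx(0.1283)
        assert out.weights.sum() == pytest.approx(0.2836)

    def test_empty_list_is_identity(self):
        w = _vec({"a": 0.4, "b": 0.6})
        assert apply_exclusions(w, []).weights.equals(w.weights)

    def test_unknown_name_warns_and_noops(self):
        w = _vec({"a": 0.4, "b": 0.6})
        with pytest.warns(UserWarning, match="ignored"):
            out = apply_exclusions(w, ["ghost"])
        assert out.weights.equals(w.weights)


class TestTopK:
    def test_published_taste_locals(self):
        """Taste top-3 of {astringency 27.59, sweetness 26.70, bitterness
        21.92, umami 13.47, sourness 10.33} renormalize to 36.20/35.03/28.76."""
        w = _vec(
            {"astringency": 0.2759, "sweetness": 0.2670, "bitterness": 0.2192,
             "umami": 0.1347, "sourness": 0.1033},
            level="taste",
        )
        local = top_k_local_normalize(w, k=3)
        assert local.attributes == ("astringency", "sweetness", "bitterness")
        assert local["astringency"] == pytest.approx(0.3620, abs=5e-5)
        assert local["sweetness"] == pytest.approx(0.3503, abs=5e-5)
        assert local["bitterness"] == pytest.approx(0.2876, abs=5e-5)

    def test_exactly_k_is_pure_renormalization(self):
        w = _vec({"a": 0.2, "b": 0.1, "c": 0.1}, normalized=False)
        local = top_k_local_normalize(w, k=3)
        assert local["a"] == pytest.approx(0.5)

    def test_tie_broken_by_ahp_then_lexicographic(self):
        w = _vec({"a": 0.3, "b": 0.2, "c": 0.2, "d": 0.3}, normalized=False)
        by_ahp = top_k_local_normalize(w, k=3, tiebreak={"b": 0.1, "c": 0.5})
        assert set(by_ahp.attributes) == {"a", "d", "c"}
        lexicographic = top_k_local_normalize(w, k=3)
        assert set(lexicographic.attributes) == {"a", "d", "b"}

    def test_too_few_attributes_names_dimension(self):
        w = _vec({"a": 0.6, "b": 0.4}, level="appearance")
        with pytest.raises(ValidationError, match="appearance"):
            top_k_local_normalize(w, k=3)


class TestIntegerize:
    def test_published_scale_fractions(self):
        fractions = pd.Series(
            [0.1884, 0.1170, 0.1134, 0.1132, 0.0989, 0.0957, 0.0930, 0.0919,
             0.0885],
            index=[f"a{i}" for i in range(9)],
        )
        out = integerize(fractions)
        assert out.tolist() == [19, 12, 11, 11, 10, 10, 9, 9, 9]
        assert out.sum() == 100

    def test_exact_halves(self):
        assert integerize(pd.Series({"a": 0.5, "b": 0.5})).tolist() == [50, 50]

    def test_three_way_tie_lexicographic(self):
        out = integerize(pd.Series({"a": 1 / 3, "b": 1 / 3, "c": 1 / 3}))
        assert out.tolist() == [34, 33, 33]

    @settings(max_examples=80, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0.01, max_value=1.0), min_size=2,
                 max_size=10)
    )
    def test_matches_brute_force_oracle(self, raw):
        total = sum(raw)
        fractions = pd.Series(
            [v / total for v in raw], index=[f"x{i:02d}" for i in range(len(raw))]
        )
        out = integerize(fractions)
        assert out.sum() == 100
        # brute-force largest-remainder oracle
        floors = {a: math.floor(100 * f) for a, f in fractions.items()}
        need = 100 - sum(floors.values())
        rem = {a: 100 * f - floors[a] for a, f in fractions.items()}
        winners = sorted(
            fractions.index, key=lambda a: (-rem[a], -fractions[a], a)
        )[:need]
        expected = {a: floors[a] + (a in winners) for a in fractions.index}
        assert out.to_dict() == expected


class TestIntegration:
    def test_single_dimension_single_attribute(self):
        locals_ = {"d": _vec({"a": 1.0}, level="d")}
        dims = _vec({"d": 0.4}, level="dimension", normalized=False)
        table = integrate_and_globalize(locals_, dims)
        assert table["weight"].tolist() == [1.0]

    def test_missing_dimension_weight_rejected(self):
        locals_ = {"d": _vec({"a": 1.0}, level="d")}
        dims = _vec({"other": 1.0}, level="dimension")
        with pytest.raises(ValidationError, match="'d'"):
            integrate_and_globalize(locals_, dims)


class TestBuildScale:
    def test_published_inputs_reproduce_nine_attributes(self, hierarchy):
        scale = build_scale(
            comprehensive_sub_vectors(),
            comprehensive_dimension_vector(),
            hierarchy,
        )
        assert set(scale.attributes) == set(FINAL_SCALE_WEIGHTS)

    def test_published_inputs_reproduce_weights(self, hierarchy):
        scale = build_scale(
            comprehensive_sub_vectors(),
            comprehensive_dimension_vector(),
            hierarchy,
        )
        got = scale.fractional_weights() * 100
        for attr, expected in FINAL_SCALE_WEIGHTS.items():
            assert got[attr] == pytest.approx(expected, abs=0.01), attr
        assert scale.table["integer_weight"].sum() == 100

    def test_uniform_inputs_give_uniform_scale(self):
        h = AttributeHierarchy(
            dimensions=("d1", "d2"),
            children={"d1": ("a", "b", "c"), "d2": ("x", "y", "z")},
        )
        sub = {
            "d1": _vec({"a": 1 / 3, "b": 1 / 3, "c": 1 / 3}, level="d1"),
            "d2": _vec({"x": 1 / 3, "y": 1 / 3, "z": 1 / 3}, level="d2"),
        }
        dims = _vec({"d1": 0.5, "d2": 0.5}, level="dimension")
        scale = build_scale(sub, dims, h, k=3)
        assert np.allclose(scale.fractional_weights(), 1 / 6)

    def test_monotone_in_sub_weight(self, hierarchy):
        sub = comprehensive_sub_vectors()
        dims = comprehensive_dimension_vector()
        base = build_scale(sub, dims, hierarchy).fractional_weights()

        boosted = {k: v for k, v in sub.items()}
        w = sub["taste"].weights.copy()
        w["astringency"] += 0.05
        boosted["taste"] = WeightVector(
            weights=w, layer="comprehensive", level="taste", normalized=False
        )
        out = build_scale(boosted, dims, hierarchy).fractional_weights()
        assert out["astringency"] >= base["astringency"]

    def test_scale_round_trips_through_dict(self, hierarchy):
        from lagerscale import ScaleDefinition

        scale = build_scale(
            comprehensive_sub_vectors(), comprehensive_dimension_vector(), hierarchy
        )
        clone = ScaleDefinition.from_dict(scale.to_dict())
        assert clone.attributes == scale.attributes
        assert np.allclose(
            clone.fractional_weights(), scale.fractional_weights()
        )
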