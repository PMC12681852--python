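import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from evrank import (
    ConfigurationError,
    DataError,
    Direction,
    FactorSpec,
    ValidationError,
    WeightVector,
    build_decision_problem,
    resolve_weights,
)

from conftest import make_matrix


def specs(names, direction=Direction.MAXIMIZE, weight=None):
    w = weight if weight is not None else 1.0 / len(names)
    return [FactorSpec(n, direction, weight=w) for n in names]


class TestFactorSpec:
    def test_rejects_empty_name(self):
        with pytest.raises(ConfigurationError):
            FactorSpec("")

    def test_rejects_weight_outside_unit_interval(self):
        with pytest.raises(ValidationError):
            FactorSpec("x", weight=1.5)

    def test_shifted_minimize_requires_positive_shift(self):
        with pytest.raises(ValidationError):
            FactorSpec("zeta", Direction.SHIFTED_MINIMIZE, shift=0.0)

    def test_direction_coerced_from_string(self):
        assert FactorSpec("x", "minimize").direction is Direction.MINIMIZE
        with pytest.raises(ConfigurationError):
            FactorSpec("x", "upwards")


class TestResolveWeights:
    def test_equal_default(self):
        assert resolve_weights(4).weights == (0.25, 0.25, 0.25, 0.25)

    def test_already_normalized_passes_through(self):
        assert resolve_weights(2, [0.3, 0.7]).weights == (0.3, 0.7)

    def test_auto_normalize_rescales_and_warns(self):
        with pytest.warns(UserWarning, match="rescaled"):
            wv = resolve_weights(2, [1.0, 3.0], auto_normalize=True)
        assert wv.weights == (0.25, 0.75)

    @pytest.mark.parametrize(
        "user", [[0.2, 0.2], [-0.1, 1.1], [0.0, 0.0]],
        ids=["sum!=1", "negative", "zero-sum"],
    )
    def test_invalid_without_auto_normalize(self, user):
        with pytest.raises(ValidationError):
            resolve_weights(2, user)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0.01, 10.0), min_size=1, max_size=13))
    def test_output_always_on_simplex(self, raw):
        wv = resolve_weights(len(raw), raw, auto_normalize=True)
        w = np.asarray(wv.weights)
        assert abs(w.sum() - 1.0) < 1e-12
        assert np.all(w >= 0)


class TestDecisionMatrixValidation:
    def test_well_formed_8x11_passes(self):
        rng = np.random.default_rng(0)
        m = make_matrix(rng.uniform(1, 100, size=(8, 11)))
        assert m.shape == (8, 11)
        assert len(m.factors) == 11

    def test_minimize_column_with_zero_rejected(self):
        with pytest.raises(ValidationError, match="strictly positive"):
            make_matrix([[1.0], [0.0]], directions=[Direction.MINIMIZE])

    def test_shifted_value_below_shift_rejected(self):
        with pytest.raises(ValidationError, match="shift"):
            make_matrix([[-150.0], [-10.0]],
                        directions=[Direction.SHIFTED_MINIMIZE])

    def test_single_alternative_rejected(self):
        with pytest.raises(ValidationError):
            make_matrix([[1.0, 2.0]])

    def test_duplicate_alternatives_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            make_matrix([[1.0], [2.0]], alternatives=["A", "A"])

    def test_weight_sum_enforced(self):
        with pytest.raises(ValidationError, match="sum"):
            make_matrix([[1.0, 2.0], [3.0, 4.0]], weights=[0.5, 0.6])


class TestBuildDecisionProblem:
    def test_columns_reordered_to_config(self):
        df = pd.DataFrame({"b": [1.0, 2.0], "a": [3.0, 4.0]}, index=["x", "y"])
        m = build_decision_problem(df, specs(["a", "b"]))
        assert m.factor_names == ["a", "b"]
        assert m.values.loc["x", "a"] == 3.0

    def test_missing_and_extra_columns_named(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "c": [3.0, 4.0]}, index=["x", "y"])
        with pytest.raises(ConfigurationError) as err:
            build_decision_problem(df, specs(["a", "b"]))
        assert "b" in str(err.value) and "c" in str(err.value)

    def test_non_numeric_cell_cites_coordinates(self):
        df = pd.DataFrame({"a": [1.0, "oops"]}, index=["x", "y"])
        df["b"] = [1.0, 2.0]
        with pytest.raises(DataError, match="'y'.*'a'"):
            build_decision_problem(df, specs(["a", "b"]))

    def test_nan_cell_rejected(self):
        df = pd.DataFrame({"a": [1.0, np.nan], "b": [1.0, 2.0]}, index=["x", "y"])
        with pytest.raises(DataError):
            build_decision_problem(df, specs(["a", "b"]))

    def test_zero_config_weights_get_equal_default(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 4.0]}, index=["x", "y"])
        m = build_decision_problem(df, specs(["a", "b"], weight=0.0))
        assert m.weights.weights == (0.5, 0.5)


class TestWeightVector:
    def test_rejects_bad_sum(self):
        with pytest.raises(ValidationError):
            WeightVector((0.5, 0.6))

    def test_iterates_and_sums_to_one(self):
        wv = WeightVector((0.25, 0.75))
        assert sum(wv) == 1.0
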