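"""Multidiversity / multifunctionality indices and profit slopes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from landuse_tradeoffs import ThresholdConfig
from landuse_tradeoffs.errors import (DegenerateDesignError, DomainError)
from landuse_tradeoffs.indices import (forest_species_subset,
                                       index_profit_slope, invert_indicator,
                                       max_performance_level, multidiversity,
                                       multifunctionality,
                                       multifunctionality_sweep,
                                       multidiversity_sweep, threshold_sweep)


def _toy_incidence():
    plots = pd.DataFrame({"land_use": ["F", "O"], "landscape": "L1",
                          "yield_kg_ha_yr": [0.0, 100.0]},
                         index=pd.Index(["pF", "pO"], name="plot_id"))
    inc = pd.DataFrame([[1, 1, 0], [0, 1, 1]], index=plots.index,
                       columns=["s1", "s2", "s3"])
    return inc, plots


def test_forest_subset_drops_non_forest_species():
    inc, plots = _toy_incidence()
    sub = forest_species_subset(inc, plots)
    assert list(sub.columns) == ["s1", "s2"]
    assert sub.loc["pO"].sum() == 1  # forest-subset richness of the O plot


def test_forest_subset_identity_when_all_species_in_forest():
    inc, plots = _toy_incidence()
    inc.loc["pF"] = 1
    pd.testing.assert_frame_equal(forest_species_subset(inc, plots), inc)


def test_forest_subset_requires_forest_plot():
    inc, plots = _toy_incidence()
    with pytest.raises(DomainError):
        forest_species_subset(inc.drop(index="pF"), plots)


@pytest.mark.parametrize("values,k,expected", [
    (list(range(1, 11)), 5, 8.0),  # mean of 6..10
    ([2, 4, 6], 5, 4.0),  # fewer than k: uses all
    ([3.5] * 7, 5, 3.5),
])
def test_max_performance_level(values, k, expected):
    assert max_performance_level(values, k) == pytest.approx(expected)


def test_max_performance_level_empty_raises():
    with pytest.raises(DomainError):
        max_performance_level([np.nan])


def test_invert_indicator_reflection():
    np.testing.assert_allclose(invert_indicator([2, 5, 10]), [10, 7, 2])
    np.testing.assert_allclose(invert_indicator([4.0, 4.0]), [4.0, 4.0])


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=20))
def test_invert_indicator_is_involution(values):
    v = np.asarray(values)
    np.testing.assert_allclose(invert_indicator(invert_indicator(v)), v,
                               atol=1e-6 * max(1.0, np.abs(v).max()))


def test_multidiversity_hand_examples():
    levels = {"a": 10.0, "b": 10.0, "c": 10.0}
    assert multidiversity({"a": 10, "b": 5, "c": 0}, levels, 0.5) == \
        pytest.approx(2 / 3)
    assert multidiversity({"a": 9, "b": 5, "c": 0}, levels, 0.98) == 0.0
    # missing group: denominator adjusts
    rich = {f"g{i}": 10.0 for i in range(13)}
    rich["g13"] = np.nan
    lev = {g: 10.0 for g in rich}
    assert multidiversity(rich, lev, 0.5) == 1.0


def test_multifunctionality_hand_example():
    meta = pd.DataFrame(
        {"function_group": ["A", "A", "B"],
         "direction": ["higher_better"] * 3},
        index=pd.Index(["a1", "a2", "b1"], name="indicator"))
    levels = {"a1": 10.0, "a2": 10.0, "b1": 10.0}
    # one of A's two indicators passes (w = 0.5), B's single one passes
    val = multifunctionality({"a1": 9, "a2": 1, "b1": 8}, meta, levels, 0.5)
    assert val == pytest.approx((0.5 + 1.0) / 2)
    assert multifunctionality({"a1": 9, "a2": 9, "b1": 8}, meta, levels,
                              0.5) == 1.0


def test_eight_indicator_function_weights():
    from landuse_tradeoffs.indices import _weights
    meta = pd.DataFrame(
        {"function_group": ["f"] * 8, "direction": ["higher_better"] * 8},
        index=pd.Index([f"i{k}" for k in range(8)], name="indicator"))
    assert (_weights(meta) == 0.125).all()


def test_threshold_sweep_shape_and_monotonicity(default_ds):
    for kind in ("multidiversity", "multifunctionality"):
        table = threshold_sweep(default_ds, kind)
        assert table.shape == (32, 99)
        vals = table.to_numpy()
        assert ((vals >= 0) & (vals <= 1)).all()
        assert (np.diff(vals, axis=1) <= 1e-12).all()


def test_plot_at_maximum_scores_one_everywhere():
    rich = pd.DataFrame({"g1": [10.0, 1.0], "g2": [8.0, 2.0]},
                        index=["top", "low"])
    table = multidiversity_sweep(rich, ThresholdConfig(top_k=1))
    assert (table.loc["top"] == 1.0).all()


def test_split_indicator_invariance():
    """Duplicating an indicator within its function leaves the index
    unchanged (weights halve, pass/fail pattern identical)."""
    rng = np.random.default_rng(0)
    idx = [f"p{i}" for i in range(10)]
    base = pd.DataFrame({"x": rng.random(10) * 5, "y": rng.random(10)},
                        index=idx)
    meta = pd.DataFrame({"function_group": ["A", "B"],
                         "direction": ["higher_better", "lower_better"]},
                        index=pd.Index(["x", "y"], name="indicator"))
    split = base.assign(x2=base["x"])
    meta_split = pd.DataFrame(
        {"function_group": ["A", "B", "A"],
         "direction": ["higher_better", "lower_better", "higher_better"]},
        index=pd.Index(["x", "y", "x2"], name="indicator"))
    a = multifunctionality_sweep(base, meta)
    b = multifunctionality_sweep(split, meta_split)
    np.testing.assert_allclose(a.to_numpy(), b.to_numpy())


def test_missing_group_does_not_affect_other_plots():
    rich = pd.DataFrame({"g1": [10.0, 6.0], "g2": [8.0, 4.0]},
                        index=["a", "b"])
    with_missing = rich.copy()
    with_missing.loc["b", "g2"] = np.nan
    cfg = ThresholdConfig(top_k=1)
    a = multidiversity_sweep(rich, cfg)
    b = multidiversity_sweep(with_missing, cfg)
    np.testing.assert_allclose(a.loc["a"], b.loc["a"])


def _profits(values):
    return pd.DataFrame({"profit_mean": values, "me_variance": 0.0},
                        index=[f"p{i}" for i in range(len(values))])


def test_slope_exact_linear_index():
    prof = np.linspace(0, 1000, 8)
    table = pd.DataFrame({0.5: 1 - 0.0008 * prof},
                         index=[f"p{i}" for i in range(8)])
    out = index_profit_slope(table, _profits(prof))
    assert out.loc[0.5, "slope_per_100usd"] == pytest.approx(-0.08)
    assert out.loc[0.5, "hi"] - out.loc[0.5, "lo"] == pytest.approx(0.0,
                                                                    abs=1e-10)


def test_slope_constant_index_is_zero():
    prof = np.linspace(0, 1000, 8)
    table = pd.DataFrame({0.5: np.full(8, 0.4)},
                         index=[f"p{i}" for i in range(8)])
    out = index_profit_slope(table, _profits(prof))
    assert out.loc[0.5, "slope_per_100usd"] == pytest.approx(0.0, abs=1e-12)


def test_slope_constant_profits_rejected():
    table = pd.DataFrame({0.5: np.linspace(0, 1, 8)},
                         index=[f"p{i}" for i in range(8)])
    with pytest.raises(DegenerateDesignError):
        index_profit_slope(table, _profits(np.full(8, 500.0)))
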