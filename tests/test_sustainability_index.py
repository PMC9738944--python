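import math

import numpy as np
import pandas as pd
import pytest

import carbonscape as cs
from carbonscape.sustainability_index import IndicatorTable, quantile_bands


def make_table(values: dict, orientations: dict, regions=None) -> IndicatorTable:
    df = pd.DataFrame(values)
    if regions is not None:
        df.index = regions
    return IndicatorTable(values=df, orientations=orientations)


def hand_entropy_method(values, orientations):
    """Independent spreadsheet-style evaluation with plain-Python loops."""
    regions = list(values.index)
    cols = list(values.columns)
    n = len(regions)
    std = {}
    for c in cols:
        col = [float(v) for v in values[c]]
        lo, hi = min(col), max(col)
        if orientations[c] == "+":
            std[c] = [(v - lo) / (hi - lo) for v in col]
        else:
            std[c] = [(hi - v) / (hi - lo) for v in col]
    entropies = {}
    for c in cols:
        total = sum(std[c])
        r = [v / total for v in std[c]]
        entropies[c] = -sum(x * math.log(x) for x in r if x > 0) / math.log(n)
    info = {c: 1 - entropies[c] for c in cols}
    wsum = sum(info.values())
    w = {c: info[c] / wsum for c in cols}
    scores = [sum(std[c][i] * w[c] for c in cols) for i in range(n)]
    return w, dict(zip(regions, scores))


class TestStandardize:
    def test_conventional_endpoints(self):
        t = make_table({"a": [10, 20, 15]}, {"a": "+"})
        std = cs.standardize(t)
        assert std["a"].iloc[0] == 0.0 and std["a"].iloc[1] == 1.0

    def test_negative_indicator_endpoints(self):
        t = make_table({"b": [10, 20, 15]}, {"b": "-"})
        std = cs.standardize(t)
        assert std["b"].iloc[0] == 1.0 and std["b"].iloc[1] == 0.0

    def test_as_printed_swaps_orientations(self):
        t = make_table({"a": [10.0, 20.0]}, {"a": "+"})
        conv = cs.standardize(t, form="conventional")
        lit = cs.standardize(t, form="as_printed")
        assert list(conv["a"]) == [0.0, 1.0]
        assert list(lit["a"]) == [1.0, 0.0]

    def test_constant_column_maps_to_half(self):
        t = make_table({"a": [5.0, 5.0], "b": [1.0, 2.0]}, {"a": "+", "b": "+"})
        std = cs.standardize(t)
        assert (std["a"] == 0.5).all()

    def test_single_region_rejected(self):
        with pytest.raises(ValueError, match="2 regions"):
            make_table({"a": [1.0]}, {"a": "+"})


class TestEntropy:
    def test_uniform_column_is_one(self):
        std = pd.DataFrame({"a": [0.4, 0.4, 0.4, 0.4]})
        assert cs.entropy(std)["a"] == pytest.approx(1.0)

    def test_one_hot_column_is_zero(self):
        std = pd.DataFrame({"a": [1.0, 0.0, 0.0]})
        assert cs.entropy(std)["a"] == pytest.approx(0.0, abs=1e-12)

    def test_hand_evaluated_three_region_column(self):
        # R = (0.5, 0.3, 0.2), n = 3 -> S ≈ 0.9372306
        std = pd.DataFrame({"a": [0.5, 0.3, 0.2]})
        assert cs.entropy(std)["a"] == pytest.approx(0.9372306, abs=1e-6)

    def test_all_zero_column_convention(self):
        std = pd.DataFrame({"a": [0.0, 0.0, 0.0]})
        assert cs.entropy(std)["a"] == 1.0


class TestWeights:
    def test_equal_entropies_equal_weights(self):
        w = cs.weights(pd.Series({"a": 0.7, "b": 0.7, "c": 0.7}))
        np.testing.assert_allclose(w, 1 / 3)

    def test_direct_ratio(self):
        w = cs.weights(pd.Series({"a": 0.9, "b": 0.8}))
        assert w["a"] == pytest.approx(1 / 3)
        assert w["b"] == pytest.approx(2 / 3)

    def test_thirteen_indicators_sum_to_one(self):
        rng = np.random.default_rng(0)
        s = pd.Series(rng.uniform(0.2, 0.99, 13), index=[f"i{j}" for j in range(13)])
        w = cs.weights(s)
        assert w.sum() == pytest.approx(1.0, abs=1e-9)
        info = 1 - s
        np.testing.assert_allclose(w, info / info.sum())

    def test_degenerate_all_max_entropy(self):
        w = cs.weights(pd.Series({"a": 1.0, "b": 1.0}))
        np.testing.assert_allclose(w, 0.5)


class TestScore:
    def test_dominating_region_scores_one(self):
        t = make_table(
            {"a": [10.0, 5.0, 1.0], "b": [1.0, 5.0, 9.0]},
            {"a": "+", "b": "-"},
            regions=["best", "mid", "worst"],
        )
        w, e = cs.assess(t)
        assert e["best"] == pytest.approx(1.0)
        assert e["worst"] == pytest.approx(0.0)

    def test_identical_rows_equal_scores(self):
        t = make_table({"a": [3.0, 3.0], "b": [7.0, 7.0]}, {"a": "+", "b": "-"})
        _, e = cs.assess(t)
        assert e.iloc[0] == e.iloc[1]

    def test_three_by_two_matches_hand_oracle(self):
        t = make_table(
            {"a": [10.0, 20.0, 40.0], "b": [5.0, 3.0, 1.0]},
            {"a": "+", "b": "-"},
            regions=["r1", "r2", "r3"],
        )
        w, e = cs.assess(t)
        hw, he = hand_entropy_method(t.values, t.orientations)
        for c in ("a", "b"):
            assert w[c] == pytest.approx(hw[c], abs=1e-12)
        for r in ("r1", "r2", "r3"):
            assert e[r] == pytest.approx(he[r], abs=1e-12)
        # frozen values from the hand computation
        assert w["a"] == pytest.approx(0.5371499, abs=1e-6)
        assert e["r2"] == pytest.approx(0.4104750, abs=1e-6)

    def test_affine_rescaling_invariance(self):
        base = {"a": [10.0, 20.0, 40.0], "b": [5.0, 3.0, 1.0]}
        t1 = make_table(base, {"a": "+", "b": "-"})
        t2 = make_table(
            {"a": [100 * v + 7 for v in base["a"]], "b": base["b"]},
            {"a": "+", "b": "-"},
        )
        _, e1 = cs.assess(t1)
        _, e2 = cs.assess(t2)
        np.testing.assert_allclose(e1, e2, atol=1e-12)

    def test_improving_positive_indicator_never_lowers_score(self):
        rng = np.random.default_rng(4)
        vals = {"a": rng.uniform(0, 10, 5).tolist(), "b": rng.uniform(0, 10, 5).tolist()}
        t = make_table(vals, {"a": "+", "b": "+"})
        _, e_before = cs.assess(t)
        vals2 = dict(vals)
        bumped = list(vals["a"])
        bumped[2] = max(bumped) + 1.0  # strictly better on a positive indicator
        vals2["a"] = bumped
        _, e_after = cs.assess(make_table(vals2, {"a": "+", "b": "+"}))
        assert e_after.iloc[2] >= e_before.iloc[2] - 1e-12

    def test_as_printed_score_uses_raw_values(self):
        t = make_table({"a": [10.0, 20.0]}, {"a": "+"})
        std = cs.standardize(t)
        w = cs.weights(cs.entropy(std))
        raw_scores = cs.score(std, w, basis="as_printed", raw=t.values)
        assert list(raw_scores) == [10.0, 20.0]  # single weight 1 on raw values


class TestSyntheticIndicatorTables:
    def test_dominated_design_wins_downstream(self):
        specs = [cs.IndicatorSpec(f"i{j}", "+" if j % 3 else "-") for j in range(13)]
        t = cs.generate_indicator_table(9, specs, seed=5, dominant_region="alpha")
        w, e = cs.assess(t)
        assert len(w) == 13 and w.sum() == pytest.approx(1.0, abs=1e-9)
        assert e.idxmax() == "alpha"

    def test_too_few_regions_rejected(self):
        with pytest.raises(ValueError):
            cs.generate_indicator_table(1, [cs.IndicatorSpec("x", "+")])

    def test_determinism(self):
        specs = [cs.IndicatorSpec("x", "+"), cs.IndicatorSpec("y", "-")]
        a = cs.generate_indicator_table(5, specs, seed=9)
        b = cs.generate_indicator_table(5, specs, seed=9)
        pd.testing.assert_frame_equal(a.values, b.values)


class TestCsvRoundTrip:
    def test_indicator_csv_round_trip(self, tmp_path):
        specs = [cs.IndicatorSpec("x", "+"), cs.IndicatorSpec("y", "-")]
        t = cs.generate_indicator_table(4, specs, seed=2)
        path = tmp_path / "ind.csv"
        t.to_csv(path)
        back = IndicatorTable.from_csv(path)
        pd.testing.assert_frame_equal(back.values, t.values)
        assert back.orientations == t.orientations


def test_quantile_bands_four_bins():
    scores = pd.Series(np.linspace(0.1, 0.9, 8), index=[f"r{i}" for i in range(8)])
    bands = quantile_bands(scores, 4)
    assert list(bands) == [1, 1, 2, 2, 3, 3, 4, 4]
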