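from itertools import permutations as iter_permutations

import numpy as np
import pandas as pd
import pytest

from elevbreak import (geochem_indices, dereplicate_predictors, all_subsets_average,
                       geo_increment, variation_partition, composite_score, path_fit,
                       permutation_lm)


class TestGeochemIndices:
    def test_cia_hand_values(self):
        t = pd.DataFrame({"al2o3": [50.0, 10.0], "cao_star": [20.0, 10.0],
                          "na2o": [15.0, 10.0], "k2o": [15.0, 10.0],
                          "ti": [1.0, 1.0], "fe": [2.0, 2.0], "al": [4.0, 4.0],
                          "mg": [1.0, 1.0], "ca": [2.0, 2.0]})
        out = geochem_indices(t)
        assert out["cia"].iloc[0] == pytest.approx(50.0)
        assert out["cia"].iloc[1] == pytest.approx(25.0)   # all oxides equal
        assert out["ca_al"].iloc[0] == pytest.approx(0.5)
        assert out["ti_fe"].iloc[0] == pytest.approx(0.5)

    def test_zero_denominator_gives_missing(self):
        t = pd.DataFrame({"al2o3": [1.0], "cao_star": [1.0], "na2o": [1.0],
                          "k2o": [1.0], "ti": [1.0], "fe": [0.0], "al": [1.0],
                          "mg": [1.0], "ca": [1.0]})
        out = geochem_indices(t)
        assert np.isnan(out["ti_fe"].iloc[0])


class TestDereplication:
    def test_duplicate_keeps_exactly_one(self, rng):
        x = pd.Series(rng.normal(size=40))
        preds = pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=40)})
        resp = pd.Series(x + rng.normal(0, 0.1, 40))
        kept, log = dereplicate_predictors(preds, resp)
        assert kept.shape[1] == 2
        assert len(log) == 1

    def test_exact_threshold_keeps_both(self):
        # constructed pair with sample correlation exactly 0.7
        x = np.array([1.0, 1.0, -1.0, -1.0])
        z = np.array([1.0, -1.0, 1.0, -1.0])
        y = 0.7 * x + np.sqrt(1 - 0.49) * z
        preds = pd.DataFrame({"a": x, "b": y})
        kept, log = dereplicate_predictors(preds, pd.Series(x))
        assert list(kept.columns) == ["a", "b"]
        assert log == []

    def test_orthogonal_predictors_untouched(self, rng):
        preds = pd.DataFrame(rng.normal(size=(60, 4)), columns=list("abcd"))
        kept, log = dereplicate_predictors(preds, pd.Series(rng.normal(size=60)))
        assert list(kept.columns) == list("abcd")


class TestModelAveraging:
    def test_single_predictor_beta_is_standardized_slope(self, rng):
        x = pd.Series(rng.normal(size=50))
        y = pd.Series(2.0 * x + rng.normal(0, 0.5, 50))
        res = all_subsets_average(y, x.to_frame("x"))
        zx = (x - x.mean()) / x.std(ddof=1)
        zy = (y - y.mean()) / y.std(ddof=1)
        slope = float(np.polyfit(zx, zy, 1)[0])
        assert res.beta["x"] == pytest.approx(slope, abs=1e-9)
        assert res.models["weight"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_orthonormal_strong_effects_match_full_ols(self, rng):
        q, _ = np.linalg.qr(rng.normal(size=(80, 3)))
        x = pd.DataFrame(q, columns=list("abc"))
        y = pd.Series(q @ np.array([3.0, -2.0, 2.5]) + rng.normal(0, 0.2, 80))
        res = all_subsets_average(y, x)
        zx = (x - x.mean()) / x.std(ddof=1)
        zy = (y - y.mean()) / y.std(ddof=1)
        full, *_ = np.linalg.lstsq(np.column_stack([np.ones(80), zx.to_numpy()]),
                                   zy.to_numpy(), rcond=None)
        for j, name in enumerate(x.columns):
            assert res.beta[name] == pytest.approx(full[j + 1], rel=0.01)
        assert ((res.importance > 0.99) | (res.importance <= 1.0)).all()

    def test_too_many_predictors_rejected(self, rng):
        x = pd.DataFrame(rng.normal(size=(40, 16)))
        with pytest.raises(ValueError, match="dereplicate"):
            all_subsets_average(pd.Series(rng.normal(size=40)), x)


class TestGeoIncrement:
    def test_duplicated_block_adds_nothing(self, rng):
        x = pd.DataFrame(rng.normal(size=(60, 2)), columns=["c1", "c2"])
        y = pd.Series(x["c1"] * 2 + rng.normal(0, 0.3, 60))
        geo = x.rename(columns={"c1": "g1", "c2": "g2"})
        res = geo_increment(y, x, geo, census=False)
        assert res.absolute_increase == pytest.approx(0.0, abs=1e-9)

    def test_planted_geological_signal_detected(self, rng):
        c = pd.DataFrame(rng.normal(size=(120, 3)), columns=["mat", "ph", "mo"])
        g = pd.DataFrame(rng.normal(size=(120, 2)), columns=["cia", "ti_fe"])
        y = pd.Series(c["mat"] + 0.8 * g["cia"] + rng.normal(0, 0.5, 120))
        res = geo_increment(y, c, g)
        assert res.p_value < 0.05
        assert res.percent_increase > 0
        assert res.significant_fraction == 1.0
        assert "cia" in res.selected_geological

    def test_blocks_must_be_disjoint(self, rng):
        x = pd.DataFrame(rng.normal(size=(30, 2)), columns=["a", "b"])
        with pytest.raises(ValueError):
            geo_increment(pd.Series(rng.normal(size=30)), x, x[["a"]], census=False)


class TestVariationPartition:
    def test_fractions_sum_to_one(self, rng):
        for _ in range(5):
            a = pd.DataFrame(rng.normal(size=(50, 3)))
            a.columns = ["a1", "a2", "a3"]
            b = pd.DataFrame(rng.normal(size=(50, 2)), columns=["b1", "b2"])
            y = pd.Series(rng.normal(size=50))
            vp = variation_partition(y, a, b)
            assert vp.a + vp.b + vp.c + vp.d == pytest.approx(1.0, abs=1e-9)
            assert vp.a + vp.b + vp.c == pytest.approx(vp.adj_r2_ab, abs=1e-9)

    def test_signal_attributed_to_generating_block(self, rng):
        a = pd.DataFrame(rng.normal(size=(400, 2)), columns=["a1", "a2"])
        b = pd.DataFrame(rng.normal(size=(400, 2)), columns=["b1", "b2"])
        y = pd.Series(a["a1"] - a["a2"] + rng.normal(0, 0.5, 400))
        vp = variation_partition(y, a, b)
        assert vp.b == pytest.approx(0.0, abs=0.02)      # B is pure noise
        assert vp.a == pytest.approx(vp.adj_r2_a, abs=0.02)
        assert vp.a > 0.5


class TestCompositeScore:
    def test_single_indicator_is_its_zscore(self, rng):
        x = pd.Series(rng.normal(size=40), name="x")
        y = pd.Series(2 * x + rng.normal(0, 0.1, 40))
        comp, w = composite_score(x.to_frame(), y)
        z = (x - x.mean()) / x.std(ddof=1)
        assert np.allclose(np.abs(comp), np.abs(z), atol=1e-9)
        assert comp.std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_equal_true_effects_get_equal_weights(self, rng):
        x = pd.DataFrame(rng.normal(size=(3000, 2)), columns=["u", "v"])
        y = pd.Series(x["u"] + x["v"] + rng.normal(0, 0.3, 3000))
        _, w = composite_score(x, y)
        assert abs(w["u"]) == pytest.approx(abs(w["v"]), rel=0.1)


class TestPathFit:
    def test_deterministic_chain(self):
        x = pd.Series(np.linspace(-2, 2, 30))
        data = pd.DataFrame({"x": x, "m": x.copy(), "y": x.copy()})
        pm = path_fit(data, [("x", "m"), ("m", "y")], outcome="y")
        assert pm.coefficients[("x", "m")] == pytest.approx(1.0)
        assert pm.coefficients[("m", "y")] == pytest.approx(1.0)
        assert pm.direct["x"] == 0.0
        assert pm.indirect["x"] == pytest.approx(1.0)
        assert pm.total["x"] == pytest.approx(1.0)

    def test_saturated_model_zero_srmr(self, rng):
        data = pd.DataFrame(rng.normal(size=(200, 3)), columns=["x", "m", "y"])
        pm = path_fit(data, [("x", "m"), ("x", "y"), ("m", "y")], outcome="y")
        assert pm.srmr == pytest.approx(0.0, abs=1e-9)

    def test_total_effect_equals_simple_slope(self, rng):
        """Path-tracing oracle: in the mediation model x -> m -> y plus x -> y on
        standardized data, x's total effect equals the simple regression slope."""
        n = 10_000
        x = rng.normal(size=n)
        m = 0.6 * x + rng.normal(0, 0.8, n)
        y = 0.5 * m + 0.3 * x + rng.normal(0, 0.7, n)
        data = pd.DataFrame({"x": x, "m": m, "y": y})
        pm = path_fit(data, [("x", "m"), ("x", "y"), ("m", "y")], outcome="y")
        zx = (x - x.mean()) / x.std(ddof=1)
        zy = (y - y.mean()) / y.std(ddof=1)
        simple = float(np.polyfit(zx, zy, 1)[0])
        assert pm.total["x"] == pytest.approx(simple, abs=0.02)

    def test_cycle_rejected(self, rng):
        data = pd.DataFrame(rng.normal(size=(30, 2)), columns=["a", "b"])
        with pytest.raises(ValueError, match="cycle"):
            path_fit(data, [("a", "b"), ("b", "a")], outcome="b")


class TestPermutationLM:
    def test_constant_response(self):
        slope, p = permutation_lm([1.0, 2.0, 3.0, 4.0], [5.0, 5.0, 5.0, 5.0])
        assert slope == 0.0 and p == 1.0

    def test_exhaustive_matches_bruteforce(self, rng):
        """n=5: all 120 response orders enumerated; p agrees with an
        independently coded enumeration of the same statistic."""
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        y = rng.normal(size=5)
        slope, p = permutation_lm(x, y, n_perm=4999)
        xc = x - x.mean()
        sxx = xc @ xc
        obs = abs(xc @ (y - y.mean()) / sxx)
        count = sum(abs(xc @ (np.array(perm) - np.mean(perm)) / sxx) >= obs - 1e-12
                    for perm in iter_permutations(y))
        assert p == pytest.approx(count / 120)

    def test_strong_signal_hits_resolution_floor(self, rng):
        x = np.linspace(0, 1, 40)
        y = 3 * x + rng.normal(0, 0.01, 40)
        _, p = permutation_lm(x, y, n_perm=999, seed=0)
        assert p == pytest.approx(1 / 1000)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError):
            permutation_lm([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])
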