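"""Presence-background model, AUC, permutation importance, variable selection."""

import numpy as np
import pandas as pd
import pytest

import invasim as iv
from invasim.suitability import PresenceBackground, training_auc

from conftest import small_grid


def auc_bruteforce(pres, bg):
    """All-pairs rank oracle: P(p > b) + 0.5 P(p == b)."""
    wins = ties = 0
    for p in pres:
        for b in bg:
            wins += p > b
            ties += p == b
    return (wins + 0.5 * ties) / (len(pres) * len(bg))


class TestAUC:
    @pytest.mark.parametrize("pres, bg, expected", [
        ([0.9, 0.8], [0.1, 0.2], 1.0),
        ([0.5], [0.5], 0.5),
        ([0.9, 0.4], [0.5, 0.1], 0.75),
    ])
    def test_examples(self, pres, bg, expected):
        assert iv.auc(pres, bg) == pytest.approx(expected)

    def test_empty_error(self):
        with pytest.raises(ValueError, match="non-empty"):
            iv.auc([], [0.5])

    def test_matches_all_pairs_oracle_on_100_random_sets(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            n_p, n_b = rng.integers(1, 30, 2)
            # coarse rounding forces plenty of ties
            pres = np.round(rng.random(n_p), 1)
            bg = np.round(rng.random(n_b), 1)
            assert iv.auc(pres, bg) == pytest.approx(auc_bruteforce(pres, bg))

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        pres, bg = rng.random(20), rng.random(30)
        base = iv.auc(pres, bg)
        for f in (lambda x: 3 * x - 1, np.exp, lambda x: x ** 3):
            assert iv.auc(f(pres), f(bg)) == pytest.approx(base)


def separable_data(n=200, seed=0, noise_col=False):
    """Presences at high values of x0, background at low values."""
    rng = np.random.default_rng(seed)
    xp = np.column_stack([rng.uniform(0.6, 1.0, n), rng.random(n)])
    xb = np.column_stack([rng.uniform(0.0, 0.4, n), rng.random(n)])
    variables = ["temp", "noise"] if noise_col else ["temp", "other"]
    if not noise_col:
        xp[:, 1] = xp[:, 0] * 0.5 + rng.normal(0, 0.05, n)
        xb[:, 1] = xb[:, 0] * 0.5 + rng.normal(0, 0.05, n)
    X = np.vstack([xp, xb])
    y = np.concatenate([np.ones(n), np.zeros(n)])
    return PresenceBackground(variables, X, y, xp, xb)


class TestFit:
    def test_separable_training_auc(self):
        data = separable_data(seed=1)
        model = iv.fit_suitability(data)
        assert training_auc(model, data) >= 0.95

    def test_noise_coefficient_shrinks_under_large_penalty(self):
        data = separable_data(seed=2, noise_col=True)
        model = iv.fit_suitability(data, reg=5.0)
        idx = [i for i, (v, t, _) in enumerate(model.feature_spec) if v == "noise"]
        assert np.all(np.abs(model.coefficients[idx]) < 10 * np.finfo(float).eps)

    def test_row_duplication_invariance(self):
        data = separable_data(seed=3)
        doubled = PresenceBackground(
            data.variables, np.vstack([data.X, data.X]),
            np.concatenate([data.y, data.y]),
            data.presence_points, data.background_points)
        m1 = iv.fit_suitability(data, tol=1e-8)
        m2 = iv.fit_suitability(doubled, tol=1e-8)
        np.testing.assert_allclose(m1.predict_rows(data.X), m2.predict_rows(data.X),
                                   atol=1e-6)

    def test_degenerate_predictor_error(self):
        data = separable_data(seed=4)
        data.X[:, 1] = 3.14
        with pytest.raises(ValueError, match="other"):
            iv.fit_suitability(data)

    def test_too_few_points_error(self):
        bad = PresenceBackground(["a"], np.array([[1.0], [0.0], [0.2]]),
                                 np.array([1.0, 0.0, 0.0]),
                                 np.zeros((1, 2)), np.zeros((2, 2)))
        with pytest.raises(ValueError, match="at least 2"):
            iv.fit_suitability(bad)


class TestPredict:
    def _layers(self, seed=0):
        g = small_grid(12)
        rng = np.random.default_rng(seed)
        return {
            "temp": iv.Layer(g, rng.uniform(0, 30, g.shape), name="temp"),
            "other": iv.Layer(g, rng.uniform(0, 1, g.shape), name="other"),
        }

    def test_range_and_mask(self):
        layers = self._layers()
        layers["temp"].mask[2, 3] = True
        g = layers["temp"].grid
        rng = np.random.default_rng(1)
        bg = iv.sample_background(g.extent, layers, 100, rng)
        pres = bg[layers["temp"].sample(bg[:, 0], bg[:, 1])[0] > 15]
        data = PresenceBackground.from_layers(pres, bg, layers)
        model = iv.fit_suitability(data)
        out = model.predict(layers)
        assert out.mask[2, 3]
        vals = out.values[~out.mask]
        assert ((vals >= 0) & (vals <= 1)).all()

    def test_all_zero_coefficients_constant_output(self):
        layers = self._layers()
        model = iv.FittedSuitabilityModel(
            variables=["temp"], feature_spec=[("temp", "linear", 0.0)],
            coefficients=np.zeros(1), intercept=0.0,
            var_min=np.array([0.0]), var_max=np.array([30.0]))
        out = model.predict({"temp": layers["temp"]})
        np.testing.assert_allclose(out.values, 1 - np.exp(-1))

    def test_monotone_in_single_positive_variable(self):
        layers = self._layers()
        model = iv.FittedSuitabilityModel(
            variables=["temp"], feature_spec=[("temp", "linear", 0.0)],
            coefficients=np.array([2.5]), intercept=-1.0,
            var_min=np.array([0.0]), var_max=np.array([30.0]))
        out = model.predict({"temp": layers["temp"]})
        order = np.argsort(layers["temp"].values.ravel())
        assert (np.diff(out.values.ravel()[order]) >= 0).all()

    def test_missing_variable_error(self):
        model = iv.FittedSuitabilityModel(
            variables=["temp"], feature_spec=[("temp", "linear", 0.0)],
            coefficients=np.zeros(1), intercept=0.0,
            var_min=np.array([0.0]), var_max=np.array([1.0]))
        with pytest.raises(ValueError, match="temp"):
            model.predict({})


class TestSampleBackground:
    def test_zero_n(self, grid10, rng):
        layers = {"x": iv.constant_layer(grid10, 1.0)}
        assert iv.sample_background(grid10.extent, layers, 0, rng).shape == (0, 2)

    def test_single_cell_extent(self, grid10, rng):
        layers = {"x": iv.constant_layer(grid10, 1.0)}
        lon, lat = grid10.center_of(3, 3)
        ext = iv.Extent(lon - 0.01, lon + 0.01, lat - 0.01, lat + 0.01)
        pts = iv.sample_background(ext, layers, 5, rng)
        assert (pts == [lon, lat]).all()

    def test_seed_determinism(self, grid10):
        layers = {"x": iv.constant_layer(grid10, 1.0)}
        a = iv.sample_background(grid10.extent, layers, 50, np.random.default_rng(9))
        b = iv.sample_background(grid10.extent, layers, 50, np.random.default_rng(9))
        np.testing.assert_array_equal(a, b)

    def test_all_masked_error(self, grid10, rng):
        lyr = iv.constant_layer(grid10, 1.0)
        lyr.mask[:] = True
        with pytest.raises(ValueError, match="unmasked"):
            iv.sample_background(grid10.extent, {"x": lyr}, 10, rng)


def importance_bruteforce(model, data, reps, seed):
    """Independent permute-and-rescore loop sharing the RNG stream."""
    rng = np.random.default_rng(seed)
    s0 = model.predict_rows(data.X)
    base = auc_bruteforce(s0[data.y == 1], s0[data.y == 0])
    rows = []
    for rep in range(reps):
        raw = []
        for j, v in enumerate(data.variables):
            Xp = data.X.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            s = model.predict_rows(Xp)
            raw.append(base - auc_bruteforce(s[data.y == 1], s[data.y == 0]))
        raw = np.maximum(np.asarray(raw), 0.0)
        tot = raw.sum()
        pct = raw / tot * 100 if tot > 0 else np.full(len(raw), 100 / len(raw))
        rows.extend({"variable": v, "rep": rep, "importance_pct": p}
                    for v, p in zip(data.variables, pct))
    return pd.DataFrame(rows)


class TestPermutationImportance:
    def test_zero_coefficient_variable_scores_zero(self):
        data = separable_data(seed=5, noise_col=True)
        model = iv.FittedSuitabilityModel(
            variables=["temp", "noise"],
            feature_spec=[("temp", "linear", 0.0), ("noise", "linear", 0.0)],
            coefficients=np.array([4.0, 0.0]), intercept=-2.0,
            var_min=data.X.min(0), var_max=data.X.max(0))
        table = iv.permutation_importance(model, data, reps=3,
                                          rng=np.random.default_rng(0))
        means = table.mean_importance()
        assert means["noise"] == pytest.approx(0.0)
        assert means["temp"] == pytest.approx(100.0)

    def test_matches_independent_loop_with_shared_rng(self):
        data = separable_data(seed=6)
        model = iv.fit_suitability(data)
        got = iv.permutation_importance(model, data, reps=5,
                                        rng=np.random.default_rng(77))
        want = importance_bruteforce(model, data, reps=5, seed=77)
        got_m = got.table.groupby("variable")["importance_pct"].mean()
        want_m = want.groupby("variable")["importance_pct"].mean()
        pd.testing.assert_series_equal(got_m, want_m, rtol=1e-12)

    def test_per_rep_normalization(self):
        data = separable_data(seed=8)
        model = iv.fit_suitability(data)
        table = iv.permutation_importance(model, data, reps=4,
                                          rng=np.random.default_rng(1)).table
        sums = table.groupby("rep")["importance_pct"].sum()
        np.testing.assert_allclose(sums, 100.0)
        assert (table["importance_pct"] >= 0).all()


class TestSelectVariables:
    def _table(self, means):
        rows = [{"variable": v, "rep": 0, "importance_pct": m} for v, m in means.items()]
        return iv.ImportanceTable(pd.DataFrame(rows))

    def test_top_k_and_ordering(self):
        t = self._table({"A": 60, "B": 30, "C": 10})
        assert iv.select_variables(t, 2) == ["A", "B"]
        assert iv.select_variables(t, 3) == ["A", "B", "C"]
        assert iv.select_variables(t, 0) == []

    def test_ties_broken_by_name(self):
        t = self._table({"B": 50, "A": 50})
        assert iv.select_variables(t, 1) == ["A"]
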