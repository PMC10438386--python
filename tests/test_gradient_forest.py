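"""Gradient-forest turnover functions, projection, and Procrustes comparison."""

import math

import numpy as np
import pandas as pd
import pytest

from landgea import envlayers, synthetic
from landgea.envlayers import EnvStack, GridSpec
from landgea.gradient import (max_splits, fit_gradient_forest, project_turnover,
                              procrustes_residuals, pcnm_surfaces,
                              TurnoverModel, TurnoverGrid)
from landgea.synthetic import LandscapeSpec, TruthTable

from _oracles import procrustes_closed_form


class TestMaxSplits:
    def test_printed_formula_values(self):
        assert max_splits(13) == pytest.approx(math.log2(0.368 * 13) / 2)
        assert max_splits(13) == pytest.approx(1.1292, abs=1e-3)
        assert max_splits(34) == pytest.approx(1.8226, abs=1e-3)

    def test_exact_half_at_two(self):
        assert max_splits(2 / 0.368) == pytest.approx(0.5, abs=1e-12)

    def test_too_few_predictors_rejected(self):
        with pytest.raises(ValueError):
            max_splits(2)


@pytest.fixture(scope="module")
def fitted():
    """Small fitted turnover model with one causal variable."""
    spec = LandscapeSpec(30, 30, 3, autocorr_range=3.0, seed=61)
    cur, futs = synthetic.simulate_landscape(spec, {"late": {"env1": 1.0}})
    tab = synthetic.simulate_samples(30, 5, cur, seed=62)
    truth = TruthTable.template(30, ["env1"], effect_size=2.5,
                                ancestral_K=3, target_fst=0.15)
    gm, t = synthetic.simulate_genotypes(tab, cur, 30, 30, truth=truth,
                                         seed=63)
    env = envlayers.extract_at_points(
        cur, gm.sample_meta[["lon", "lat"]].to_numpy())[cur.names]
    loc_xy = gm.sample_meta.groupby("locality", sort=True)[
        ["lon", "lat"]].first().to_numpy()
    sv = envlayers.pcnm(loc_xy)
    pops = gm.sample_meta.groupby("locality", sort=True).ngroup().to_numpy()
    pred = pd.concat([env.reset_index(drop=True),
                      pd.DataFrame(sv.vectors[pops], columns=sv.names)], axis=1)
    model = fit_gradient_forest(gm, pred, n_trees=150, seed=64)
    extra = pcnm_surfaces(sv.vectors, loc_xy, cur)
    return dict(model=model, current=cur, future=futs["late"], extra=extra,
                pred=pred, truth=t)


class TestFitGradientForest:
    def test_causal_variable_ranks_first(self, fitted):
        assert fitted["model"].importance.idxmax() == "env1"

    def test_causal_dominates_noncausal_env(self, fitted):
        imp = fitted["model"].importance
        others = [imp[v] for v in ("env2", "env3")]
        assert imp["env1"] >= 2 * max(max(others), 1e-12)

    def test_turnover_functions_monotone_from_zero(self, fitted):
        model = fitted["model"]
        for var in model.variables:
            knots, heights = model.functions[var]
            assert heights[0] == 0.0
            assert knots[0] == model.train_ranges[var][0]
            assert np.all(np.diff(heights) >= -1e-12)
            assert np.all(np.diff(knots) >= 0)

    def test_importances_nonnegative_r2_bounded(self, fitted):
        model = fitted["model"]
        assert (model.importance >= 0).all()
        assert (model.snp_r2.dropna() <= 1.0).all()

    def test_noise_snps_excluded(self):
        rng = np.random.default_rng(71)
        pred = pd.DataFrame(rng.normal(size=(120, 4)),
                            columns=["a", "b", "c", "d"])
        noise = rng.integers(0, 3, (120, 12)).astype(float)
        signal = rng.binomial(
            2, 1 / (1 + np.exp(-2.0 * pred["a"].to_numpy()))).astype(float)
        d = np.column_stack([noise, signal])
        model = fit_gradient_forest(d, pred, n_trees=100, seed=72)
        r2 = model.snp_r2.to_numpy()
        assert np.nanmean(r2[:12] <= 0.05) >= 0.75  # noise columns
        assert r2[12] > 0.2                          # planted column
        # excluded R2<=0 SNPs contribute nothing: total height stays finite
        assert model.importance.sum() > 0

    def test_all_noise_rejected(self):
        rng = np.random.default_rng(73)
        pred = pd.DataFrame(rng.normal(size=(60, 4)), columns=list("abcd"))
        d = rng.integers(0, 3, (60, 3)).astype(float)
        with pytest.raises(ValueError, match="R\\^2"):
            fit_gradient_forest(d, pred, n_trees=50, seed=74)

    def test_serialization_round_trip(self, fitted, tmp_path):
        model = fitted["model"]
        model.to_json(tmp_path / "m.json")
        back = TurnoverModel.from_json(tmp_path / "m.json")
        assert back.variables == model.variables
        for v in model.variables:
            np.testing.assert_allclose(back.functions[v][1],
                                       model.functions[v][1])

    def test_predictor_order_leaves_ranking(self, fitted):
        # feature subsampling depends on column order, so importances agree
        # in ranking (the causal variable stays on top), not bitwise
        rng = np.random.default_rng(75)
        pred = fitted["pred"]
        spec = LandscapeSpec(30, 30, 3, autocorr_range=3.0, seed=61)
        cur, _ = synthetic.simulate_landscape(spec)
        tab = synthetic.simulate_samples(30, 5, cur, seed=62)
        truth = TruthTable.template(30, ["env1"], effect_size=2.5,
                                    ancestral_K=3, target_fst=0.15)
        gm, _ = synthetic.simulate_genotypes(tab, cur, 30, 30, truth=truth,
                                             seed=63)
        reversed_pred = pred[list(pred.columns)[::-1]]
        model = fit_gradient_forest(gm, reversed_pred, n_trees=150, seed=64)
        assert model.importance.idxmax() == "env1"


class TestProjectTurnover:
    def test_constant_landscape_zero_scores(self, fitted):
        model = fitted["model"]
        grid = GridSpec(6, 6)
        layers = {v: np.zeros((6, 6)) for v in model.variables}
        stack = EnvStack(dict(list(layers.items())[:3]), grid)
        tg = project_turnover(model, stack,
                              extra_layers={k: v for k, v in layers.items()
                                            if k.startswith("pcnm")})
        assert np.allclose(tg.pcs, 0.0, atol=1e-12)
        rows = tg.transformed
        np.testing.assert_allclose(rows - rows[0][None, :],
                                   np.zeros_like(rows), atol=1e-12)

    def test_training_site_matches_model_transform(self, fitted):
        model = fitted["model"]
        pred = fitted["pred"]
        site_vec = model.transform(pred.iloc[[0]])
        np.testing.assert_allclose(
            site_vec[0],
            [model.evaluate(v, pred.iloc[0][v]) for v in model.variables],
            atol=1e-12)

    def test_transform_is_per_variable_evaluation(self, fitted):
        # additivity: the turnover-space vector is exactly the stack of
        # per-variable evaluations
        model = fitted["model"]
        rng = np.random.default_rng(81)
        table = pd.DataFrame({v: rng.uniform(-3, 3, 40)
                              for v in model.variables})
        got = model.transform(table)
        expected = np.column_stack([model.evaluate(v, table[v].to_numpy())
                                    for v in model.variables])
        np.testing.assert_array_equal(got, expected)

    def test_interpolation_matches_knot_scan_oracle(self, fitted):
        model = fitted["model"]
        var = "env1"
        knots, heights = model.functions[var]
        rng = np.random.default_rng(82)
        xs = rng.uniform(knots[0] - 1, knots[-1] + 1, 200)
        got = model.evaluate(var, xs)
        for x, g in zip(xs, got):
            if x <= knots[0]:
                expected = heights[0]
            elif x >= knots[-1]:
                expected = heights[-1]
            else:
                i = np.searchsorted(knots, x) - 1
                i = min(i, len(knots) - 2)
                if knots[i + 1] == knots[i]:
                    expected = heights[i + 1]
                else:
                    w = (x - knots[i]) / (knots[i + 1] - knots[i])
                    expected = heights[i] * (1 - w) + heights[i + 1] * w
            assert g == pytest.approx(expected, abs=1e-9)

    def test_missing_layer_named(self, fitted):
        model, cur = fitted["model"], fitted["current"]
        with pytest.raises(ValueError, match="pcnm"):
            project_turnover(model, cur)


class TestProcrustes:
    def _grid(self, pcs, mask=None):
        n = pcs.shape[0]
        side = int(np.ceil(np.sqrt(n)))
        m = np.zeros((side, side), bool)
        m.ravel()[:n] = True
        return TurnoverGrid(transformed=pcs.copy(), pcs=pcs,
                            explained_variance_ratio=np.ones(pcs.shape[1]),
                            mask=m, grid=GridSpec(side, side),
                            var_names=[f"v{i}" for i in range(pcs.shape[1])])

    def test_identity_zero_residuals(self):
        rng = np.random.default_rng(91)
        pcs = rng.normal(size=(40, 3))
        g = self._grid(pcs)
        resid = procrustes_residuals(g, self._grid(pcs.copy()))
        assert np.nanmax(resid) < 1e-10

    def test_rotation_scale_invariance(self):
        rng = np.random.default_rng(92)
        pcs = rng.normal(size=(50, 3))
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0],
                        [0, 0, 1.0]])
        other = 2.5 * pcs @ rot + np.array([3.0, -1.0, 0.5])
        resid = procrustes_residuals(self._grid(pcs), self._grid(other))
        assert np.nanmax(resid) < 1e-8

    def test_matches_closed_form_svd_oracle(self):
        rng = np.random.default_rng(93)
        x = rng.normal(size=(50, 3))
        y = rng.normal(size=(50, 3))
        resid = procrustes_residuals(self._grid(x), self._grid(y))
        expected = procrustes_closed_form(x, y)
        np.testing.assert_allclose(resid[self._grid(x).mask], expected,
                                   atol=1e-8)

    def test_mask_mismatch_rejected(self):
        rng = np.random.default_rng(94)
        a = self._grid(rng.normal(size=(40, 3)))
        b = self._grid(rng.normal(size=(40, 3)))
        b.mask = ~b.mask
        with pytest.raises(ValueError, match="mask"):
            procrustes_residuals(a, b)
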