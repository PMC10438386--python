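"""Genomic offset, cross-scenario scaling, and seed-source similarity."""

import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from landgea import envlayers, synthetic
from landgea.envlayers import EnvStack, GridSpec
from landgea.gradient import (TurnoverGrid, fit_gradient_forest,
                              project_turnover, pcnm_surfaces)
from landgea.offset import (ScenarioSpec, OffsetMap, genomic_offset,
                            scale_offsets, variable_contributions,
                            similarity_map, aggregate_offsets)
from landgea.synthetic import LandscapeSpec, TruthTable


def grid_of(transformed, side=None):
    n, p = transformed.shape
    side = side or int(np.ceil(np.sqrt(n)))
    mask = np.zeros((side, side), bool)
    mask.ravel()[:n] = True
    t = np.asarray(transformed, float)
    return TurnoverGrid(transformed=t, pcs=t.copy(),
                        explained_variance_ratio=np.ones(p), mask=mask,
                        grid=GridSpec(side, side),
                        var_names=[f"v{i}" for i in range(p)])


class TestScenarioSpec:
    def test_valid(self):
        s = ScenarioSpec("MIROC6", 370, "2081-2100")
        assert s.label == "MIROC6_ssp370_2081-2100"

    @pytest.mark.parametrize("kwargs", [
        dict(gcm="", ssp=370, period="2081-2100"),
        dict(gcm="MIROC6", ssp=999, period="2081-2100"),
        dict(gcm="MIROC6", ssp=370, period="2090-2110"),
    ])
    def test_invalid(self, kwargs):
        with pytest.raises(ValueError):
            ScenarioSpec(**kwargs)


class TestGenomicOffset:
    def test_zero_when_future_equals_current(self):
        rng = np.random.default_rng(1)
        t = rng.normal(size=(30, 4))
        om = genomic_offset(grid_of(t), grid_of(t.copy()))
        assert np.nanmax(om.raw) == 0.0

    def test_single_coordinate_difference(self):
        t = np.zeros((9, 3))
        f = t.copy()
        f[4, 1] = 0.7
        om = genomic_offset(grid_of(t), grid_of(f))
        vals = om.raw[om.mask]
        assert vals[4] == pytest.approx(0.7)
        assert np.delete(vals, 4).max() == 0.0

    def test_matches_brute_force_loop(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=(25, 5)), rng.normal(size=(25, 5))
        om = genomic_offset(grid_of(a), grid_of(b))
        vals = om.raw[om.mask]
        for i in range(25):
            expected = np.sqrt(sum((b[i, k] - a[i, k]) ** 2 for k in range(5)))
            assert vals[i] == pytest.approx(expected, abs=1e-10)

    def test_no_sqrt_variant(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=(10, 3)), rng.normal(size=(10, 3))
        om1 = genomic_offset(grid_of(a), grid_of(b), sqrt=True)
        om2 = genomic_offset(grid_of(a), grid_of(b), sqrt=False)
        np.testing.assert_allclose(om1.raw[om1.mask] ** 2, om2.raw[om2.mask])

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=15, deadline=None)
    def test_metric_properties(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c = rng.normal(size=(3, 12, 4))
        d_ab = genomic_offset(grid_of(a), grid_of(b)).raw
        d_ba = genomic_offset(grid_of(b), grid_of(a)).raw
        d_ac = genomic_offset(grid_of(a), grid_of(c)).raw
        d_cb = genomic_offset(grid_of(c), grid_of(b)).raw
        np.testing.assert_allclose(d_ab, d_ba, atol=1e-12)
        m = grid_of(a).mask
        assert np.all(d_ab[m] <= d_ac[m] + d_cb[m] + 1e-9)

    def test_linear_in_uniform_shift(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=(20, 4))
        delta = rng.normal(size=4)
        om1 = genomic_offset(grid_of(a), grid_of(a + delta))
        om3 = genomic_offset(grid_of(a), grid_of(a + 3.0 * delta))
        np.testing.assert_allclose(om3.raw[om3.mask], 3.0 * om1.raw[om1.mask],
                                   atol=1e-10)

    def test_predictor_mismatch_rejected(self):
        a = grid_of(np.zeros((9, 3)))
        b = grid_of(np.zeros((9, 4)))
        with pytest.raises(ValueError, match="predictor"):
            genomic_offset(a, b)


class TestScaleOffsets:
    def test_minmax_arithmetic(self):
        base = grid_of(np.zeros((3, 1)))
        maps = []
        for v in (2.0, 4.0, 6.0):
            raw = np.full(base.mask.shape, np.nan)
            raw[base.mask] = v
            maps.append(OffsetMap(raw=raw, scenario=None, mask=base.mask))
        scale_offsets(maps)
        got = sorted(float(np.nanmean(m.scaled)) for m in maps)
        assert got == [0.0, 0.5, 1.0]

    def test_degenerate_logged(self, caplog):
        base = grid_of(np.zeros((4, 1)))
        raw = np.where(base.mask, 1.0, np.nan)
        om = OffsetMap(raw=raw, scenario=None, mask=base.mask)
        with caplog.at_level(logging.WARNING):
            scale_offsets([om])
        assert "degenerate" in caplog.text
        assert np.nanmax(om.scaled) == 0.0

    def test_global_max_in_right_scenario(self):
        rng = np.random.default_rng(5)
        base = grid_of(np.zeros((16, 1)))
        maps = []
        for s in range(3):
            raw = np.full(base.mask.shape, np.nan)
            raw[base.mask] = rng.uniform(0, 1, 16)
            maps.append(OffsetMap(raw=raw, scenario=None, mask=base.mask))
        maps[1].raw[base.mask] = np.linspace(0, 5, 16)  # holds the pooled max
        scale_offsets(maps)
        assert np.nanmax(maps[1].scaled) == 1.0
        assert np.nanmax(maps[0].scaled) < 1.0
        assert np.nanmax(maps[2].scaled) < 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            scale_offsets([])


class TestVariableContributions:
    def test_single_changing_variable(self):
        rng = np.random.default_rng(6)
        a = rng.normal(size=(12, 3))
        b = a.copy()
        b[:, 2] += 1.0
        grids, means = variable_contributions(grid_of(a), grid_of(b))
        assert means["v2"] == pytest.approx(1.0)
        assert means["v0"] == pytest.approx(0.0)

    def test_contributions_sum_to_one(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(size=(15, 4)), rng.normal(size=(15, 4))
        grids, _ = variable_contributions(grid_of(a), grid_of(b))
        total = sum(g for g in grids.values())
        mask = grid_of(a).mask
        np.testing.assert_allclose(total[mask], 1.0, atol=1e-12)

    def test_matches_direct_recomputation(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(size=(10, 3)), rng.normal(size=(10, 3))
        grids, means = variable_contributions(grid_of(a), grid_of(b))
        d2 = (b - a) ** 2
        frac = d2 / d2.sum(axis=1, keepdims=True)
        mask = grid_of(a).mask
        for i, name in enumerate(["v0", "v1", "v2"]):
            np.testing.assert_allclose(grids[name][mask], frac[:, i],
                                       atol=1e-12)
        np.testing.assert_allclose(means.to_numpy(), frac.mean(axis=0),
                                   atol=1e-12)


@pytest.fixture(scope="module")
def small_fit():
    spec = LandscapeSpec(18, 18, 2, autocorr_range=3.0, seed=81)
    cur, futs = synthetic.simulate_landscape(spec, {"late": {"env1": 1.0}})
    tab = synthetic.simulate_samples(16, 6, cur, seed=82)
    truth = TruthTable.template(20, ["env1"], effect_size=2.5,
                                ancestral_K=3, target_fst=0.15)
    gm, _ = synthetic.simulate_genotypes(tab, cur, 20, 20, truth=truth,
                                         seed=83)
    env = envlayers.extract_at_points(
        cur, gm.sample_meta[["lon", "lat"]].to_numpy())[cur.names]
    loc_xy = gm.sample_meta.groupby("locality", sort=True)[
        ["lon", "lat"]].first().to_numpy()
    sv = envlayers.pcnm(loc_xy)
    pops = gm.sample_meta.groupby("locality", sort=True).ngroup().to_numpy()
    pred = pd.concat([env.reset_index(drop=True),
                      pd.DataFrame(sv.vectors[pops], columns=sv.names)], axis=1)
    model = fit_gradient_forest(gm, pred, n_trees=100, seed=84)
    extra = pcnm_surfaces(sv.vectors, loc_xy, cur)
    return dict(model=model, current=cur, future=futs["late"], extra=extra)


class TestSimilarityMap:
    def test_span_and_own_cell(self, small_fit):
        cur = small_fit["current"]
        site = (9.5, 9.5)
        sim = similarity_map(site, small_fit["model"], cur, cur,
                             extra_layers=small_fit["extra"])
        assert np.nanmin(sim) == 0.0
        assert np.nanmax(sim) == 1.0
        r, c = cur.grid.cell_index(np.array([site[0]]), np.array([site[1]]))
        assert sim[int(r[0]), int(c[0])] == 1.0

    def test_matches_brute_force(self, small_fit):
        model, cur, fut = (small_fit["model"], small_fit["current"],
                           small_fit["future"])
        extra = small_fit["extra"]
        site = (5.5, 12.5)
        sim = similarity_map(site, model, cur, fut, extra_layers=extra)
        tg_cur = project_turnover(model, cur, extra_layers=extra)
        tg_fut = project_turnover(model, fut, extra_layers=extra)
        r, c = cur.grid.cell_index(np.array([site[0]]), np.array([site[1]]))
        flat = np.flatnonzero(cur.mask.ravel())
        pos = int(np.searchsorted(flat, int(r[0]) * cur.grid.ncols + int(c[0])))
        site_vec = tg_fut.transformed[pos]
        dist = np.sqrt(((tg_cur.transformed - site_vec) ** 2).sum(axis=1))
        expected = 1 - (dist - dist.min()) / (dist.max() - dist.min())
        np.testing.assert_allclose(sim[cur.mask], expected, atol=1e-12)

    def test_site_outside_mask_rejected(self, small_fit):
        cur = small_fit["current"].copy()
        cur.mask[:] = True
        cur.mask[0, 0] = False
        y = cur.grid.nrows - 0.5
        with pytest.raises(ValueError, match="mask"):
            similarity_map((0.5, y), small_fit["model"], cur, cur,
                           extra_layers=small_fit["extra"])


class TestAggregate:
    def test_mean_over_gcms(self):
        base = grid_of(np.zeros((9, 1)))
        maps = []
        for gcm, v in (("MIROC6", 1.0), ("BCC-CSM2-MR", 3.0)):
            raw = np.where(base.mask, v, np.nan)
            maps.append(OffsetMap(raw=raw,
                                  scenario=ScenarioSpec(gcm, 370, "2081-2100"),
                                  mask=base.mask))
        agg = aggregate_offsets(maps)
        assert set(agg) == {(370, "2081-2100")}
        assert np.nanmean(agg[(370, "2081-2100")].raw) == pytest.approx(2.0)


def test_causal_shift_gives_larger_offset(small_fit):
    """Shifting the causal layer moves the adaptive model further than an
    equal shift of a non-causal layer (end-to-end sanity on planted truth)."""
    model, cur = small_fit["model"], small_fit["current"]
    extra = small_fit["extra"]
    tg_cur = project_turnover(model, cur, extra_layers=extra)
    shifted = {}
    for var in ("env1", "env2"):
        fut = cur.copy()
        fut.layers[var] = fut.layers[var] + 1.0
        tg = project_turnover(model, fut, extra_layers=extra)
        shifted[var] = float(np.nanmean(genomic_offset(tg_cur, tg).raw))
    assert shifted["env1"] > shifted["env2"]
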