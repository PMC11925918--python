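import numpy as np
import pytest

import heatrisk as hr
from heatrisk.camarkov import _window_sum
from heatrisk.risk_index import REFERENCE_BREAKS, RISK_LEVELS


def class_map(codes, mask=None):
    g = hr.Grid(np.asarray(codes, float), mask)
    return hr.RiskClassMap(g, REFERENCE_BREAKS)


# --------------------------------------------------------------------------
# estimate_transition
# --------------------------------------------------------------------------

def test_identity_for_identical_maps():
    rng = np.random.default_rng(0)
    m = class_map(rng.integers(0, 5, (20, 20)))
    model = hr.estimate_transition(m, m)
    np.testing.assert_allclose(model.P, np.eye(5))


def test_even_split_gives_half_half_row():
    a = np.zeros((2, 10))          # all class 0
    b = np.zeros((2, 10))
    b[:, 5:] = 1                   # half become class 1
    model = hr.estimate_transition(class_map(a), class_map(b))
    np.testing.assert_allclose(model.P[0], [0.5, 0.5, 0, 0, 0])


def test_absent_class_gets_identity_row():
    m1 = class_map(np.zeros((4, 4)))
    m2 = class_map(np.ones((4, 4)))
    model = hr.estimate_transition(m1, m2)
    np.testing.assert_allclose(model.P[3], np.eye(5)[3])


def test_recovers_generating_matrix():
    P = np.zeros((5, 5))
    P[:2, :2] = [[0.9, 0.1], [0.2, 0.8]]
    P[2:, 2:] = np.eye(3)
    rng = np.random.default_rng(1)
    init = hr.Grid(rng.integers(0, 2, (200, 200)).astype(float))
    step = hr.gen_markov_series(P, init, 1, seed=9, spatial_mixing=0.0)[0]
    model = hr.estimate_transition(
        hr.RiskClassMap(init, REFERENCE_BREAKS), hr.RiskClassMap(step, REFERENCE_BREAKS))
    assert np.abs(model.P[:2, :2] - P[:2, :2]).max() < 0.02


def test_estimation_error_shrinks_with_cell_count():
    P = np.zeros((5, 5))
    P[:3, :3] = [[0.8, 0.15, 0.05], [0.1, 0.8, 0.1], [0.05, 0.15, 0.8]]
    P[3:, 3:] = np.eye(2)
    errors = []
    for n in (50, 100, 200):
        errs = []
        for seed in range(3):
            rng = np.random.default_rng(1000 * n + seed)
            init = hr.Grid(rng.integers(0, 3, (n, n)).astype(float))
            step = hr.gen_markov_series(P, init, 1, seed=seed, spatial_mixing=0.0)[0]
            model = hr.estimate_transition(
                hr.RiskClassMap(init, REFERENCE_BREAKS),
                hr.RiskClassMap(step, REFERENCE_BREAKS))
            errs.append(np.abs(model.P[:3, :3] - P[:3, :3]).max())
        errors.append(np.mean(errs))
    assert errors[2] < errors[0]


# --------------------------------------------------------------------------
# project_markov
# --------------------------------------------------------------------------

def _model(P):
    return hr.TransitionModel(states=RISK_LEVELS, counts=np.ones((5, 5)), P=np.asarray(P))


def test_identity_projection_is_fixed_point():
    model = _model(np.eye(5))
    areas = np.array([10.0, 20, 30, 25, 15])
    np.testing.assert_allclose(hr.project_markov(areas, model, steps=7), areas)


def test_rank_one_chain_forgets_the_start():
    q = np.array([0.1, 0.2, 0.3, 0.25, 0.15])
    model = _model(np.tile(q, (5, 1)))
    out = hr.project_markov(np.array([100.0, 0, 0, 0, 0]), model)
    np.testing.assert_allclose(out, 100.0 * q)


def test_two_steps_equal_one_step_twice():
    rng = np.random.default_rng(2)
    P = rng.dirichlet(np.ones(5), size=5)
    model = _model(P)
    areas = rng.uniform(0, 100, 5)
    one_twice = hr.project_markov(hr.project_markov(areas, model), model)
    np.testing.assert_allclose(hr.project_markov(areas, model, steps=2), one_twice)


def test_total_area_conserved():
    rng = np.random.default_rng(3)
    model = _model(rng.dirichlet(np.ones(5), size=5))
    areas = rng.uniform(0, 50, 5)
    assert hr.project_markov(areas, model, 5).sum() == pytest.approx(areas.sum())


def test_negative_areas_rejected():
    with pytest.raises(ValueError, match="non-negative"):
        hr.project_markov(np.array([-1.0, 0, 0, 0, 1]), _model(np.eye(5)))


# --------------------------------------------------------------------------
# build_suitability
# --------------------------------------------------------------------------

def test_window_sum_matches_naive():
    rng = np.random.default_rng(4)
    arr = rng.random((11, 13))
    for size in (3, 5):
        out = _window_sum(arr, size)
        r = size // 2
        for i in range(arr.shape[0]):
            for j in range(arr.shape[1]):
                win = arr[max(0, i - r):i + r + 1, max(0, j - r):j + r + 1]
                assert out[i, j] == pytest.approx(win.sum())


def test_uniform_map_has_unit_suitability():
    atlas = hr.build_suitability(class_map(np.full((10, 10), 2.0)), 5)
    np.testing.assert_allclose(atlas.surfaces[2].values, 1.0)
    for k in (0, 1, 3, 4):
        np.testing.assert_allclose(atlas.surfaces[k].values, 0.0)


def test_isolated_cell_scores_one_twentyfifth():
    codes = np.ones((11, 11))
    codes[5, 5] = 3
    atlas = hr.build_suitability(class_map(codes), 5)
    assert atlas.surfaces[3].values[5, 5] == pytest.approx(1 / 25)


def test_suitability_partitions_to_one():
    rng = np.random.default_rng(5)
    mask = rng.random((12, 12)) < 0.15
    atlas = hr.build_suitability(class_map(rng.integers(0, 5, (12, 12)), mask), 5)
    total = sum(s.values for s in atlas.surfaces.values())
    valid_windows = ~mask  # any valid centre has at least itself in the window
    np.testing.assert_allclose(total[valid_windows], 1.0)


def test_even_filter_size_rejected():
    with pytest.raises(ValueError, match="odd"):
        hr.build_suitability(class_map(np.zeros((5, 5))), 4)


# --------------------------------------------------------------------------
# simulate / predict_pipeline
# --------------------------------------------------------------------------

def test_identity_demand_returns_base_exactly():
    rng = np.random.default_rng(6)
    base = class_map(rng.integers(0, 5, (30, 30)))
    out = hr.simulate(base, _model(np.eye(5)), hr.SimulationConfig(seed=1))
    np.testing.assert_array_equal(out.classes.values, base.classes.values)


def test_forced_total_conversion():
    base = class_map(np.ones(((20, 20))))
    P = np.eye(5)
    P[1] = [0, 0, 1, 0, 0]  # every low cell must become medium
    out = hr.simulate(base, _model(P), hr.SimulationConfig(iterations=1, seed=0))
    assert np.all(out.classes.values == 2)


def test_class_shares_match_markov_demand(small_region):
    # spatially structured base map from a smoothed field
    rng = np.random.default_rng(7)
    from scipy.ndimage import gaussian_filter
    field = gaussian_filter(rng.standard_normal((128, 128)), 5)
    codes = np.digitize(field, np.quantile(field, [0.2, 0.4, 0.6, 0.8]))
    base = class_map(codes)
    P = np.array([
        [0.85, 0.15, 0.0, 0.0, 0.0],
        [0.05, 0.8, 0.15, 0.0, 0.0],
        [0.0, 0.05, 0.8, 0.15, 0.0],
        [0.0, 0.0, 0.05, 0.8, 0.15],
        [0.0, 0.0, 0.0, 0.1, 0.9],
    ])
    model = _model(P)
    out = hr.simulate(base, model, hr.SimulationConfig(iterations=10, seed=3))
    total = base.classes.values.size
    demand = hr.project_markov(base.counts(), model)
    realised = out.counts()
    assert np.abs(realised - demand).max() <= 0.005 * total
    assert realised.sum() == total  # cell count conserved exactly


def test_simulation_is_deterministic():
    rng = np.random.default_rng(8)
    base = class_map(rng.integers(0, 5, (40, 40)))
    P = np.full((5, 5), 0.04) + np.eye(5) * 0.8
    cfg = hr.SimulationConfig(iterations=5, seed=11)
    a = hr.simulate(base, _model(P), cfg)
    b = hr.simulate(base, _model(P), cfg)
    np.testing.assert_array_equal(a.classes.values, b.classes.values)


def test_masked_cells_never_change():
    rng = np.random.default_rng(9)
    mask = rng.random((20, 20)) < 0.3
    codes = rng.integers(0, 5, (20, 20))
    base = class_map(codes, mask)
    P = np.full((5, 5), 0.2)
    out = hr.simulate(base, _model(P), hr.SimulationConfig(iterations=2, seed=0))
    np.testing.assert_array_equal(out.classes.values[mask], codes[mask].astype(float))


def test_allocation_is_spatially_coherent():
    """Simulated maps should score higher mean own-class suitability than a
    random allocation with identical class counts."""
    from scipy.ndimage import gaussian_filter
    wins = 0
    for seed in range(10):
        rng = np.random.default_rng(200 + seed)
        field = gaussian_filter(rng.standard_normal((64, 64)), 4)
        codes = np.digitize(field, np.quantile(field, [0.2, 0.4, 0.6, 0.8]))
        base = class_map(codes)
        P = np.eye(5) * 0.7 + 0.06 * (1 - np.eye(5)) * 1.25
        P /= P.sum(1, keepdims=True)
        out = hr.simulate(base, _model(P), hr.SimulationConfig(iterations=5, seed=seed))

        def mean_own_suit(cm):
            atlas = hr.build_suitability(cm, 5)
            codes = cm.classes.values.astype(int)
            suit = np.stack([atlas.surfaces[k].values for k in range(5)])
            return suit[codes, *np.indices(codes.shape)].mean()

        shuffled_codes = out.classes.values.copy().ravel()
        rng.shuffle(shuffled_codes)
        shuffled = class_map(shuffled_codes.reshape(out.classes.shape))
        if mean_own_suit(out) > mean_own_suit(shuffled):
            wins += 1
    assert wins == 10


def test_predict_pipeline_identical_maps_returns_second_map():
    rng = np.random.default_rng(10)
    m = class_map(rng.integers(0, 5, (25, 25)))
    pred = hr.predict_pipeline(m, m, hr.SimulationConfig(seed=2))
    np.testing.assert_array_equal(pred.classes.values, m.classes.values)


def test_hindcast_beats_shuffled_baseline():
    """On a stationary synthetic series the CA-Markov hindcast should agree
    with the true third date far better than a shuffled map does."""
    P = np.eye(5) * 0.8
    P += 0.2 * np.eye(5, k=1)
    P[4, 4] = 1.0
    wins = 0
    for seed in range(10):
        rng = np.random.default_rng(300 + seed)
        from scipy.ndimage import gaussian_filter
        field = gaussian_filter(rng.standard_normal((64, 64)), 4)
        codes = np.digitize(field, np.quantile(field, [0.2, 0.4, 0.6, 0.8]))
        init = hr.Grid(codes.astype(float))
        series = hr.gen_markov_series(P, init, 2, seed=seed, spatial_mixing=0.3)
        m0 = hr.RiskClassMap(init, REFERENCE_BREAKS)
        m1 = hr.RiskClassMap(series[0], REFERENCE_BREAKS)
        m2 = hr.RiskClassMap(series[1], REFERENCE_BREAKS)
        pred = hr.predict_pipeline(m0, m1, hr.SimulationConfig(iterations=5, seed=seed))
        k_model = hr.kappa(pred, m2).kappa
        shuffled_codes = pred.classes.values.copy().ravel()
        rng.shuffle(shuffled_codes)
        shuffled = hr.RiskClassMap(hr.Grid(shuffled_codes.reshape(pred.classes.shape)),
                                   REFERENCE_BREAKS)
        k_null = hr.kappa(shuffled, m2).kappa
        if k_model > k_null:
            wins += 1
    assert wins >= 9


def test_infeasible_base_fails():
    base = class_map(np.zeros((3, 3)), np.ones((3, 3), bool))
    with pytest.raises(ValueError, match="unmasked"):
        hr.simulate(base, _model(np.eye(5)), hr.SimulationConfig(seed=0))
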