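"""The synthetic study-system generator: determinism, geometry, and targets."""

import numpy as np
import pandas as pd
import pytest

from riskscape.landscape import merge_classes
from riskscape.simulate import (
    SimulationConfig,
    flying_config,
    generate_cone_series,
    generate_landscape,
    place_predator_nests,
    place_sites,
    simulate_dataset,
    simulate_occupancy,
)
from conftest import small_flying_config


def _rng(seed=0):
    return np.random.default_rng(seed)


def test_class_mix_must_sum_to_one():
    with pytest.raises(ValueError, match="sum"):
        SimulationConfig(class_mix={"Mo spruce": 0.5, "Field": 0.4})


def test_single_class_mix_gives_uniform_grid():
    cfg = small_flying_config(class_mix={"Mo spruce": 1.0})
    grid = generate_landscape(cfg, _rng(1))
    assert np.unique(grid.cells).tolist() == [11]  # raw code for mature spruce


def test_landscape_proportions_within_three_points():
    cfg = small_flying_config(extent_m=10_000.0, cell_size_m=50.0)
    grid = generate_landscape(cfg, _rng(2))
    merged = merge_classes(grid)
    counts = pd.Series(merged.cells.ravel()).value_counts(normalize=True)
    for code, label in merged.labels.items():
        target = cfg.class_mix.get(label, 0.0)
        got = counts.get(code, 0.0)
        assert abs(got - target) <= 0.03, (label, got, target)


def test_landscape_deterministic_under_seed():
    cfg = small_flying_config()
    g1 = generate_landscape(cfg, _rng(3))
    g2 = generate_landscape(cfg, _rng(3))
    np.testing.assert_array_equal(g1.cells, g2.cells)


def _join_count(grid) -> float:
    """Fraction of horizontally adjacent cell pairs sharing a class."""
    same = grid.cells[:, 1:] == grid.cells[:, :-1]
    return float(same.mean())


def test_clustering_range_increases_spatial_cohesion():
    rough = generate_landscape(
        small_flying_config(extent_m=6_000.0, n_sites=5, clustering_range_m=0.0),
        _rng(4))
    smooth = generate_landscape(
        small_flying_config(extent_m=6_000.0, n_sites=5, clustering_range_m=1_000.0),
        _rng(4))
    assert _join_count(smooth) > _join_count(rough)


def test_sites_respect_spacing_and_box_distance():
    cfg = small_flying_config()
    grid = generate_landscape(cfg, _rng(5))
    boxes = place_sites(cfg, grid, _rng(6))
    centers = boxes.groupby("site_id")[["x", "y"]].first().to_numpy()
    from scipy.spatial.distance import pdist

    assert pdist(centers).min() >= cfg.min_site_spacing_m
    for _, grp in boxes.groupby("site_id"):
        assert len(grp) == 2
        xy = grp[["x", "y"]].to_numpy()
        d = np.hypot(*(xy[0] - xy[1]))
        assert 80.0 <= d <= 100.0


def test_single_site_trivially_valid():
    cfg = small_flying_config(n_sites=1)
    grid = generate_landscape(cfg, _rng(7))
    boxes = place_sites(cfg, grid, _rng(8))
    assert boxes["site_id"].nunique() == 1


def test_infeasible_packing_raises():
    cfg = small_flying_config(n_sites=5)
    grid = generate_landscape(cfg, _rng(9))
    cfg.n_sites = 4000  # bypass the constructor's feasibility check
    with pytest.raises(RuntimeError, match="could not place"):
        place_sites(cfg, grid, _rng(10))


def test_predator_poisson_mean():
    """Year-1 nest count is Poisson(density x area): Monte-Carlo mean check."""
    cfg = small_flying_config(extent_m=10_000.0, cell_size_m=100.0,
                              predator_density={"ural_owl": 2.0})
    grid = generate_landscape(cfg, _rng(11))
    counts = []
    for s in range(200):
        nests = place_predator_nests(cfg, grid, _rng(100 + s))
        counts.append((nests["year"] == cfg.years[0] - 1).sum())
    # 2 pairs / 10 km^2 on 100 km^2: expectation 20
    assert np.mean(counts) == pytest.approx(20.0, abs=1.0)


def test_persistence_extremes():
    cfg = small_flying_config(years=(2002, 2003, 2004))
    grid = generate_landscape(cfg, _rng(12))
    static = place_predator_nests(
        small_flying_config(years=(2002, 2003, 2004), territory_persistence=1.0),
        grid, _rng(13))
    per_year = {y: set(map(tuple, g[["x", "y"]].to_numpy()))
                for y, g in static[static.species == "ural_owl"].groupby("year")}
    sets = list(per_year.values())
    assert all(s == sets[0] for s in sets)

    moving = place_predator_nests(
        small_flying_config(years=(2002, 2003, 2004), territory_persistence=0.0),
        grid, _rng(13))
    per_year = {y: set(map(tuple, g[["x", "y"]].to_numpy()))
                for y, g in moving[moving.species == "ural_owl"].groupby("year")}
    sets = list(per_year.values())
    assert all(len(sets[0] & s) == 0 for s in sets[1:])


def test_cone_series_covers_lag_year():
    cfg = small_flying_config()
    cone = generate_cone_series(cfg, _rng(14))
    assert cone["year"].min() == cfg.years[0] - 1
    assert (cone["crop"] > 0).all()


def _fake_boxes_and_covariates(n_sites, years):
    boxes = pd.DataFrame({
        "box_id": [f"b{i}" for i in range(n_sites)],
        "site_id": [f"s{i}" for i in range(n_sites)],
        "x": np.arange(n_sites, dtype=float), "y": 0.0,
    })
    cov = boxes[["box_id"]].merge(pd.DataFrame({"year": years}), how="cross")
    cov["risk"] = np.random.default_rng(0).uniform(0, 1, len(cov))
    return boxes, cov


def test_occupancy_rate_closed_forms():
    years = list(range(2000, 2010))
    boxes, cov = _fake_boxes_and_covariates(300, years)
    cfg = flying_config(beta={"Intercept": 0.0}, sigma_site=0.0, sigma_box=0.0)
    occ, truth = simulate_occupancy(cfg, boxes, cov, _rng(15))
    assert occ["occupied"].mean() == pytest.approx(0.5, abs=0.02)

    boxes, cov = _fake_boxes_and_covariates(600, years)
    cfg = flying_config(beta={"Intercept": -4.0}, sigma_site=0.0, sigma_box=0.0)
    occ, _ = simulate_occupancy(cfg, boxes, cov, _rng(16))
    assert occ["occupied"].mean() == pytest.approx(1 / (1 + np.exp(4.0)), abs=0.01)


def test_unknown_beta_term_errors():
    boxes, cov = _fake_boxes_and_covariates(10, [2000])
    cfg = flying_config(beta={"Intercept": 0.0, "ghost": 1.0})
    with pytest.raises(ValueError, match="ghost"):
        simulate_occupancy(cfg, boxes, cov, _rng(17))


def test_full_chain_deterministic_and_truth_sufficient():
    cfg = small_flying_config(n_sites=10, years=(2002, 2003))
    a = simulate_dataset(cfg)
    b = simulate_dataset(cfg)
    pd.testing.assert_frame_equal(a.boxes, b.boxes)
    pd.testing.assert_frame_equal(a.occupancy, b.occupancy)
    pd.testing.assert_frame_equal(a.visits, b.visits)
    np.testing.assert_array_equal(a.grid.cells, b.grid.cells)
    # the recorded truth reproduces every outcome probability
    from scipy.special import expit

    p = expit(a.truth.linear_predictor)
    assert len(p) == len(a.occupancy)
    assert ((p > 0) & (p < 1)).all()


def test_visits_reduce_back_to_occupancy():
    """First-visit cleaning of the generated visit table recovers the
    simulated outcomes (minus the deliberately late-visited box-years)."""
    from riskscape.occupancy import first_visit_filter

    cfg = small_flying_config(n_sites=15, years=(2002, 2003, 2004))
    res = simulate_dataset(cfg)
    cleaned = first_visit_filter(res.visits)
    merged = cleaned.merge(res.occupancy, on=["box_id", "year"],
                           suffixes=("_clean", "_true"))
    assert (merged["occupied_clean"] == merged["occupied_true"]).all()
    dropped = len(res.occupancy) - len(cleaned)
    assert 0 <= dropped <= 0.1 * len(res.occupancy)
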