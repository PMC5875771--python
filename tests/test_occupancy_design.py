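"""Visit cleaning, standardisation, design construction and VIF screening."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from riskscape.design import (
    ModelSpec,
    add_quadratic,
    build_design,
    compute_vif,
    standardize,
    vif_screen,
)
from riskscape.occupancy import attach_time_period, first_visit_filter


# ---------------------------------------------------------------------------
# First-visit cleaning


def test_first_visit_rule_keeps_earliest(toy_visits):
    out = first_visit_filter(toy_visits)
    a2010 = out[(out.box_id == "A") & (out.year == 2010)]
    assert a2010["occupied"].item() == 0  # April visit, not the May one


def test_july_only_box_dropped(toy_visits):
    out = first_visit_filter(toy_visits)
    assert "B" not in set(out.box_id)


def test_toy_table_surviving_records(toy_visits):
    out = first_visit_filter(toy_visits)
    assert len(out) == 3
    assert set(zip(out.box_id, out.year)) == {("A", 2010), ("A", 2011), ("C", 2010)}


def test_unparseable_date_reports_row_index(toy_visits):
    bad = toy_visits.copy()
    bad.loc[3, "date"] = "not-a-date"
    with pytest.raises(ValueError, match="row index 3"):
        first_visit_filter(bad)


def test_time_period_split():
    rec = pd.DataFrame({"box_id": ["a", "a"], "year": [2005, 2006], "occupied": [0, 1]})
    out = attach_time_period(rec)
    assert out["time_period"].tolist() == [1, 2]


# ---------------------------------------------------------------------------
# Standardisation and quadratics


def test_standardize_symmetric_triple():
    z, mean, sd = standardize([1.0, 2.0, 3.0])
    np.testing.assert_allclose(z, [-1.0, 0.0, 1.0])
    assert (mean, sd) == (2.0, 1.0)


def test_standardize_constant_errors():
    with pytest.raises(ValueError):
        standardize([4.0, 4.0, 4.0])


@given(st.lists(st.floats(-1e4, 1e4), min_size=3, max_size=60, unique=True))
@settings(max_examples=100, deadline=None)
def test_standardize_definition(values):
    from hypothesis import assume

    assume(np.ptp(values) > 1e-3)
    z, _, _ = standardize(values)
    assert abs(z.mean()) < 1e-8
    assert abs(z.std(ddof=1) - 1.0) < 1e-8


def test_add_quadratic_values_and_missing_term():
    X = pd.DataFrame({"f": [-1.0, 0.0, 2.0]})
    out = add_quadratic(X, "f")
    np.testing.assert_allclose(out["f^2"], [1.0, 0.0, 4.0])
    with pytest.raises(ValueError):
        add_quadratic(X, "missing")


def test_add_quadratic_degenerate_warns(caplog):
    X = pd.DataFrame({"f": [-1.0, 1.0, -1.0, 1.0]})
    with caplog.at_level("WARNING"):
        out = add_quadratic(X, "f")
    assert np.all(out["f^2"] == 1.0)
    assert any("constant" in r.message for r in caplog.records)


# ---------------------------------------------------------------------------
# VIF


def _correlated_pair(rho, n=400, seed=5):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    y = rho * x + np.sqrt(1 - rho**2) * rng.normal(size=n)
    return pd.DataFrame({"x": x, "y": y})


def test_vif_orthogonal_is_one():
    df = pd.DataFrame({"x": [1.0, -1.0, 1.0, -1.0], "y": [1.0, 1.0, -1.0, -1.0]})
    report = compute_vif(df, ["x", "y"])
    assert report.vif["x"] == pytest.approx(1.0)
    assert report.vif["y"] == pytest.approx(1.0)


def test_vif_matches_direct_least_squares_oracle():
    df = _correlated_pair(0.8)
    # independent oracle: R^2 of x ~ y by explicit least squares
    A = np.column_stack([np.ones(len(df)), df["y"]])
    coef, *_ = np.linalg.lstsq(A, df["x"].to_numpy(), rcond=None)
    resid = df["x"] - A @ coef
    r2 = 1 - (resid @ resid) / ((df["x"] - df["x"].mean()) ** 2).sum()
    report = compute_vif(df, ["x", "y"])
    assert report.vif["x"] == pytest.approx(1.0 / (1.0 - r2), abs=1e-6)


def test_vif_perfect_collinearity_is_infinite():
    df = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0]})
    df["y"] = df["x"]
    report = compute_vif(df, ["x", "y"])
    assert np.isinf(report.vif["x"])


def test_vif_screen_drops_near_sum_variable_first():
    rng = np.random.default_rng(8)
    a = rng.normal(size=300)
    b = rng.normal(size=300)
    df = pd.DataFrame({"a": a, "b": b, "c": a + b + rng.normal(0, 0.05, 300)})
    report = vif_screen(df, ["a", "b", "c"], threshold=5.0)
    assert report.dropped == ["c"]
    assert all(v < 5.0 for v in report.vif.values())


def test_vif_screen_noop_when_below_threshold():
    df = _correlated_pair(0.3)
    report = vif_screen(df, ["x", "y"], threshold=5.0)
    assert report.dropped == []


def test_vif_screen_infeasible_threshold_errors():
    df = _correlated_pair(0.8)
    with pytest.raises(ValueError, match="cannot reach"):
        vif_screen(df, ["x", "y"], threshold=1.0000001)


def test_vif_screen_exempt_never_dropped():
    rng = np.random.default_rng(9)
    a = rng.normal(size=200)
    df = pd.DataFrame({
        "year": a,
        "h1": a + rng.normal(0, 0.05, 200),  # collinear with the exempt term
        "h2": rng.normal(size=200),
    })
    report = vif_screen(df, ["year", "h1", "h2"], threshold=1.5, exempt=["year"])
    assert report.dropped == ["h1"]
    assert "year" in report.vif


# ---------------------------------------------------------------------------
# Design building


def _table(n=40, seed=2):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "occupied": rng.integers(0, 2, n),
            "year": rng.integers(2000, 2010, n),
            "Field": rng.uniform(0, 10, n),
            "risk": rng.uniform(0, 3, n),
            "site_id": rng.integers(0, 8, n),
            "box_id": np.arange(n),
        }
    )


def test_build_design_standardises_and_squares():
    spec = ModelSpec(mandatory=["year"], habitat=["Field"], risk=["risk"],
                     quadratic=["Field"], random="site_box")
    d = build_design(_table(), spec)
    for col in ("year", "Field", "risk"):
        assert abs(d.X[col].mean()) < 1e-8
        assert abs(d.X[col].std(ddof=1) - 1) < 1e-8
    np.testing.assert_allclose(d.X["Field^2"], d.X["Field"] ** 2)
    assert list(d.X.columns)[0] == "Intercept"


def test_build_design_constant_covariate_errors():
    t = _table()
    t["Field"] = 3.0
    spec = ModelSpec(mandatory=["year"], habitat=["Field"], random="site")
    with pytest.raises(ValueError, match="Field"):
        build_design(t, spec)


def test_build_design_constant_interaction_is_rank_deficiency_error():
    t = _table()
    # parents whose standardised product is constant (no usable overlap
    # variation between the risk and habitat columns)
    t["risk"] = np.tile([1.0, -1.0], len(t) // 2)
    t["h"] = t["risk"]
    spec = ModelSpec(mandatory=["year"], habitat=["h"], risk=["risk"],
                     interactions=[("risk", "h")], random="site")
    with pytest.raises(ValueError, match="rank-deficient"):
        build_design(t, spec)


def test_spec_validates_quadratic_parent():
    with pytest.raises(ValueError):
        ModelSpec(mandatory=["year"], quadratic=["ghost"])
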