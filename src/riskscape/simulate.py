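"""Synthetic study-system generator.

Emulates the statistical structure of the boreal nest-box study design so the
whole pipeline is testable without field data: a spatially clustered
categorical land-use mosaic (Gaussian-random-field argmax with class-share
calibration), nest-box sites placed by hard-core inhibition in forest (two
boxes 80-100 m apart per site for the flying-squirrel program, one for the
red-squirrel program, sites >= 0.8 km apart), predator territories drawn as
a Poisson process over forest with year-to-year persistence, a yearly spruce
cone-crop index with occasional mast years, and occupancy outcomes from a
logistic model with site- and box-level Gaussian random intercepts and
user-set true coefficients on standardised covariates.

Random streams are split per component from the master seed, so changing one
component's parameters leaves the other components' draws untouched.  All
outputs are byte-identical under a fixed seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dc_field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .kernel import KernelParams, risk_covariate
from .landscape import (
    ClassTable,
    LandUseGrid,
    MERGED_CLASSES,
    compositions_for_boxes,
    default_class_table,
    merge_classes,
    write_grid,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "SimulationResult",
    "flying_config",
    "red_config",
    "generate_landscape",
    "place_sites",
    "place_predator_nests",
    "generate_cone_series",
    "simulate_occupancy",
    "simulate_dataset",
    "write_dataset",
]

#: Classes treated as forest for site and predator-nest placement.
FOREST_CLASSES = [
    "Y birch", "Y pine", "Y mix",
    "Mo birch", "Mo pine", "Mo spruce",
    "Mo birch pine", "Mo pine spruce", "Mo birch spruce",
]

_DEFAULT_MIX = {
    "Clear cut": 0.06, "Y birch": 0.05, "Y pine": 0.08, "Y mix": 0.08,
    "Mo birch": 0.04, "Mo pine": 0.12, "Mo spruce": 0.12, "Mo birch pine": 0.05,
    "Mo pine spruce": 0.08, "Mo birch spruce": 0.05, "Built": 0.03,
    "Bog": 0.09, "Field": 0.15,
}


@dataclass
class SimulationConfig:
    """All generator truths; defaults follow the emulated study design."""

    species: str = "flying"
    seed: int = 0
    extent_m: float = 20_000.0
    cell_size_m: float = 25.0
    class_mix: dict = dc_field(default_factory=lambda: dict(_DEFAULT_MIX))
    clustering_range_m: float = 300.0
    n_sites: int = 200
    boxes_per_site: int = 2
    box_spacing_m: tuple[float, float] = (80.0, 100.0)
    min_site_spacing_m: float = 800.0
    years: tuple[int, ...] = tuple(range(2002, 2016))
    radius_small_m: float = 200.0
    radius_large_m: float = 1000.0
    predator_density: dict = dc_field(
        default_factory=lambda: {"ural_owl": 2.0, "goshawk": 1.0}
    )  # pairs per 10 km^2
    territory_persistence: float = 0.8
    kernel_truth: KernelParams = dc_field(
        default_factory=lambda: KernelParams(sd_m=3000.0, flat_top_m=2500.0)
    )
    kernel_lag: int = 1
    kernel_species: str = "ural_owl"
    aggregation: str = "sum"
    beta: dict = dc_field(
        default_factory=lambda: {
            "Intercept": -0.09, "year": 0.26, "ural_owl": -2.4,
            "Field": 0.71, "Field^2": -0.23,
        }
    )
    sigma_site: float = 1.0
    sigma_box: float = 0.5
    cone_log_sd: float = 0.5
    cone_mast_prob: float = 0.25
    cone_mast_factor: float = 4.0
    visit_duplicate_prob: float = 0.3
    visit_late_prob: float = 0.02

    def __post_init__(self) -> None:
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"class_mix proportions sum to {total}, expected 1")
        margin = self.margin_m
        interior = self.extent_m - 2.0 * margin
        if interior <= 0:
            raise ValueError("extent too small for the buffer margin")
        # generous feasibility check for hard-core packing
        cap = 0.5 * interior**2 / (np.pi * (self.min_site_spacing_m / 2.0) ** 2)
        if self.n_sites > cap:
            raise ValueError(
                f"cannot place {self.n_sites} sites with {self.min_site_spacing_m} m "
                f"spacing inside a {interior / 1000:.1f} km interior"
            )

    @property
    def margin_m(self) -> float:
        """Edge margin so no study buffer is truncated by the grid boundary."""
        return max(self.radius_small_m, self.radius_large_m) + self.box_spacing_m[1]


def flying_config(**overrides) -> SimulationConfig:
    """Flying-squirrel study preset (nested box-in-site design, Ural-owl risk)."""
    return SimulationConfig(**overrides)


def red_config(**overrides) -> SimulationConfig:
    """Red-squirrel study preset: one box per site, goshawk risk at the
    current year, monitoring-period factor, and cone-crop effects."""
    defaults = dict(
        species="red",
        extent_m=26_000.0,
        n_sites=200,
        boxes_per_site=1,
        years=tuple(range(1999, 2016)),
        radius_small_m=300.0,
        radius_large_m=2500.0,
        kernel_truth=KernelParams(sd_m=1000.0, flat_top_m=500.0),
        kernel_lag=0,
        kernel_species="goshawk",
        beta={
            "Intercept": -2.27, "year": -0.16, "time_period_2": 1.33,
            "goshawk": -0.22, "Field": 0.36, "Field^2": -0.08, "Built": 0.11,
            "cone": 0.17, "cone:Mo spruce": 0.08,
        },
        sigma_box=0.0,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@dataclass
class SimulationTruth:
    """Everything needed to recompute each simulated outcome probability."""

    covariates: pd.DataFrame  # standardised columns actually used in eta
    linear_predictor: np.ndarray
    ranef_site: dict
    ranef_box: dict
    beta: dict


@dataclass
class SimulationResult:
    config: SimulationConfig
    grid: LandUseGrid  # raw land-use codes
    class_table: ClassTable
    boxes: pd.DataFrame
    nests: pd.DataFrame
    cone: pd.DataFrame
    covariates: pd.DataFrame  # raw-scale box-year covariates
    occupancy: pd.DataFrame
    visits: pd.DataFrame
    truth: SimulationTruth


# ---------------------------------------------------------------------------
# Landscape


def _representative_raw_codes(table: ClassTable) -> dict[str, int]:
    rep: dict[str, int] = {}
    for code, label in table.mapping.items():
        rep.setdefault(label, code)
    return rep


def generate_landscape(
    config: SimulationConfig, rng: np.random.Generator
) -> LandUseGrid:
    """Spatially clustered categorical raster matching the target class mix.

    One smoothed Gaussian random field per class; each cell takes the class
    with the largest field value plus a per-class offset, initialised at the
    log target share and calibrated iteratively so empirical proportions land
    within a few tenths of a percentage point of the target.  Cells carry raw
    land-use codes (one representative code per merged class) so the merging
    step of the analysis is exercised.
    """
    labels = list(config.class_mix)
    target = np.array([config.class_mix[c] for c in labels], dtype=float)
    n = int(round(config.extent_m / config.cell_size_m))
    if len(labels) == 1:
        cells = np.zeros((n, n), dtype=np.int64)
    else:
        sigma = config.clustering_range_m / config.cell_size_m
        fields = np.empty((len(labels), n, n), dtype=np.float32)
        for k in range(len(labels)):
            f = rng.standard_normal((n, n))
            if sigma > 0:
                f = gaussian_filter(f, sigma=sigma, mode="wrap")
            f = (f - f.mean()) / (f.std() + 1e-12)
            fields[k] = f
        offsets = np.log(np.maximum(target, 1e-12))
        cells = None
        for _ in range(60):
            cells = np.argmax(fields + offsets[:, None, None], axis=0)
            counts = np.bincount(cells.ravel(), minlength=len(labels))
            observed = counts / counts.sum()
            err = np.abs(observed - target).max()
            if err < 1e-3:
                break
            offsets += 0.8 * (np.log(np.maximum(target, 1e-12))
                              - np.log(np.maximum(observed, 1e-12)))
    rep = _representative_raw_codes(default_class_table())
    code_lut = np.array([rep[lab] for lab in labels], dtype=np.int64)
    return LandUseGrid(
        origin_x=0.0,
        origin_y=0.0,
        cell_size=config.cell_size_m,
        cells=code_lut[cells],
        nodata_code=-9999,
    )


# ---------------------------------------------------------------------------
# Point processes


def _forest_mask(grid: LandUseGrid) -> np.ndarray:
    merged = merge_classes(grid, default_class_table())
    forest_codes = [
        code for code, lab in merged.labels.items() if lab in FOREST_CLASSES
    ]
    return np.isin(merged.cells, forest_codes)


def place_sites(
    config: SimulationConfig, grid: LandUseGrid, rng: np.random.Generator
) -> pd.DataFrame:
    """Hard-core site placement in forest, with within-site box pairs.

    Site centers keep at least ``min_site_spacing_m`` from each other and sit
    on forest cells inside the buffer margin; the second box of a pair is
    placed at a uniform random bearing, 80-100 m away.
    """
    mask = _forest_mask(grid)
    margin = config.margin_m
    lo, hi = margin, config.extent_m - margin
    sites_x: list[float] = []
    sites_y: list[float] = []
    max_tries = max(20_000, config.n_sites * 2_000)
    stall_limit = 20_000  # give up after this many rejections in a row
    tries = 0
    stalled = 0
    while len(sites_x) < config.n_sites and tries < max_tries and stalled < stall_limit:
        tries += 1
        stalled += 1
        x = rng.uniform(lo, hi)
        y = rng.uniform(lo, hi)
        col = int(x / grid.cell_size)
        row = grid.n_rows - 1 - int(y / grid.cell_size)
        if not mask[row, col]:
            continue
        if sites_x:
            d2 = (np.array(sites_x) - x) ** 2 + (np.array(sites_y) - y) ** 2
            if d2.min() < config.min_site_spacing_m**2:
                continue
        sites_x.append(x)
        sites_y.append(y)
        stalled = 0
    if len(sites_x) < config.n_sites:
        raise RuntimeError(
            f"could not place {config.n_sites} sites (max achieved "
            f"{len(sites_x)} after {tries} tries)"
        )
    rows = []
    for i, (x, y) in enumerate(zip(sites_x, sites_y)):
        site_id = f"S{i:04d}"
        rows.append({"box_id": f"{site_id}B1", "site_id": site_id,
                     "species_program": config.species, "x": x, "y": y})
        if config.boxes_per_site == 2:
            bearing = rng.uniform(0.0, 2.0 * np.pi)
            dist = rng.uniform(*config.box_spacing_m)
            rows.append({
                "box_id": f"{site_id}B2", "site_id": site_id,
                "species_program": config.species,
                "x": x + dist * np.cos(bearing), "y": y + dist * np.sin(bearing),
            })
    boxes = pd.DataFrame(rows)
    _assert_geometry(boxes, config)
    return boxes


def _assert_geometry(boxes: pd.DataFrame, config: SimulationConfig) -> None:
    centers = boxes.groupby("site_id")[["x", "y"]].first().to_numpy()
    if len(centers) > 1:
        from scipy.spatial.distance import pdist

        if pdist(centers).min() < config.min_site_spacing_m - 1e-6:
            raise AssertionError("site spacing constraint violated")
    if config.boxes_per_site == 2:
        for _, grp in boxes.groupby("site_id"):
            xy = grp[["x", "y"]].to_numpy()
            d = np.hypot(*(xy[0] - xy[1]))
            lo, hi = config.box_spacing_m
            if not (lo - 1e-6 <= d <= hi + 1e-6):
                raise AssertionError("box spacing constraint violated")


def place_predator_nests(
    config: SimulationConfig, grid: LandUseGrid, rng: np.random.Generator
) -> pd.DataFrame:
    """Predator nests per species and year: Poisson in forest, persistent.

    Year 1 (the year before the first analysis year, so lag-1 covariates are
    defined) draws Poisson(density x area) nests on forest cells; each
    subsequent year every nest keeps its location with probability
    ``territory_persistence`` and otherwise relocates.
    """
    mask = _forest_mask(grid)
    forest_idx = np.flatnonzero(mask.ravel())
    n_cols = grid.n_cols
    area_10km2 = config.extent_m**2 / 1e7

    def draw_points(k: int) -> np.ndarray:
        flat = rng.choice(forest_idx, size=k, replace=True)
        row, col = np.divmod(flat, n_cols)
        x = (col + rng.uniform(0, 1, k)) * grid.cell_size
        y = (grid.n_rows - row - rng.uniform(0, 1, k)) * grid.cell_size
        return np.column_stack([x, y])

    years = [config.years[0] - 1] + list(config.years)
    rows = []
    for species, density in config.predator_density.items():
        count = int(rng.poisson(density * area_10km2))
        xy = draw_points(max(count, 0))
        for year in years:
            if year > years[0] and len(xy):
                move = rng.uniform(size=len(xy)) > config.territory_persistence
                if move.any():
                    xy = xy.copy()
                    xy[move] = draw_points(int(move.sum()))
            for x, y in xy:
                rows.append({"species": species, "year": year, "x": x, "y": y})
    return pd.DataFrame(rows, columns=["species", "year", "x", "y"])


def generate_cone_series(
    config: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Yearly spruce cone index: i.i.d. log-normal with occasional mast years."""
    years = [config.years[0] - 1] + list(config.years)
    crop = np.exp(rng.normal(0.0, config.cone_log_sd, len(years)))
    mast = rng.uniform(size=len(years)) < config.cone_mast_prob
    crop[mast] *= config.cone_mast_factor
    return pd.DataFrame({"year": years, "crop": crop})


# ---------------------------------------------------------------------------
# Outcomes


def _standardized_term(cov: pd.DataFrame, term: str, cache: dict) -> np.ndarray:
    if term in cache:
        return cache[term]
    if term.endswith("^2"):
        z = _standardized_term(cov, term[:-2], cache) ** 2
    elif ":" in term:
        a, b = term.split(":", 1)
        z = _standardized_term(cov, a, cache) * _standardized_term(cov, b, cache)
    elif term == "time_period_2":
        z = (cov["year"].to_numpy(dtype=float) >= 2006).astype(float)
    else:
        if term not in cov.columns:
            raise ValueError(f"beta term {term!r} has no matching covariate column")
        x = cov[term].to_numpy(dtype=float)
        sd = x.std(ddof=1)
        if sd == 0:
            raise ValueError(f"beta term {term!r} is constant in the simulation")
        z = (x - x.mean()) / sd
    cache[term] = z
    return z


def simulate_occupancy(
    config: SimulationConfig,
    boxes: pd.DataFrame,
    covariates: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Draw Bernoulli occupancy from the logistic truth model.

    ``covariates`` is the raw-scale box-year table (one row per box-year);
    each beta term is standardised over the table before the linear predictor
    eta = beta0 + sum beta_t x_t + b_site + b_box is formed.
    """
    cov = covariates.merge(boxes[["box_id", "site_id"]], on="box_id", how="left")
    cache: dict[str, np.ndarray] = {}
    eta = np.zeros(len(cov))
    used = {}
    for term, coef in config.beta.items():
        if term == "Intercept":
            eta = eta + coef
            continue
        z = _standardized_term(cov, term, cache)
        used[term] = z
        eta = eta + coef * z

    site_ids = sorted(cov["site_id"].unique())
    b_site = dict(zip(site_ids, rng.normal(0.0, config.sigma_site, len(site_ids))))
    eta = eta + np.array([b_site[s] for s in cov["site_id"]])
    b_box: dict = {}
    if config.boxes_per_site == 2 and config.sigma_box > 0:
        box_ids = sorted(cov["box_id"].unique())
        b_box = dict(zip(box_ids, rng.normal(0.0, config.sigma_box, len(box_ids))))
        eta = eta + np.array([b_box[b] for b in cov["box_id"]])

    prob = expit(eta)
    occupied = rng.binomial(1, prob)
    occ = cov[["box_id", "year"]].copy()
    occ["occupied"] = occupied
    if config.species == "red":
        occ["time_period"] = (occ["year"] >= 2006).astype(int) + 1
    truth = SimulationTruth(
        covariates=pd.DataFrame(used, index=cov.index).assign(
            box_id=cov["box_id"], year=cov["year"]
        ),
        linear_predictor=eta,
        ranef_site=b_site,
        ranef_box=b_box,
        beta=dict(config.beta),
    )
    return occ, truth


def _make_visits(
    occ: pd.DataFrame, config: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Raw visit table implied by the occupancy records.

    The first visit carries the true state; a fraction of box-years get a
    second, later visit (random state) and a small fraction are visited for
    the first time only in July, which the cleaning step must drop.
    """
    rows = []
    for rec in occ.itertuples(index=False):
        late = rng.uniform() < config.visit_late_prob
        month, day = (7, int(rng.integers(1, 15))) if late else (
            int(rng.integers(4, 7)), int(rng.integers(1, 29)))
        rows.append({
            "box_id": rec.box_id,
            "date": f"{rec.year:04d}-{month:02d}-{day:02d}",
            "occupied": int(rec.occupied),
        })
        if not late and rng.uniform() < config.visit_duplicate_prob:
            rows.append({
                "box_id": rec.box_id,
                "date": f"{rec.year:04d}-{month + int(rng.integers(1, 3)):02d}-"
                        f"{int(rng.integers(1, 29)):02d}",
                "occupied": int(rng.integers(0, 2)),
            })
    return pd.DataFrame(rows)


def simulate_dataset(config: SimulationConfig) -> SimulationResult:
    """Run the full generator chain under split per-component seed streams."""
    streams = np.random.SeedSequence(config.seed).spawn(6)
    rng_land, rng_sites, rng_pred, rng_cone, rng_out, rng_visit = (
        np.random.default_rng(s) for s in streams
    )
    grid = generate_landscape(config, rng_land)
    boxes = place_sites(config, grid, rng_sites)
    nests = place_predator_nests(config, grid, rng_pred)
    cone = generate_cone_series(config, rng_cone)

    merged = merge_classes(grid, default_class_table())
    comp = compositions_for_boxes(merged, boxes, config.radius_small_m)
    comp = comp.drop(columns=["radius_m"])
    years = list(config.years)
    cov = comp.merge(pd.DataFrame({"year": years}), how="cross")
    risk = risk_covariate(
        boxes, nests, config.kernel_species, years, config.kernel_truth,
        lag=config.kernel_lag, aggregation=config.aggregation,
    )
    cov = cov.merge(
        risk[["box_id", "year", "value"]].rename(
            columns={"value": config.kernel_species}),
        on=["box_id", "year"], how="left", validate="one_to_one",
    )
    if any(t.split(":")[0] == "cone" or t == "cone" for t in config.beta):
        lookup = dict(zip(cone["year"], cone["crop"]))
        cov["cone"] = [lookup[y - 1] for y in cov["year"]]

    occ, truth = simulate_occupancy(config, boxes, cov, rng_out)
    visits = _make_visits(occ, config, rng_visit)
    return SimulationResult(
        config=config, grid=grid, class_table=default_class_table(),
        boxes=boxes, nests=nests, cone=cone, covariates=cov,
        occupancy=occ, visits=visits, truth=truth,
    )


def write_dataset(result: SimulationResult, outdir: str | Path) -> None:
    """Persist the fixture bundle as plain-text files (raster + CSVs + truth)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_grid(result.grid, outdir / "landuse.asc")
    result.class_table.to_csv(outdir / "class_table.csv")
    result.boxes.to_csv(outdir / "boxes.csv", index=False)
    result.nests.to_csv(outdir / "predator_nests.csv", index=False)
    result.cone.to_csv(outdir / "cone_index.csv", index=False)
    result.visits.to_csv(outdir / "visits.csv", index=False)
    result.occupancy.to_csv(outdir / "occupancy_true.csv", index=False)
    cfg = asdict(result.config)
    cfg["kernel_truth"] = asdict(result.config.kernel_truth)
    truth = {
        "beta": result.truth.beta,
        "sigma_site": result.config.sigma_site,
        "sigma_box": result.config.sigma_box,
        "config": cfg,
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, default=float)
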