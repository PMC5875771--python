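"""Shared fixtures: small grids, toy visit tables, and reduced study simulations."""

import numpy as np
import pandas as pd
import pytest

from riskscape.landscape import LandUseGrid, default_class_table, merge_classes
from riskscape.simulate import SimulationConfig, flying_config, red_config, simulate_dataset

#: Reduced landscape mix used by the small pipeline fixtures (5 classes keeps
#: the habitat design well-conditioned at small n).
SMALL_MIX = {"Mo spruce": 0.30, "Mo pine": 0.20, "Y pine": 0.15, "Field": 0.20, "Bog": 0.15}


@pytest.fixture(scope="session")
def uniform_spruce_grid() -> LandUseGrid:
    """1 km x 1 km single-class (mature spruce) grid at 25 m cells."""
    cells = np.full((40, 40), 11, dtype=np.int64)
    return LandUseGrid(origin_x=0.0, origin_y=0.0, cell_size=25.0, cells=cells)


@pytest.fixture()
def toy_visits() -> pd.DataFrame:
    """Six visits: two box-years with duplicate visits, one July-only box."""
    return pd.DataFrame(
        {
            "box_id": ["A", "A", "A", "A", "B", "C"],
            "date": [
                "2010-04-10", "2010-05-20",  # duplicate year; first is April
                "2011-05-05", "2011-06-01",  # duplicate year; first is May
                "2010-07-05",                # first visit after June: dropped
                "2010-04-01",
            ],
            "occupied": [0, 1, 1, 0, 1, 1],
        }
    )


def small_flying_config(**overrides) -> SimulationConfig:
    defaults = dict(
        seed=11,
        extent_m=12_000.0,
        cell_size_m=50.0,
        class_mix=dict(SMALL_MIX),
        n_sites=40,
        years=tuple(range(2002, 2007)),
        radius_large_m=500.0,
    )
    defaults.update(overrides)
    return flying_config(**defaults)


def small_red_config(**overrides) -> SimulationConfig:
    defaults = dict(
        seed=12,
        extent_m=12_000.0,
        cell_size_m=50.0,
        class_mix=dict(SMALL_MIX),
        n_sites=60,
        years=tuple(range(2002, 2010)),
        radius_large_m=1000.0,
        # the reduced landscape mix has no built areas
        beta={
            "Intercept": -2.27, "year": -0.16, "time_period_2": 1.33,
            "goshawk": -0.22, "Field": 0.36, "Field^2": -0.08,
            "cone": 0.17, "cone:Mo spruce": 0.08,
        },
    )
    defaults.update(overrides)
    return red_config(**defaults)


@pytest.fixture(scope="session")
def small_flying_dataset():
    return simulate_dataset(small_flying_config())


@pytest.fixture(scope="session")
def small_red_dataset():
    return simulate_dataset(small_red_config())


def analysis_table(result) -> pd.DataFrame:
    """Box-year table joining simulated outcomes, covariates and grouping."""
    return (
        result.occupancy.merge(result.covariates, on=["box_id", "year"])
        .merge(result.boxes[["box_id", "site_id"]], on="box_id")
    )


@pytest.fixture(scope="session")
def table_builder():
    return analysis_table


def write_pipeline_fixture(base_dir, species="flying", sim_overrides=None,
                           **config_overrides):
    """Simulate a small dataset, persist it, and build a pipeline config."""
    from pathlib import Path

    from riskscape.pipeline import PipelineConfig
    from riskscape.simulate import simulate_dataset, write_dataset

    base = Path(base_dir)
    maker = small_flying_config if species == "flying" else small_red_config
    result = simulate_dataset(maker(**(sim_overrides or {})))
    data_dir = base / "data"
    write_dataset(result, data_dir)
    defaults = dict(
        species=species,
        grid_path=str(data_dir / "landuse.asc"),
        class_table_path=str(data_dir / "class_table.csv"),
        boxes_path=str(data_dir / "boxes.csv"),
        visits_path=str(data_dir / "visits.csv"),
        nests_path=str(data_dir / "predator_nests.csv"),
        cone_path=str(data_dir / "cone_index.csv"),
        out_dir=str(base / "out"),
        radius_small_m=result.config.radius_small_m,
        radius_large_m=result.config.radius_large_m,
        predators=["ural_owl", "goshawk"] if species == "flying" else ["goshawk"],
        sd_values=[2000.0, 3000.0],
        flat_top_values=[500.0, 2500.0],
        lags=[0, 1],
        moran_radii=[500.0, 2000.0],
        best_subset_terms=(["ural_owl", "Field"] if species == "flying"
                           else ["goshawk", "Field"]),
    )
    defaults.update(config_overrides)
    return PipelineConfig(**defaults), result
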