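"""Flat-top Gaussian predation-risk surfaces around predator nests.

The risk surface around a predator nest is 1 on a plateau of radius
``flat_top_m``, decays beyond it as ``exp(-(d - flat_top_m)^2 / (2 sd_m^2))``,
and is truncated to 0 past ``cutoff_m`` (10 km by default).  The surface
height at a prey nest-box location, aggregated over all predator nests of one
species and year (sum by default, pointwise max optionally), is the
predation-risk covariate.  Kernel hyperparameters (SD of the flank, plateau
radius) and the temporal lag (current vs previous year's nests) are selected
by refitting the full occupancy model for every candidate and taking the
minimum-AIC combination.

The kernel is unit-height rather than a normalised density: the covariate is
standardised downstream, so only relative heights matter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "KernelParams",
    "KernelSelectionResult",
    "DEFAULT_SD_VALUES",
    "DEFAULT_FLAT_TOP_VALUES",
    "kernel_height",
    "risk_at_point",
    "risk_covariate",
    "kernel_grid_search",
]

#: Default candidate grids: SDs of 1-4 km crossed with plateau radii of
#: 500-2500 m (20 combinations), evaluated at each temporal lag.
DEFAULT_SD_VALUES = (1000.0, 2000.0, 3000.0, 4000.0)
DEFAULT_FLAT_TOP_VALUES = (500.0, 1000.0, 1500.0, 2000.0, 2500.0)


@dataclass(frozen=True)
class KernelParams:
    """Hyperparameters of the flat-top Gaussian risk kernel (all meters)."""

    sd_m: float
    flat_top_m: float
    cutoff_m: float = 10_000.0

    def __post_init__(self) -> None:
        if self.sd_m <= 0:
            raise ValueError("sd_m must be positive")
        if self.flat_top_m < 0:
            raise ValueError("flat_top_m must be non-negative")
        if self.cutoff_m <= self.flat_top_m:
            raise ValueError("cutoff_m must exceed flat_top_m")


def kernel_height(distance_m, params: KernelParams):
    """Height of the flat-top Gaussian kernel at the given distance(s).

    1 on the plateau, Gaussian decay on the flank, 0 beyond the cutoff.
    Vectorised; scalar in, scalar out.
    """
    d = np.asarray(distance_m, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance_m must be non-negative")
    excess = np.maximum(d - params.flat_top_m, 0.0)
    h = np.exp(-(excess**2) / (2.0 * params.sd_m**2))
    h = np.where(d > params.cutoff_m, 0.0, h)
    return float(h) if np.isscalar(distance_m) else h


def _nest_xy(nests) -> np.ndarray:
    if isinstance(nests, pd.DataFrame):
        for col in ("species", "year"):
            if col in nests.columns and nests[col].nunique() > 1:
                raise ValueError(
                    f"nest set mixes multiple values of {col!r}: "
                    f"{sorted(nests[col].unique().tolist())}"
                )
        return nests[["x", "y"]].to_numpy(dtype=float)
    arr = np.asarray(nests, dtype=float)
    return arr.reshape(0, 2) if arr.size == 0 else arr.reshape(-1, 2)


def risk_at_point(
    x: float,
    y: float,
    nests,
    params: KernelParams,
    aggregation: str = "sum",
) -> float:
    """Aggregate kernel height at (x, y) over one species-year nest set.

    ``nests`` is an (k, 2) coordinate array or a DataFrame with x, y (and
    optionally species/year columns, which must be homogeneous).
    """
    if aggregation not in {"sum", "max"}:
        raise ValueError("aggregation must be 'sum' or 'max'")
    xy = _nest_xy(nests)
    if xy.shape[0] == 0:
        return 0.0
    d = np.hypot(xy[:, 0] - x, xy[:, 1] - y)
    h = kernel_height(d, params)
    return float(h.sum() if aggregation == "sum" else h.max())


class MissingPredatorYearError(ValueError):
    """Required predator-nest years are absent and filling is disabled."""

    def __init__(self, years: Sequence[int]):
        self.years = sorted(years)
        super().__init__(f"no predator nest data for required year(s) {self.years}")


def _fill_year(needed: int, available: Sequence[int]) -> int:
    """Nearest available year, preferring the later one on ties."""
    avail = sorted(available)
    return min(avail, key=lambda y: (abs(y - needed), -y))


def risk_covariate(
    boxes: pd.DataFrame,
    nests: pd.DataFrame,
    species: str,
    years: Iterable[int],
    params: KernelParams,
    lag: int = 0,
    aggregation: str = "sum",
    fill_missing: bool = True,
) -> pd.DataFrame:
    """Per-box-per-year risk covariate for one predator species.

    For analysis year ``y`` the nests of year ``y - lag`` are used; an absent
    predator year is filled from the nearest available year (later preferred)
    when ``fill_missing`` is true, and the substitution is flagged in the
    ``filled_from`` column and logged.

    Returns columns box_id, year, species, value, lag, sd_m, flat_top_m,
    aggregation, filled_from (NaN when no fill happened).
    """
    if lag not in (0, 1):
        raise ValueError("lag must be 0 or 1")
    years = sorted(set(int(y) for y in years))
    sub = nests[nests["species"] == species] if "species" in nests.columns else nests
    available = sorted(sub["year"].unique().tolist()) if len(sub) else []
    box_xy = boxes[["x", "y"]].to_numpy(dtype=float)

    missing = [y - lag for y in years if (y - lag) not in available]
    if missing and not fill_missing:
        raise MissingPredatorYearError(missing)
    if missing and not available:
        raise MissingPredatorYearError(missing)

    out = []
    for year in years:
        need = year - lag
        filled_from = np.nan
        use = need
        if need not in available:
            use = _fill_year(need, available)
            filled_from = use
            logger.info(
                "predator year %d missing for %s; using nests from %d", need, species, use
            )
        nest_xy = sub.loc[sub["year"] == use, ["x", "y"]].to_numpy(dtype=float)
        if nest_xy.shape[0]:
            dx = box_xy[:, 0][:, None] - nest_xy[None, :, 0]
            dy = box_xy[:, 1][:, None] - nest_xy[None, :, 1]
            h = kernel_height(np.hypot(dx, dy), params)
            vals = h.sum(axis=1) if aggregation == "sum" else h.max(axis=1)
        else:
            vals = np.zeros(len(boxes))
        out.append(
            pd.DataFrame(
                {
                    "box_id": boxes["box_id"].to_numpy(),
                    "year": year,
                    "species": species,
                    "value": vals,
                    "lag": lag,
                    "sd_m": params.sd_m,
                    "flat_top_m": params.flat_top_m,
                    "aggregation": aggregation,
                    "filled_from": filled_from,
                }
            )
        )
    return pd.concat(out, ignore_index=True)


@dataclass
class KernelSelectionResult:
    """AIC table over the kernel hyperparameter x lag grid and the winner."""

    table: pd.DataFrame  # columns sd_m, flat_top_m, lag, aic, converged
    selected: KernelParams
    selected_lag: int
    delta_aic_runner_up: float


def kernel_grid_search(
    boxes: pd.DataFrame,
    nests: pd.DataFrame,
    species: str,
    years: Iterable[int],
    base_table: pd.DataFrame,
    fit_fn: Callable[[pd.DataFrame], object],
    sd_values: Sequence[float] = DEFAULT_SD_VALUES,
    flat_top_values: Sequence[float] = DEFAULT_FLAT_TOP_VALUES,
    lags: Sequence[int] = (0, 1),
    aggregation: str = "sum",
    cutoff_m: float = 10_000.0,
    risk_col: str = "risk",
    fill_missing: bool = True,
) -> KernelSelectionResult:
    """Select kernel hyperparameters and lag by full-model AIC.

    For every (sd, flat-top, lag) candidate the risk covariate is recomputed,
    written into ``base_table`` under ``risk_col``, and ``fit_fn`` (which must
    fit the full occupancy model and return an object with ``aic`` and
    ``converged`` attributes) is called.  The converged candidate with minimal
    AIC wins; ties break toward smaller flat-top, then smaller SD, then
    smaller lag.  Non-converged fits are recorded but excluded from the
    argmin.
    """
    rows = []
    for lag in lags:
        for sd in sd_values:
            for flat in flat_top_values:
                params = KernelParams(sd_m=sd, flat_top_m=flat, cutoff_m=cutoff_m)
                cov = risk_covariate(
                    boxes, nests, species, years, params,
                    lag=lag, aggregation=aggregation, fill_missing=fill_missing,
                )
                table = base_table.merge(
                    cov[["box_id", "year", "value"]].rename(columns={"value": risk_col}),
                    on=["box_id", "year"],
                    how="left",
                    validate="many_to_one",
                )
                if table[risk_col].isna().any():
                    raise ValueError("risk covariate missing for some box-years")
                try:
                    fit = fit_fn(table)
                    aic = float(fit.aic)
                    converged = bool(getattr(fit, "converged", True))
                except Exception as exc:  # noqa: BLE001 - recorded, not raised
                    logger.warning("kernel candidate (%s, %s, lag %s) failed: %s",
                                   sd, flat, lag, exc)
                    aic, converged = np.nan, False
                rows.append(
                    {"sd_m": sd, "flat_top_m": flat, "lag": lag,
                     "aic": aic, "converged": converged}
                )
    table = pd.DataFrame(rows)
    ok = table[table["converged"] & table["aic"].notna()]
    if ok.empty:
        raise RuntimeError("kernel grid search: no candidate model converged")
    ranked = ok.sort_values(
        ["aic", "flat_top_m", "sd_m", "lag"], kind="mergesort"
    ).reset_index(drop=True)
    best = ranked.iloc[0]
    delta = float(ranked.iloc[1]["aic"] - best["aic"]) if len(ranked) > 1 else np.nan
    return KernelSelectionResult(
        table=table,
        selected=KernelParams(
            sd_m=float(best["sd_m"]), flat_top_m=float(best["flat_top_m"]), cutoff_m=cutoff_m
        ),
        selected_lag=int(best["lag"]),
        delta_aic_runner_up=delta,
    )
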