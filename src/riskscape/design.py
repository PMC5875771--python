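"""Model specification, covariate standardisation, and collinearity screening.

All continuous covariates (including calendar year) are standardised as
``(x - mean(x)) / sd(x)`` with the sample SD (n-1 denominator).  Quadratic
and interaction columns are built from the *standardised* parents and are
not themselves re-standardised.  Multicollinearity among main-effect
habitat/risk covariates is screened with variance inflation factors,
iteratively removing the largest-VIF variable until all fall below the
threshold (5 by default); mandatory terms such as year and the monitoring
period are exempt from screening.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "DesignMatrix",
    "VifReport",
    "standardize",
    "add_quadratic",
    "build_design",
    "compute_vif",
    "vif_screen",
]


def standardize(values) -> tuple[np.ndarray, float, float]:
    """Center and scale to mean 0, sample SD 1; returns (z, mean, sd)."""
    x = np.asarray(values, dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("cannot standardize a constant column")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    return (x - mean) / sd, mean, sd


@dataclass
class ModelSpec:
    """Terms and grouping structure of one occupancy model.

    ``quadratic`` lists parents whose squared (standardised) value enters as
    an extra column; ``interactions`` are pairs of term names whose
    standardised product enters.  ``random`` is "site_box" (box nested in
    site), "site", or "none".  ``factors`` are two-level 1/2 factors entered
    as a 0/1 indicator for level 2 and never standardised.
    """

    response: str = "occupied"
    mandatory: list[str] = field(default_factory=lambda: ["year"])
    habitat: list[str] = field(default_factory=list)
    risk: list[str] = field(default_factory=list)
    quadratic: list[str] = field(default_factory=list)
    interactions: list[tuple[str, str]] = field(default_factory=list)
    random: str = "site_box"
    factors: list[str] = field(default_factory=lambda: ["time_period"])
    standardize: bool = True

    @property
    def main_terms(self) -> list[str]:
        return list(self.mandatory) + list(self.habitat) + list(self.risk)

    def __post_init__(self) -> None:
        if self.random not in {"site_box", "site", "none"}:
            raise ValueError("random must be 'site_box', 'site' or 'none'")
        for parent in self.quadratic:
            if parent not in self.main_terms:
                raise ValueError(f"quadratic parent {parent!r} is not a model term")
        for a, b in self.interactions:
            for t in (a, b):
                if t not in self.main_terms:
                    raise ValueError(f"interaction term {t!r} is not a model term")


@dataclass
class DesignMatrix:
    """Standardised design for one model fit.

    ``X`` has an Intercept column first; ``scalers`` maps each standardised
    term to its (mean, sd) so fits can be mapped back to the raw scale.
    """

    X: pd.DataFrame
    y: np.ndarray
    site: np.ndarray | None
    box: np.ndarray | None
    site_levels: np.ndarray | None
    box_levels: np.ndarray | None
    scalers: dict[str, tuple[float, float]]
    spec: ModelSpec


def add_quadratic(X: pd.DataFrame, term: str) -> pd.DataFrame:
    """Append the elementwise square of a standardised column as ``term^2``."""
    if term not in X.columns:
        raise ValueError(f"term {term!r} not in design")
    out = X.copy()
    sq = out[term].to_numpy() ** 2
    if np.ptp(sq) < 1e-12:
        logger.warning("quadratic column %s^2 is (near-)constant", term)
    out[f"{term}^2"] = sq
    return out


def build_design(table: pd.DataFrame, spec: ModelSpec) -> DesignMatrix:
    """Assemble the standardised design matrix from a box-year table.

    ``table`` needs the response, every model term, and site_id (plus box_id
    for nested random structure).
    """
    for col in [spec.response] + spec.main_terms:
        if col not in table.columns:
            raise ValueError(f"column {col!r} missing from analysis table")
    y = table[spec.response].to_numpy(dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("response must be binary 0/1")

    X = pd.DataFrame(index=table.index)
    X["Intercept"] = 1.0
    scalers: dict[str, tuple[float, float]] = {}
    for term in spec.main_terms:
        raw = table[term].to_numpy(dtype=float)
        if term in spec.factors:
            levels = np.unique(raw)
            if not np.isin(levels, (1.0, 2.0)).all():
                raise ValueError(f"factor {term!r} must have levels 1/2")
            X[f"{term}_2"] = (raw == 2.0).astype(float)
        elif spec.standardize:
            try:
                z, mean, sd = standardize(raw)
            except ValueError as exc:
                raise ValueError(f"covariate {term!r}: {exc}") from exc
            scalers[term] = (mean, sd)
            X[term] = z
        else:
            X[term] = raw
    for parent in spec.quadratic:
        X = add_quadratic(X, parent)
    for a, b in spec.interactions:
        prod = X[a].to_numpy() * X[b].to_numpy()
        if np.ptp(prod) < 1e-12:
            raise ValueError(
                f"interaction {a}:{b} is constant (rank-deficient design)"
            )
        X[f"{a}:{b}"] = prod

    site = box = site_levels = box_levels = None
    if spec.random in {"site_box", "site"}:
        if "site_id" not in table.columns:
            raise ValueError("site_id column required for random structure")
        site, site_levels = pd.factorize(table["site_id"], sort=True)
    if spec.random == "site_box":
        if "box_id" not in table.columns:
            raise ValueError("box_id column required for nested random structure")
        box, box_levels = pd.factorize(table["box_id"], sort=True)
    return DesignMatrix(
        X=X, y=y, site=site, box=box,
        site_levels=site_levels, box_levels=box_levels,
        scalers=scalers, spec=spec,
    )


@dataclass
class VifReport:
    """Variance inflation factors, with any screening drops in order."""

    vif: dict[str, float]
    dropped: list[str]
    threshold: float | None


def compute_vif(table: pd.DataFrame, variables: Sequence[str]) -> VifReport:
    """VIF_j = 1/(1 - R^2_j) from regressing each variable on the others.

    Main-effect columns only; perfectly collinear variables report +inf.
    """
    variables = list(variables)
    if len(variables) < 2:
        raise ValueError("VIF needs at least two variables")
    from statsmodels.stats.outliers_influence import variance_inflation_factor
    from statsmodels.tools import add_constant

    mat = add_constant(table[variables].to_numpy(dtype=float), has_constant="add")
    vifs: dict[str, float] = {}
    with np.errstate(divide="ignore"):
        for j, name in enumerate(variables, start=1):
            vifs[name] = float(variance_inflation_factor(mat, j))
    return VifReport(vif=vifs, dropped=[], threshold=None)


def vif_screen(
    table: pd.DataFrame,
    variables: Sequence[str],
    threshold: float = 5.0,
    exempt: Sequence[str] = (),
) -> VifReport:
    """Iteratively drop the largest-VIF screened variable until all < threshold.

    ``exempt`` variables (mandatory model terms) contribute to the VIF
    computation but are never dropped.  Raises when the threshold cannot be
    met without reducing the screened set below two usable variables.
    """
    if threshold <= 1:
        raise ValueError("threshold must exceed 1")
    current = [v for v in variables if v not in exempt]
    exempt = [v for v in variables if v in exempt]
    dropped: list[str] = []
    while True:
        cols = exempt + current
        if len(cols) < 2:
            report = VifReport(vif={c: 1.0 for c in cols}, dropped=dropped, threshold=threshold)
            return report
        report = compute_vif(table, cols)
        screened = {v: report.vif[v] for v in current}
        worst = max(screened, key=screened.get) if screened else None
        if worst is None or screened[worst] < threshold:
            return VifReport(vif=report.vif, dropped=dropped, threshold=threshold)
        if len(current) - 1 < 1 or (len(current) - 1) + len(exempt) < 2:
            raise ValueError(
                f"VIF screening cannot reach threshold {threshold} without "
                f"emptying the screened variable set (remaining: {current})"
            )
        current.remove(worst)
        dropped.append(worst)
        logger.info("VIF screen: dropped %s (VIF %.2f)", worst, screened[worst])
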