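"""AIC model ranking, predator-habitat interactions, and cone-crop models.

Covers the comparison of the full occupancy model against the best submodels
(exhaustive subset enumeration ranked by AIC), the test of predator-kernel x
habitat interactions at the home-range scale (non-significant interactions
are dropped and the model refit), and the red-squirrel food models pairing
the previous autumn's spruce-cone index with pine or spruce forest area
under a site-only random intercept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .design import ModelSpec, build_design
from .glmm import FitResult, fit_glmm

logger = logging.getLogger(__name__)

__all__ = [
    "ModelRanking",
    "best_subset_search",
    "interaction_analysis",
    "cone_interaction_models",
    "effect_curve",
]

MAX_OPTIONAL_TERMS = 20


@dataclass
class ModelRanking:
    """Ranked candidate models: term subsets with AIC and delta-AIC."""

    table: pd.DataFrame  # columns: terms (tuple), n_terms, aic, delta_aic
    top_k: int


def best_subset_search(
    table: pd.DataFrame,
    spec: ModelSpec,
    optional_terms: Sequence[str] | None = None,
    top_k: int = 10,
    **fit_kwargs,
) -> ModelRanking:
    """Exhaustively fit subsets of optional main-effect terms, rank by AIC.

    Mandatory terms are always included; a quadratic term enters exactly when
    its parent does.  Ties break toward fewer terms, then lexicographic term
    order.  Raises when more than 20 optional terms would make the 2^m
    enumeration intractable.
    """
    if optional_terms is None:
        optional_terms = list(spec.habitat) + list(spec.risk)
    optional_terms = list(optional_terms)
    m = len(optional_terms)
    if m > MAX_OPTIONAL_TERMS:
        raise ValueError(
            f"{m} optional terms would need 2^{m} fits; reduce the term set "
            f"to at most {MAX_OPTIONAL_TERMS}"
        )
    fit_kwargs.setdefault("se_method", "profile")  # only AIC is needed here
    rows = []
    for k in range(m + 1):
        for subset in combinations(optional_terms, k):
            sub = replace(
                spec,
                habitat=[t for t in spec.habitat if t in subset],
                risk=[t for t in spec.risk if t in subset],
                quadratic=[q for q in spec.quadratic if q in subset or q in spec.mandatory],
                interactions=[],
            )
            design = build_design(table, sub)
            fit = fit_glmm(design, warn_nonconverged=False, **fit_kwargs)
            rows.append(
                {
                    "terms": subset,
                    "n_terms": len(subset),
                    "aic": fit.aic,
                    "converged": fit.converged,
                }
            )
    tab = pd.DataFrame(rows)
    tab = tab.sort_values(
        by=["aic", "n_terms", "terms"], kind="mergesort"
    ).reset_index(drop=True)
    tab["delta_aic"] = tab["aic"] - tab["aic"].iloc[0]
    return ModelRanking(table=tab.head(min(top_k, len(tab))), top_k=top_k)


def interaction_analysis(
    table: pd.DataFrame,
    spec: ModelSpec,
    pairs: Sequence[tuple[str, str]],
    alpha: float = 0.05,
    **fit_kwargs,
) -> tuple[FitResult, FitResult, list[tuple[str, str]]]:
    """Fit predator x habitat interactions; drop non-significant ones and refit.

    Returns (full fit with all interactions, final fit with only retained
    interactions, retained pairs).  Intended for the home-range-scale model.
    """
    full_spec = replace(spec, interactions=list(pairs))
    full_fit = fit_glmm(build_design(table, full_spec), **fit_kwargs)
    retained = []
    for a, b in pairs:
        p = float(full_fit.p[full_fit.terms.index(f"{a}:{b}")])
        if p < alpha:
            retained.append((a, b))
        else:
            logger.info("dropping interaction %s:%s (p = %.3f)", a, b, p)
    final_spec = replace(spec, interactions=retained)
    final_fit = fit_glmm(build_design(table, final_spec), **fit_kwargs)
    return full_fit, final_fit, retained


def join_cone_index(
    table: pd.DataFrame, cone: pd.DataFrame, lag: int = 1, col: str = "cone"
) -> pd.DataFrame:
    """Attach the previous year's cone-crop index to each box-year row."""
    if not {"year", "crop"} <= set(cone.columns):
        raise ValueError("cone index needs columns year, crop")
    lookup = dict(zip(cone["year"].astype(int), cone["crop"].astype(float)))
    need = sorted(set(int(y) - lag for y in table["year"].unique()))
    missing = [y for y in need if y not in lookup]
    if missing:
        raise ValueError(f"cone index missing for lag-year(s) {missing}")
    out = table.copy()
    out[col] = [lookup[int(y) - lag] for y in out["year"]]
    return out


def cone_interaction_models(
    table: pd.DataFrame,
    cone: pd.DataFrame,
    spruce_term: str = "Mo spruce",
    pine_term: str = "Mo pine",
    mandatory: Sequence[str] = ("year", "time_period"),
    **fit_kwargs,
) -> dict[str, FitResult]:
    """The two red-squirrel food models: cone x spruce and cone x pine.

    Each model has the lag-1 cone index, one forest-area term, and their
    product (standardised before multiplication), with a site-only random
    intercept.  Returns a dict keyed "spruce" / "pine".
    """
    joined = join_cone_index(table, cone, lag=1, col="cone")
    mandatory = [m for m in mandatory if m in joined.columns]
    fits: dict[str, FitResult] = {}
    for name, forest in (("spruce", spruce_term), ("pine", pine_term)):
        spec = ModelSpec(
            mandatory=list(mandatory),
            habitat=[forest, "cone"],
            risk=[],
            quadratic=[],
            interactions=[("cone", forest)],
            random="site",
        )
        fits[name] = fit_glmm(build_design(joined, spec), **fit_kwargs)
    return fits


def effect_curve(
    fit: FitResult,
    term: str,
    values_std: np.ndarray | None = None,
) -> pd.DataFrame:
    """Predicted occupancy probability along one standardised covariate.

    Other covariates are held at 0 (their mean), random effects at their
    population mean; the term's quadratic column, if present, follows the
    term.  Raw covariate values are included when the fit recorded scalers.
    """
    if values_std is None:
        values_std = np.linspace(-2.0, 2.0, 101)
    values_std = np.asarray(values_std, dtype=float)
    if term not in fit.terms:
        raise ValueError(f"term {term!r} not in fit")
    eta = np.zeros_like(values_std)
    if "Intercept" in fit.terms:
        eta += fit.coef("Intercept")
    eta += fit.coef(term) * values_std
    if f"{term}^2" in fit.terms:
        eta += fit.coef(f"{term}^2") * values_std**2
    out = pd.DataFrame({"value_std": values_std, "probability": 1.0 / (1.0 + np.exp(-eta))})
    if term in fit.scalers:
        mean, sd = fit.scalers[term]
        out.insert(1, "value_raw", values_std * sd + mean)
    return out
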