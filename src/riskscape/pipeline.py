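"""End-to-end orchestration of the occupancy analysis workflow.

Stages (in order): clean visit records, habitat compositions at both buffer
scales, VIF screening of habitat covariates, kernel hyperparameter + lag
selection per predator, full mixed occupancy models at both scales, separate
young-pine models, predator x habitat interaction analysis at the home-range
scale, cone-crop interaction models (red squirrel), best-subset AIC ranking,
and Moran's I residual diagnostics.  Every stage persists plain-CSV outputs
into the configured directory as it completes, so a failing stage leaves all
earlier outputs intact, and a manifest records the configuration hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field as dc_field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import occupancy as occ_mod
from .design import ModelSpec, build_design, vif_screen
from .diagnostics import model_residuals, residual_moran
from .glmm import FitResult, fit_glmm, wald_table
from .kernel import (
    DEFAULT_FLAT_TOP_VALUES,
    DEFAULT_SD_VALUES,
    KernelParams,
    kernel_grid_search,
    risk_covariate,
)
from .landscape import ClassTable, MERGED_CLASSES, compositions_for_boxes, merge_classes, read_grid
from .selection import best_subset_search, cone_interaction_models, interaction_analysis

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineStageError", "Pipeline", "run_pipeline", "STAGES"]

STAGES = [
    "clean", "habitat", "vif", "risk", "fit", "youngpine",
    "interactions", "cones", "subsets", "diagnose", "report",
]

HABITAT_TERMS = [c for c in MERGED_CLASSES if c not in ("Field",)]


@dataclass
class PipelineConfig:
    """Inputs, analysis settings and output location for one pipeline run."""

    species: str  # "flying" | "red"
    grid_path: str
    boxes_path: str
    visits_path: str
    out_dir: str
    class_table_path: str | None = None
    nests_path: str | None = None
    cone_path: str | None = None
    radius_small_m: float = 200.0
    radius_large_m: float = 1000.0
    predators: list = dc_field(default_factory=lambda: ["ural_owl", "goshawk"])
    sd_values: list = dc_field(default_factory=lambda: list(DEFAULT_SD_VALUES))
    flat_top_values: list = dc_field(default_factory=lambda: list(DEFAULT_FLAT_TOP_VALUES))
    lags: list = dc_field(default_factory=lambda: [0, 1])
    cutoff_m: float = 10_000.0
    aggregation: str = "sum"
    vif_threshold: float = 5.0
    alpha: float = 0.05
    moran_radii: list = dc_field(default_factory=lambda: [50.0, 500.0, 5000.0])
    preferred_habitat: str = "Mo spruce"
    nonpreferred_habitat: str = "Y pine"
    best_subset_terms: list | None = None
    top_k: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.species not in {"flying", "red"}:
            raise ValueError("species must be 'flying' or 'red'")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        for r in [self.radius_small_m, self.radius_large_m, *self.moran_radii]:
            if r <= 0:
                raise ValueError("radii must be positive")
        if not self.sd_values or not self.flat_top_values:
            raise ValueError("kernel candidate lists must be non-empty")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @property
    def random_structure(self) -> str:
        # one box per site in the red-squirrel program: site-only intercept
        return "site_box" if self.species == "flying" else "site"

    @property
    def mandatory_terms(self) -> list[str]:
        return ["year"] if self.species == "flying" else ["year", "time_period"]


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


def _write_fit(fit: FitResult, out: Path, name: str, alpha: float) -> None:
    wald_table(fit, alpha=alpha).to_csv(out / f"{name}_coefficients.csv", index=False)
    with open(out / f"{name}_summary.json", "w") as fh:
        json.dump(fit.summary_dict(), fh, indent=2, default=float)


class Pipeline:
    """Stateful stage runner; see :data:`STAGES` for the stage order."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.state: dict = {}

    # -- stage bodies ------------------------------------------------------
    def _stage_clean(self) -> None:
        cfg = self.config
        visits = pd.read_csv(cfg.visits_path)
        records = occ_mod.first_visit_filter(visits)
        if cfg.species == "red":
            records = occ_mod.attach_time_period(records)
        boxes = pd.read_csv(cfg.boxes_path)
        records = records[records["box_id"].isin(boxes["box_id"])].reset_index(drop=True)
        self.state["boxes"] = boxes
        self.state["records"] = records
        records.to_csv(self.out / "cleaned.csv", index=False)
        logger.info("clean: %d box-year records", len(records))

    def _stage_habitat(self) -> None:
        cfg = self.config
        grid = read_grid(cfg.grid_path)
        table = (
            ClassTable.from_csv(cfg.class_table_path)
            if cfg.class_table_path
            else ClassTable()
        )
        merged = merge_classes(grid, table)
        boxes = self.state["boxes"]
        for label, radius in (("small", cfg.radius_small_m), ("large", cfg.radius_large_m)):
            comp = compositions_for_boxes(merged, boxes, radius)
            comp.to_csv(self.out / f"habitat_{label}.csv", index=False)
            self.state[f"habitat_{label}"] = comp
            logger.info("habitat (%s scale, %.0f m): %d boxes", label, radius, len(comp))
        self.state["grid"] = merged

    def _table(self, scale: str) -> pd.DataFrame:
        """Box-year analysis table at one scale (habitat + year + outcome)."""
        records = self.state["records"]
        comp = self.state[f"habitat_{scale}"].drop(columns=["radius_m"])
        boxes = self.state["boxes"][["box_id", "site_id"]]
        return records.merge(comp, on="box_id").merge(boxes, on="box_id")

    def _stage_vif(self) -> None:
        cfg = self.config
        screened = {}
        for scale in ("small", "large"):
            table = self._table(scale)
            variables = []
            for t in HABITAT_TERMS + ["Field"]:
                if t not in table.columns:
                    continue
                if table[t].nunique() < 2:
                    logger.info("vif (%s): %s constant in this dataset, excluded",
                                scale, t)
                    continue
                variables.append(t)
            report = vif_screen(table, variables, threshold=cfg.vif_threshold)
            screened[scale] = [v for v in variables if v not in report.dropped]
            pd.DataFrame(
                {"variable": list(report.vif), "vif": list(report.vif.values())}
            ).assign(scale=scale, dropped=lambda d: d["variable"].isin(report.dropped)
                     ).to_csv(self.out / f"vif_{scale}.csv", index=False)
            logger.info("vif (%s): dropped %s", scale, report.dropped or "nothing")
        self.state["screened"] = screened

    def _model_spec(self, scale: str, risk_terms: list[str],
                    extra_habitat: list[str] | None = None) -> ModelSpec:
        cfg = self.config
        habitat = [t for t in self.state["screened"][scale] if t != "Field"]
        if extra_habitat:
            habitat = habitat + [t for t in extra_habitat if t not in habitat]
        quadratic = ["Field"] if "Field" in self.state["screened"][scale] else []
        if cfg.species == "flying" and "goshawk" in risk_terms:
            quadratic.append("goshawk")
        return ModelSpec(
            mandatory=cfg.mandatory_terms,
            habitat=habitat + (["Field"] if "Field" in self.state["screened"][scale] else []),
            risk=risk_terms,
            quadratic=quadratic,
            random=self.config.random_structure,
        )

    def _stage_risk(self) -> None:
        """Kernel hyperparameter and lag selection per predator."""
        cfg = self.config
        nests = pd.read_csv(cfg.nests_path)
        boxes = self.state["boxes"]
        table = self._table("small")
        years = sorted(table["year"].unique().tolist())
        selected: dict[str, tuple[KernelParams, int]] = {}
        for predator in cfg.predators:
            base = table.copy()
            fixed_risk = []
            for prev, (params, lag) in selected.items():
                cov = risk_covariate(boxes, nests, prev, years, params,
                                     lag=lag, aggregation=cfg.aggregation)
                base = base.merge(
                    cov[["box_id", "year", "value"]].rename(columns={"value": prev}),
                    on=["box_id", "year"],
                )
                fixed_risk.append(prev)
            spec = self._model_spec("small", fixed_risk + [predator])

            def fit_fn(tab, spec=spec):
                return fit_glmm(build_design(tab, spec), warn_nonconverged=False,
                                se_method="profile")

            result = kernel_grid_search(
                boxes, nests, predator, years, base, fit_fn,
                sd_values=cfg.sd_values, flat_top_values=cfg.flat_top_values,
                lags=cfg.lags, aggregation=cfg.aggregation, cutoff_m=cfg.cutoff_m,
                risk_col=predator,
            )
            selected[predator] = (result.selected, result.selected_lag)
            result.table.assign(species=predator).to_csv(
                self.out / f"kernel_selection_{predator}.csv", index=False
            )
            logger.info(
                "risk: %s kernel sd=%.0f flat=%.0f lag=%d (delta-AIC %.2f)",
                predator, result.selected.sd_m, result.selected.flat_top_m,
                result.selected_lag, result.delta_aic_runner_up,
            )
        self.state["kernels"] = selected
        rows = [
            {"species": sp, "sd_m": p.sd_m, "flat_top_m": p.flat_top_m,
             "cutoff_m": p.cutoff_m, "lag": lag}
            for sp, (p, lag) in selected.items()
        ]
        pd.DataFrame(rows).to_csv(self.out / "kernels_selected.csv", index=False)
        # risk covariates under the selected kernels, for reuse downstream
        for sp, (params, lag) in selected.items():
            cov = risk_covariate(boxes, pd.read_csv(cfg.nests_path), sp, years,
                                 params, lag=lag, aggregation=cfg.aggregation)
            cov.to_csv(self.out / f"risk_{sp}.csv", index=False)
            self.state[f"risk_{sp}"] = cov

    def _analysis_table(self, scale: str) -> pd.DataFrame:
        table = self._table(scale)
        for sp in self.state["kernels"]:
            cov = self.state[f"risk_{sp}"]
            table = table.merge(
                cov[["box_id", "year", "value"]].rename(columns={"value": sp}),
                on=["box_id", "year"],
            )
        return table

    def _stage_fit(self) -> None:
        cfg = self.config
        self.state["fits"] = {}
        for scale in ("small", "large"):
            table = self._analysis_table(scale)
            spec = self._model_spec(scale, list(self.state["kernels"]))
            fit = fit_glmm(build_design(table, spec))
            self.state["fits"][scale] = (fit, table, spec)
            _write_fit(fit, self.out, f"full_{scale}", cfg.alpha)
            logger.info("fit (%s): AIC %.1f, converged=%s", scale, fit.aic, fit.converged)

    def _stage_youngpine(self) -> None:
        """Separate models adding young pine (excluded by the VIF screen)."""
        cfg = self.config
        rows = []
        for scale in ("small", "large"):
            table = self._analysis_table(scale)
            if cfg.nonpreferred_habitat not in table.columns:
                continue
            spec = self._model_spec(scale, list(self.state["kernels"]),
                                    extra_habitat=[cfg.nonpreferred_habitat])
            fit = fit_glmm(build_design(table, spec))
            _write_fit(fit, self.out, f"youngpine_{scale}", cfg.alpha)
            i = fit.terms.index(cfg.nonpreferred_habitat)
            rows.append({"scale": scale, "term": cfg.nonpreferred_habitat,
                         "estimate": fit.estimate[i], "se": fit.se[i],
                         "z": fit.z[i], "p": fit.p[i]})
        pd.DataFrame(rows).to_csv(self.out / "youngpine_effects.csv", index=False)

    def _stage_interactions(self) -> None:
        cfg = self.config
        table = self._analysis_table("small")
        primary = cfg.predators[0] if cfg.species == "flying" else "goshawk"
        # interaction parents must be present as main effects even when the
        # VIF screen removed them from the additive model
        spec = self._model_spec(
            "small", list(self.state["kernels"]),
            extra_habitat=[cfg.preferred_habitat, cfg.nonpreferred_habitat],
        )
        pairs = [(primary, cfg.preferred_habitat), (primary, cfg.nonpreferred_habitat)]
        full, final, retained = interaction_analysis(
            table, spec, pairs, alpha=cfg.alpha
        )
        _write_fit(full, self.out, "interactions_full", cfg.alpha)
        _write_fit(final, self.out, "interactions_final", cfg.alpha)
        pd.DataFrame(
            {"pair": [f"{a}:{b}" for a, b in pairs],
             "retained": [pair in retained for pair in pairs]}
        ).to_csv(self.out / "interactions_retained.csv", index=False)

    def _stage_cones(self) -> None:
        cfg = self.config
        if cfg.species != "red":
            logger.info("cones: skipped (flying-squirrel run)")
            return
        if not cfg.cone_path:
            raise ValueError("cone index file required for red-squirrel cone models")
        cone = pd.read_csv(cfg.cone_path)
        table = self._analysis_table("small")
        fits = cone_interaction_models(table, cone, mandatory=cfg.mandatory_terms)
        for name, fit in fits.items():
            _write_fit(fit, self.out, f"cones_{name}", cfg.alpha)

    def _stage_subsets(self) -> None:
        cfg = self.config
        for scale in ("small", "large"):
            fit, table, spec = self.state["fits"][scale]
            optional = cfg.best_subset_terms
            if optional is None:
                optional = [t for t in spec.risk + ["Field"] if t in spec.main_terms]
            ranking = best_subset_search(table, spec, optional_terms=optional,
                                         top_k=cfg.top_k)
            out = ranking.table.copy()
            out["terms"] = out["terms"].map(lambda t: "+".join(t) if t else "(mandatory only)")
            out.to_csv(self.out / f"best_subsets_{scale}.csv", index=False)

    def _stage_diagnose(self) -> None:
        cfg = self.config
        rows = []
        for scale in ("small", "large"):
            fit, table, _ = self.state["fits"][scale]
            resid = model_residuals(fit, y=table["occupied"].to_numpy())
            pd.DataFrame(
                {"box_id": table["box_id"], "year": table["year"], "residual": resid}
            ).to_csv(self.out / f"residuals_{scale}.csv", index=False)
            for radius in cfg.moran_radii:
                try:
                    moran = residual_moran(resid, table, self.state["boxes"],
                                           radii=(radius,))
                    moran["scale"] = scale
                    rows.append(moran)
                except ValueError as exc:
                    logger.warning("moran at %.0f m (%s): %s", radius, scale, exc)
                    rows.append(pd.DataFrame(
                        [{"radius_m": radius, "scale": scale, "error": str(exc)}]
                    ))
        pd.concat(rows, ignore_index=True).to_csv(self.out / "moran.csv", index=False)

    def _stage_report(self) -> None:
        cfg = self.config
        # analysis settings only: input/output paths are environment-specific
        # and would break byte-level reproducibility of the bundle
        settings = {
            k: v for k, v in asdict(cfg).items()
            if not (k.endswith("_path") or k.endswith("_dir"))
        }
        manifest = {
            "settings": settings,
            "settings_sha256": hashlib.sha256(
                json.dumps(settings, sort_keys=True, default=float).encode()
            ).hexdigest(),
            "stages": STAGES,
        }
        with open(self.out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=float)

    # -- driver ------------------------------------------------------------
    def run(self, stages: list[str] | None = None) -> dict:
        todo = stages or STAGES
        unknown = set(todo) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s) {sorted(unknown)}")
        for stage in STAGES:
            if stage not in todo:
                continue
            logger.info("=== stage %s ===", stage)
            try:
                getattr(self, f"_stage_{stage}")()
            except Exception as exc:
                raise PipelineStageError(stage, exc) from exc
        return self.state


def run_pipeline(config: PipelineConfig, stages: list[str] | None = None) -> dict:
    """Run the workflow end to end (or a prefix of stages); returns state."""
    return Pipeline(config).run(stages)
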