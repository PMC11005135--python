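"""End-to-end pipeline driver.

Stages: (optional) simulate -> rescale weights -> fit candidate models
-> select by AIC -> predict the full cell grid -> build the raked
post-stratification frame -> post-stratify overall and subgroup
prevalences -> bootstrap CIs -> validate against the gold survey and,
when truth is available, score recovery.  Each stage logs row counts and
timing; the whole run is deterministic given the configured seeds.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from .. import design, frame_builder, glmm, poststratify, synthetic, uncertainty, validation
from ..design import ModelSpec, TimeBasisSpec
from ..uncertainty import BootstrapConfig
from . import io as tableio

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

logger = logging.getLogger(__name__)


def _spec_from_mapping(m: dict, n_waves: int) -> ModelSpec:
    time_spec = TimeBasisSpec(
        m.get("time", "linear"), n_waves, tuple(m.get("knots", ()))
    )
    return ModelSpec(
        id=m["id"],
        time_spec=time_spec,
        random_intercepts=tuple(m.get("random_intercepts", ("domain",))),
        use_weights=bool(m.get("weighted", True)),
    )


@dataclass
class PipelineConfig:
    """Parsed pipeline configuration (see ``mrp-prev --help``)."""

    out: Path
    data_dir: Path | None = None
    simulate: dict | None = None
    models: list[dict] | None = None
    bootstrap: BootstrapConfig = field(
        default_factory=lambda: BootstrapConfig(n_replicates=2)
    )
    n_replicates: int = 0
    seed: int = 0
    log_level: str = "INFO"

    def model_specs(self, n_waves: int) -> list[ModelSpec]:
        if self.models is None:
            return design.default_model_specs(n_waves)
        return [_spec_from_mapping(m, n_waves) for m in self.models]


def load_config(path: str | Path, **overrides: Any) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    raw.update({k: v for k, v in overrides.items() if v is not None})
    boot_raw = raw.get("bootstrap", {})
    n_reps = int(boot_raw.get("replicates", 0))
    boot = BootstrapConfig(
        n_replicates=max(2, n_reps),
        alpha=float(boot_raw.get("alpha", 0.05)),
        seed=int(boot_raw.get("seed", raw.get("seed", 0))),
    )
    return PipelineConfig(
        out=Path(raw.get("out", "mrprev_out")),
        data_dir=Path(raw["data_dir"]) if raw.get("data_dir") else None,
        simulate=raw.get("simulate"),
        models=raw.get("models"),
        bootstrap=boot,
        n_replicates=n_reps,
        seed=int(raw.get("seed", 0)),
        log_level=str(raw.get("log_level", "INFO")),
    )


def _truth_config_from(sim: dict, seed: int) -> synthetic.TruthConfig:
    cfg = synthetic.default_truth_config(
        n_domains=int(sim.get("n_domains", 3)),
        n_waves=int(sim.get("n_waves", 4)),
        seed=int(sim.get("seed", seed)),
        sample_sizes=synthetic.SampleSizes(
            outcome=int(sim.get("n_outcome", 500)),
            smoking=int(sim.get("n_smoking", 2000)),
            gold=int(sim.get("n_gold", 2000)),
        ),
        sigma_domain=float(sim.get("sigma_domain", 0.3)),
        sigma_nested=float(sim.get("sigma_nested", 0.0)),
    )
    return cfg


class _Stage:
    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        self.t0 = time.perf_counter()
        logger.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.perf_counter() - self.t0
        if exc is None:
            logger.info("stage %s: done in %.2fs", self.name, dt)
            return False
        raise RuntimeError(f"stage {self.name} failed: {exc}") from exc


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute every stage and return the paths of written artifacts."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    truth = None
    if config.simulate is not None:
        with _Stage("simulate"):
            tcfg = _truth_config_from(config.simulate, config.seed)
            data_dir = out / "data"
            paths = synthetic.write_all(tcfg, data_dir)
            truth = synthetic.build_truth(tcfg)
            written.update(paths)
            logger.info("simulate: wrote %d artifacts", len(paths))
    else:
        if config.data_dir is None:
            raise RuntimeError("stage load failed: no data_dir and no simulate block")
        data_dir = Path(config.data_dir)

    with _Stage("load"):
        outcome = tableio.read_table(
            data_dir / "outcome_survey.csv", tableio.OUTCOME_SURVEY_SCHEMA
        )
        smoking = tableio.read_table(
            data_dir / "smoking_survey.csv", tableio.SMOKING_SURVEY_SCHEMA
        )
        population = tableio.read_table(
            data_dir / "population.csv", tableio.POPULATION_SCHEMA
        )
        gold = tableio.read_table(data_dir / "gold.csv", tableio.GOLD_SCHEMA)
        logger.info(
            "load: outcome=%d smoking=%d population=%d gold=%d rows",
            len(outcome), len(smoking), len(population), len(gold),
        )

    with _Stage("prepare"):
        rates = outcome[["domain", "wave", "labor_force_rate"]].drop_duplicates()
        rates = rates.rename(columns={"labor_force_rate": "rate"})
        lf = design.center_labor_force(rates)
        outcome = outcome.merge(
            lf[["domain", "wave", "lf_partic_c"]], on=["domain", "wave"]
        )
        outcome = glmm.rescale_weights(outcome)
        n_waves = int(outcome["wave"].nunique())

    with _Stage("fit"):
        fits = []
        for spec in config.model_specs(n_waves):
            fits.append(glmm.fit(outcome, spec))
            logger.info(
                "fit %s: aic=%.2f bic=%.2f converged=%s",
                spec.id, fits[-1].aic, fits[-1].bic, fits[-1].converged,
            )
        fits_path = out / "model_fits.json"
        fits_path.write_text(
            json.dumps([f.to_dict() for f in fits], indent=1, default=str)
        )
        written["model_fits"] = fits_path

    with _Stage("select"):
        best = glmm.select_model(fits)
        logger.info("select: %s (aic=%.2f)", best.spec.id, best.aic)
        sel_path = out / "selected_model.json"
        sel_path.write_text(json.dumps(best.to_dict(), indent=1, default=str))
        written["selected_model"] = sel_path

    with _Stage("predict"):
        predictions = glmm.predict_cells(best, lf)
        written["cell_predictions"] = tableio.write_table(
            predictions, out / "cell_predictions.csv"
        )
        logger.info("predict: %d cell predictions", len(predictions))

    with _Stage("frame"):
        frame, margins = frame_builder.build_frame(smoking, population)
        written["frame"] = tableio.write_table(frame, out / "frame.csv")
        written["margins"] = tableio.write_table(margins, out / "margins.csv")
        logger.info("frame: %d cells", len(frame))

    with _Stage("estimate"):
        estimates = poststratify.subgroup_estimates(predictions, frame)
        logger.info("estimate: %d rows", len(estimates))

    if config.n_replicates >= 2:
        with _Stage("bootstrap"):
            ci = uncertainty.bootstrap_pipeline(
                outcome, frame, best.spec, lf, config.bootstrap
            )
            estimates = estimates.merge(
                ci[["domain", "wave", "subgroup", "ci_low", "ci_high"]],
                on=["domain", "wave", "subgroup"],
                how="left",
            )
    written["estimates"] = tableio.write_table(estimates, out / "estimates.csv")

    with _Stage("validate"):
        report = validation.agreement_report(estimates, gold)
        written["validation"] = tableio.write_table(report, out / "validation.csv")
        if truth is not None:
            truth_agg = synthetic.true_subgroup_aggregates(truth)
            metrics = validation.recovery_metrics(estimates, truth_agg)
            rec_path = out / "recovery.json"
            rec_path.write_text(json.dumps(metrics, indent=1))
            written["recovery"] = rec_path
            logger.info("recovery: %s", metrics)

    return written
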