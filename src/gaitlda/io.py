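"""Observation-table and model I/O, run configuration, and the pipeline
driver behind the command line.

Observation tables are plain CSV with the header
``dog_id, cohort_label, age_days, sf, reg, tp, ccp_tp, dvp_tp, mlp_tp,
sl_hw``; power fractions are stored in [0, 1].  Tables whose fraction
columns sum to ~100 (percent-scaled exports) are auto-detected and rescaled
on read with a logged warning.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import lda, models, phenotype, synthetic, treatment
from .synthetic import GAIT_VARIABLES, OBS_COLUMNS, POWER_FRACTIONS

logger = logging.getLogger(__name__)

FRACTION_SUM_TOL = 0.02


class ObservationFormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# observation tables
# ---------------------------------------------------------------------------

def write_observations(observations: pd.DataFrame, path) -> None:
    observations.to_csv(path, index=False, columns=OBS_COLUMNS,
                        float_format="%.12g")


def read_observations(path) -> pd.DataFrame:
    """Read and validate an observation table.

    Rejects malformed headers, missing/non-numeric values and rows whose
    power fractions do not sum to 1 (or 100 for percent-scaled files, which
    are rescaled with a warning), reporting offending row numbers (1-based,
    excluding the header).
    """
    df = pd.read_csv(path)
    missing = [c for c in OBS_COLUMNS if c not in df.columns]
    if missing:
        raise ObservationFormatError(
            f"{path}: missing required columns {missing}")
    df = df[OBS_COLUMNS].copy()
    numeric = ["age_days"] + GAIT_VARIABLES
    for col in numeric:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    bad = df[numeric].isna().any(axis=1)
    if bad.any():
        rows = (np.where(bad)[0] + 1).tolist()
        raise ObservationFormatError(
            f"{path}: missing or non-numeric values in rows {rows}")

    sums = df[POWER_FRACTIONS].sum(axis=1)
    median = float(sums.median())
    if 99.0 < median < 101.0:
        logger.warning("%s: power fractions look percent-scaled "
                       "(median sum %.2f); rescaling to [0, 1]", path, median)
        df[POWER_FRACTIONS] = df[POWER_FRACTIONS] / 100.0
        sums = sums / 100.0
    bad = (sums - 1.0).abs() > FRACTION_SUM_TOL
    if bad.any():
        rows = (np.where(bad)[0] + 1).tolist()
        raise ObservationFormatError(
            f"{path}: power fractions do not sum to 1 in rows {rows}")
    bad = (df["sf"] <= 0) | (df["tp"] <= 0) | (df["sl_hw"] <= 0) \
        | (df["age_days"] <= 0)
    if bad.any():
        rows = (np.where(bad)[0] + 1).tolist()
        raise ObservationFormatError(
            f"{path}: non-positive sf/tp/sl_hw/age_days in rows {rows}")
    return df


# ---------------------------------------------------------------------------
# fitted-model documents
# ---------------------------------------------------------------------------

def save_fitted_model(fitted: models.FittedGaitModel, path,
                      meta: dict | None = None) -> None:
    extra = {
        "model_name": fitted.spec.name,
        "explanatory": list(fitted.spec.explanatory),
        "month_length_days": fitted.spec.month_length_days,
        "class_table": {c: list(v) for c, v in fitted.class_table.items()},
        "ridge": fitted.ridge,
    }
    if meta:
        extra["meta"] = meta
    lda.save_model(fitted.model, path, extra=extra)


def load_fitted_model(path) -> models.FittedGaitModel:
    model, doc = lda.load_model(path)
    spec = models.model_spec(doc["model_name"],
                             month_length_days=doc["month_length_days"])
    class_table = {c: (v[0], None if v[1] is None else float(v[1]))
                   for c, v in doc["class_table"].items()}
    return models.FittedGaitModel(spec=spec, model=model,
                                  class_table=class_table,
                                  ridge=doc.get("ridge"))


# ---------------------------------------------------------------------------
# run configuration and pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Top-level pipeline configuration (YAML-loadable)."""

    out_dir: str = "gaitlda_run"
    model: int = 3
    priors: str = "proportional"
    month_length_days: float = synthetic.MONTH_DAYS
    lower_threshold: float = 0.05
    upper_threshold: float = 0.95
    reg_threshold: float = 70.0
    seed: int = 0
    verbosity: str = "INFO"
    input: str | None = None  # observation CSV; simulate when absent

    def __post_init__(self) -> None:
        if not 0 < self.lower_threshold < self.upper_threshold < 1:
            raise ValueError("thresholds must satisfy 0 < lower < upper < 1")

    def config_hash(self) -> str:
        doc = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(doc).hexdigest()[:16]


def load_run_config(path, **overrides) -> RunConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    doc.update({k: v for k, v in overrides.items() if v is not None})
    if "seed" not in doc:
        raise ValueError("a seed is mandatory (config file or --seed flag)")
    return RunConfig(**doc)


def run_pipeline(config: RunConfig) -> dict[str, str]:
    """simulate -> regularity filter -> fit -> leave-one-out -> blind
    classify -> treatment evaluation; writes every artifact under
    ``config.out_dir`` and a ``run_meta.json`` stamping all of them with
    the config hash and seed.  Identical configs produce identical
    artifacts."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.verbosity)
    artifacts: dict[str, str] = {}

    if config.input is None:
        cohort_cfg = synthetic.default_config(config.seed)
        obs = synthetic.simulate_cohort(cohort_cfg)
        write_observations(obs, out / "observations.csv")
        artifacts["observations"] = "observations.csv"
    else:
        obs = read_observations(config.input)
    obs = synthetic.apply_regularity_filter(obs, config.reg_threshold)

    spec = models.model_spec(config.model,
                             month_length_days=config.month_length_days)
    fitted = models.fit_model(obs, spec, priors=config.priors)
    save_fitted_model(fitted, out / "model.json",
                      meta={"config_hash": config.config_hash(),
                            "seed": config.seed})
    artifacts["model"] = "model.json"

    data, _ = models.build_design(obs, spec)
    report = models.run_report(fitted, data, loo=True, priors=config.priors)
    report["config_hash"] = config.config_hash()
    report["seed"] = config.seed
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1)
    artifacts["report"] = "report.json"

    if fitted.spec.with_age_classes:
        truth = {d: models.PHENOTYPE_OF_COHORT[c]
                 for d, c in obs.groupby("dog_id")["cohort_label"].first().items()}
        grid, per_dog, summary = phenotype.blind_test_report(
            fitted, obs, truth, config.lower_threshold, config.upper_threshold)
        grid.to_csv(out / "grid.csv", index=False, float_format="%.12g")
        per_dog.to_csv(out / "calls.csv", index=False)
        artifacts["grid"] = "grid.csv"
        artifacts["calls"] = "calls.csv"

        treated = obs[obs["cohort_label"] == synthetic.TREATED]
        if not treated.empty:
            trajs = [treatment.centroid_trajectory(fitted, obs, lab)
                     for lab in (synthetic.HEALTHY, synthetic.GRMD,
                                 synthetic.TREATED)]
            pd.concat([treatment.trajectory_table(t) for t in trajs]) \
                .to_csv(out / "trajectory.csv", index=False,
                        float_format="%.12g")
            artifacts["trajectory"] = "trajectory.csv"
            age_axis = None
            if fitted.spec.uses_age_explanatory:
                age_axis = treatment.project_age_axis(fitted, obs)
            treatment.plot_treatment(fitted, trajs, age_axis,
                                     path=out / "treatment.png")
            artifacts["plot"] = "treatment.png"

    meta = {"config": asdict(config), "config_hash": config.config_hash(),
            "seed": config.seed, "artifacts": artifacts}
    with open(out / "run_meta.json", "w") as fh:
        json.dump(meta, fh, indent=1)
    artifacts["run_meta"] = "run_meta.json"
    return artifacts
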