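"""The three discriminant model designs over gait observation tables.

* **Model 1** — genotype (Healthy vs GRMD) as the dependent variable, the
  seven gait parameters as explanatory variables.  Two groups, hence a
  single canonical axis.
* **Model 2** — dependent classes are genotype x half-month age class
  (``GRMD_2`` ... ``GRMD_12``, ``Healthy_2`` ... ``Healthy_9.5``); same
  seven explanatory variables.
* **Model 3** — Model 2's classes, with age in days added as an eighth
  explanatory variable, which stretches the factorial plane along age and
  separates neighbouring age classes.

Age classes are half-month bins by the floor convention (a 2.49-month dog
is in class 2.0) with a month of 30.4375 days (365.25/12).  Classes with
fewer than ``min_class_size`` observations are dropped with a warning; the
realized class count is reported rather than forced.
"""

from __future__ import annotations

import logging

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import lda
from .lda import LabeledMatrix, LDAModel
from .synthetic import GAIT_VARIABLES, GRMD, HEALTHY, MONTH_DAYS, TREATED

logger = logging.getLogger(__name__)

PHENOTYPES = (HEALTHY, GRMD)
#: cohort label -> phenotype used as (part of) the dependent class
PHENOTYPE_OF_COHORT = {HEALTHY: HEALTHY, GRMD: GRMD, TREATED: GRMD}


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one of the three model designs."""

    name: str                      # "model1" | "model2" | "model3"
    explanatory: tuple[str, ...]
    with_age_classes: bool
    month_length_days: float = MONTH_DAYS
    min_class_size: int = 3

    @property
    def uses_age_explanatory(self) -> bool:
        return "age_days" in self.explanatory


def model_spec(which: int | str, month_length_days: float = MONTH_DAYS,
               min_class_size: int = 3) -> ModelSpec:
    """Build the spec for model 1, 2 or 3."""
    name = f"model{which}" if isinstance(which, int) else str(which).lower()
    base = tuple(GAIT_VARIABLES)
    table = {
        "model1": (base, False),
        "model2": (base, True),
        "model3": (base + ("age_days",), True),
    }
    if name not in table:
        raise ValueError(f"unknown model {which!r}; expected 1, 2 or 3")
    explanatory, with_age = table[name]
    return ModelSpec(name=name, explanatory=explanatory,
                     with_age_classes=with_age,
                     month_length_days=month_length_days,
                     min_class_size=min_class_size)


#: ridge strength used when the seven-variable design is singular (the three
#: power fractions sum to 1 exactly, so the within-group scatter has a null
#: direction; both the data and the group means lie in the same hyperplane,
#: which makes this regularization essentially exact)
AUTO_RIDGE = 1e-8


@dataclass
class FittedGaitModel:
    spec: ModelSpec
    model: LDAModel
    #: class label -> (phenotype, age_class_months or None)
    class_table: dict[str, tuple[str, float | None]]
    #: ridge actually used by the fit (None = exact); LOO refits reuse it
    ridge: float | None = None

    @property
    def phenotype_map(self) -> dict[str, str]:
        return {cls: ph for cls, (ph, _age) in self.class_table.items()}


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def assign_age_group(age_days, month_length_days: float = MONTH_DAYS):
    """Half-month age class (in months) by the floor convention:
    ``floor(age_days / month_length_days / 0.5) * 0.5``."""
    a = np.asarray(age_days, dtype=float)
    if np.any(a <= 0):
        raise ValueError("age_days must be positive")
    cls = np.floor(a / month_length_days / 0.5) * 0.5
    return float(cls) if np.isscalar(age_days) else cls


def _format_class(phenotype: str, age_class: float) -> str:
    return f"{phenotype}_{age_class:g}"


def build_design(observations: pd.DataFrame, spec: ModelSpec
                 ) -> tuple[LabeledMatrix, dict[str, tuple[str, float | None]]]:
    """Construct the labeled explanatory matrix for a model spec.

    Observations should already be regularity-filtered.  Rows from cohorts
    other than Healthy/GRMD (e.g. a treated cohort) are excluded from
    training.  Tiny classes (< ``spec.min_class_size`` rows) are dropped
    with a logged warning.
    """
    df = observations[observations["cohort_label"].isin(PHENOTYPES)]
    if df.empty:
        raise ValueError("no Healthy/GRMD observations to train on")
    phenotype = df["cohort_label"].map(PHENOTYPE_OF_COHORT)

    if spec.with_age_classes:
        age_class = assign_age_group(df["age_days"].to_numpy(),
                                     spec.month_length_days)
        labels = np.array([_format_class(ph, ac)
                           for ph, ac in zip(phenotype, age_class)])
        class_table = {_format_class(ph, ac): (ph, float(ac))
                       for ph, ac in zip(phenotype, age_class)}
    else:
        labels = phenotype.to_numpy()
        age_class = None
        class_table = {ph: (ph, None) for ph in np.unique(labels)}

    # drop under-populated classes
    uniq, counts = np.unique(labels, return_counts=True)
    tiny = set(uniq[counts < spec.min_class_size])
    if tiny:
        logger.warning("dropping %d class(es) with < %d observations: %s",
                       len(tiny), spec.min_class_size, sorted(tiny))
        keep = ~np.isin(labels, list(tiny))
        df, labels = df[keep], labels[keep]
        class_table = {c: v for c, v in class_table.items() if c not in tiny}
    uniq, counts = np.unique(labels, return_counts=True)
    if np.any(counts < 2):
        bad = uniq[counts < 2].tolist()
        raise ValueError(f"classes with fewer than 2 observations: {bad}")

    missing = [v for v in spec.explanatory if v not in df.columns]
    if missing:
        raise ValueError(f"explanatory variables absent from table: {missing}")
    X = df[list(spec.explanatory)].to_numpy(dtype=float)
    row_ids = [f"{d}@{a:.1f}" for d, a in zip(df["dog_id"], df["age_days"])]
    data = LabeledMatrix(X=X, y=labels,
                         variable_names=list(spec.explanatory),
                         row_ids=row_ids)
    return data, class_table


def fit_model(observations: pd.DataFrame, spec: ModelSpec,
              priors="proportional", ridge="auto") -> FittedGaitModel:
    """Build the design for ``spec`` and fit the canonical LDA.

    ``ridge="auto"`` (default) first attempts an exact fit and, if the
    pooled covariance is singular — which the power-fraction closure
    guarantees whenever all three fractions are explanatory — retries with
    the small trace-scaled ridge ``AUTO_RIDGE``, logging a notice.  Pass
    ``ridge=None`` to forbid regularization or a float to force it.
    """
    data, class_table = build_design(observations, spec)
    if ridge == "auto":
        try:
            model = lda.fit_lda(data, priors=priors, ridge=None)
            used = None
        except lda.FitError as err:
            if "singular" not in str(err):
                raise
            logger.info("pooled covariance singular (%s); refitting with "
                        "ridge %.0e", err, AUTO_RIDGE)
            model = lda.fit_lda(data, priors=priors, ridge=AUTO_RIDGE)
            used = AUTO_RIDGE
    else:
        model = lda.fit_lda(data, priors=priors, ridge=ridge)
        used = ridge
    return FittedGaitModel(spec=spec, model=model, class_table=class_table,
                           ridge=used)


# ---------------------------------------------------------------------------
# reporting helpers
# ---------------------------------------------------------------------------

def phenotype_axis(fitted: FittedGaitModel) -> int:
    """Index of the canonical axis that discriminates phenotype, detected
    empirically since axis ordering depends on the data: the axis with the
    largest between-phenotype centroid gap *relative to* the within-
    phenotype spread of class centroids.  The standardization matters for
    age-augmented fits, where an asymmetric sampling schedule (dystrophic
    dogs followed longer) shifts the raw mean of the age axis between
    phenotypes even though that axis orders classes by age, not genotype."""
    model = fitted.model
    pheno = np.array([fitted.class_table[str(g)][0] for g in model.groups])
    h = model.centroid_scores[pheno == HEALTHY]
    g = model.centroid_scores[pheno == GRMD]
    gap = np.abs(h.mean(axis=0) - g.mean(axis=0))
    spread = np.sqrt(h.var(axis=0) + g.var(axis=0)) + 1e-12
    return int(np.argmax(gap / spread))


def run_report(fitted: FittedGaitModel, data: LabeledMatrix | None = None,
               loo: bool = False, priors="proportional") -> dict:
    """Summary of a fit: variance explained and canonical correlations of
    the leading axes, realized class count, and (optionally) leave-one-out
    confusion at class and phenotype level."""
    m = fitted.model
    report = {
        "model": fitted.spec.name,
        "n_classes": m.n_groups,
        "n_axes": m.n_axes,
        "explanatory": list(fitted.spec.explanatory),
        "eigenvalues": m.eigenvalues.tolist(),
        "canonical_correlations": m.canonical_correlations.tolist(),
        "variance_explained": m.variance_explained.tolist(),
        "variance_explained_f1_f2": float(m.variance_explained[:2].sum()),
        "phenotype_axis": phenotype_axis(fitted) if fitted.spec.with_age_classes
        else 0,
    }
    if loo:
        if data is None:
            raise ValueError("leave-one-out report needs the training data")
        cm = lda.loo_misclassification(data, priors=priors,
                                       ridge=fitted.ridge)
        collapsed = lda.collapse_confusion_to_phenotype(
            cm, {g: fitted.class_table[str(g)][0] for g in cm.labels})
        report["loo"] = {
            "labels": [str(v) for v in cm.labels],
            "counts": cm.counts.tolist(),
            "misclassification_rate": cm.misclassification_rate,
            "phenotype_misclassification_rate": collapsed.misclassification_rate,
        }
    return report
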