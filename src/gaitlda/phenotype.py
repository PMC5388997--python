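"""Blind-test decision rule: per-timepoint healthy-membership probability,
three-way thresholding, and a per-dog majority call.

For each time point the posterior mass on all Healthy-labelled classes is
summed and averaged over that session's replicate sequences, giving the
session's healthy-membership probability ``p``.  The call is three-way with
strict inequalities: ``p > 0.95`` healthy-like, ``p < 0.05`` GRMD-like,
anything in between an intermediate gait.  A dog is called Healthy (GRMD)
when strictly more than half of its time points are healthy-like
(GRMD-like); ties and fragmented call patterns are inconclusive ("n.c.").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import lda
from .models import FittedGaitModel
from .synthetic import HEALTHY, GRMD

logger = logging.getLogger(__name__)

HEALTHY_LIKE, GRMD_LIKE, INTERMEDIATE = "healthy_like", "grmd_like", "intermediate"
INCONCLUSIVE = "inconclusive"

UPPER_THRESHOLD = 0.95
LOWER_THRESHOLD = 0.05


@dataclass(frozen=True)
class TimepointCall:
    dog_id: str
    age_days: float
    p_healthy: float
    call: str


@dataclass(frozen=True)
class DogCall:
    dog_id: str
    timepoint_calls: tuple[TimepointCall, ...]
    final: str  # Healthy | GRMD | inconclusive


def healthy_membership(fitted: FittedGaitModel, x: np.ndarray):
    """Posterior probability that an observation's gait belongs to any
    Healthy class.  Accepts a single explanatory vector or an (n, p)
    batch."""
    pmap = fitted.phenotype_map
    missing = [str(g) for g in fitted.model.groups if str(g) not in pmap]
    if missing:
        raise ValueError(f"model classes without phenotype mapping: {missing}")
    mask = np.array([pmap[str(g)] == HEALTHY for g in fitted.model.groups])
    post = lda.posterior_probabilities(fitted.model, x)
    if post.ndim == 1:
        return float(post[mask].sum())
    return post[:, mask].sum(axis=1)


def _threshold_call(p: float, lower: float = LOWER_THRESHOLD,
                    upper: float = UPPER_THRESHOLD) -> str:
    if p > upper:
        return HEALTHY_LIKE
    if p < lower:
        return GRMD_LIKE
    return INTERMEDIATE


def call_timepoint(fitted: FittedGaitModel, session: pd.DataFrame,
                   lower: float = LOWER_THRESHOLD,
                   upper: float = UPPER_THRESHOLD) -> TimepointCall:
    """Call one session (all replicate sequences of one dog at one age):
    average the healthy membership over replicates and threshold."""
    if session.empty:
        raise ValueError("empty session")
    dogs = session["dog_id"].unique()
    if len(dogs) != 1:
        raise ValueError(f"a session must belong to a single dog, got {dogs}")
    X = session[list(fitted.spec.explanatory)].to_numpy(dtype=float)
    p = float(np.mean(healthy_membership(fitted, X)))
    return TimepointCall(dog_id=str(dogs[0]),
                         age_days=float(session["age_days"].iloc[0]),
                         p_healthy=p, call=_threshold_call(p, lower, upper))


def call_dog(timepoint_calls) -> DogCall:
    """Strict-majority rule over a dog's time points."""
    calls = tuple(timepoint_calls)
    if not calls:
        raise ValueError("need at least one timepoint call")
    n = len(calls)
    n_healthy = sum(c.call == HEALTHY_LIKE for c in calls)
    n_grmd = sum(c.call == GRMD_LIKE for c in calls)
    if n_healthy * 2 > n:
        final = HEALTHY
    elif n_grmd * 2 > n:
        final = GRMD
    else:
        final = INCONCLUSIVE
    return DogCall(dog_id=calls[0].dog_id, timepoint_calls=calls, final=final)


def blind_test_report(fitted: FittedGaitModel, observations: pd.DataFrame,
                      true_labels: dict[str, str] | None = None,
                      lower: float = LOWER_THRESHOLD,
                      upper: float = UPPER_THRESHOLD
                      ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Classify every dog in a cohort, blind to its label.

    Returns ``(grid, per_dog, summary)``: a tidy per-dog-per-timepoint grid
    (one row per session — dogs as grid rows, time points as columns once
    pivoted), a per-dog table with the final call, and an accuracy summary
    when true labels are supplied.  Missing sessions are simply absent
    rows/cells.
    """
    grid_rows, dog_rows = [], []
    n_correct = n_truth = 0
    for dog_id, dog_obs in observations.groupby("dog_id", sort=True):
        calls = []
        for age, session in dog_obs.groupby("age_days", sort=True):
            calls.append(call_timepoint(fitted, session, lower, upper))
        if calls:
            dog_call = call_dog(calls)
        else:  # pragma: no cover - groupby never yields empty groups
            logger.warning("dog %s has no usable sessions; inconclusive", dog_id)
            dog_call = DogCall(dog_id=str(dog_id), timepoint_calls=(),
                               final=INCONCLUSIVE)
        for c in dog_call.timepoint_calls:
            grid_rows.append({"dog_id": c.dog_id, "age_days": c.age_days,
                              "p_healthy": c.p_healthy, "call": c.call})
        row = {"dog_id": str(dog_id), "n_timepoints": len(calls),
               "predicted": dog_call.final}
        if true_labels is not None:
            truth = true_labels.get(str(dog_id))
            row["truth"] = truth
            if truth is not None:
                n_truth += 1
                n_correct += dog_call.final == truth
        dog_rows.append(row)
    grid = pd.DataFrame(grid_rows)
    per_dog = pd.DataFrame(dog_rows)
    summary = {"n_dogs": len(dog_rows)}
    if true_labels is not None:
        summary.update({"n_with_truth": n_truth, "n_correct": n_correct,
                        "accuracy": n_correct / n_truth if n_truth else float("nan")})
    return grid, per_dog, summary
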