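"""Synthetic longitudinal gait cohorts for the GRMD-vs-healthy analysis.

The generator emulates an accelerometric gait study in growing dogs: each
dog walks a test corridor twice a month from 2 months of age to 9.5 months
(healthy) or 12 months (dystrophic, GRMD), and every session yields one or
two 10-second steady-state locomotion sequences summarized by seven gait
parameters:

====== ======================================================== =========
symbol meaning                                                  unit
====== ======================================================== =========
sf     stride frequency                                         strides/s
reg    stride regularity (similarity of successive strides)     unitless
tp     total power of trunk accelerations                       W/kg
ccp_tp cranio-caudal fraction of total power                    in [0, 1]
dvp_tp dorso-ventral fraction of total power                    in [0, 1]
mlp_tp medio-lateral fraction of total power                    in [0, 1]
sl_hw  stride length normalized to height at withers            unitless
====== ======================================================== =========

Dystrophic gait has lower power, regularity, stride frequency and relative
stride length, and shifts acceleration power from the cranio-caudal to the
medio-lateral axis.  Observations are drawn from a multivariate Gaussian
around cohort mean trajectories with a single within-group covariance
shared by all cohorts and ages — exactly the homoscedasticity assumption of
the downstream linear discriminant analysis, which makes the generator a
faithful null for it.  Per-dog random intercepts model inter-individual
variability; a uniform birth-date jitter desynchronizes age-in-days within
a sampling session; the second sequence of a session drops out with a
cohort-specific probability (dystrophic dogs often cannot complete it).
"""

from __future__ import annotations

import math
from dataclasses import dataclass


import numpy as np
import pandas as pd

GAIT_VARIABLES = ["sf", "reg", "tp", "ccp_tp", "dvp_tp", "mlp_tp", "sl_hw"]
POWER_FRACTIONS = ["ccp_tp", "dvp_tp", "mlp_tp"]
OBS_COLUMNS = ["dog_id", "cohort_label", "age_days"] + GAIT_VARIABLES

HEALTHY, GRMD, TREATED = "Healthy", "GRMD", "GRMD_treated"
COHORTS = (HEALTHY, GRMD, TREATED)

MONTH_DAYS = 30.4375  # 365.25 / 12


class ConfigurationError(ValueError):
    """Raised for an invalid cohort configuration."""


@dataclass(frozen=True)
class Trajectory:
    """Cohort mean of one gait variable as a function of age.

    Linear in age (months), optionally flattening beyond ``saturation_month``:
    ``mean(a) = intercept + slope * min(a, saturation_month)``.
    """

    intercept: float
    slope: float = 0.0
    saturation_month: float | None = None

    def __call__(self, age_months):
        a = np.asarray(age_months, dtype=float)
        if self.saturation_month is not None:
            a = np.minimum(a, self.saturation_month)
        return self.intercept + self.slope * a


@dataclass(frozen=True)
class Schedule:
    """Sampling schedule: sessions every ``interval_days`` from
    ``start_age_days`` up to and including ``end_age_days``."""

    start_age_days: float
    end_age_days: float
    interval_days: float = 15.0

    def nominal_ages(self) -> np.ndarray:
        k = int(math.floor((self.end_age_days - self.start_age_days)
                           / self.interval_days + 1e-9))
        return self.start_age_days + self.interval_days * np.arange(k + 1)


@dataclass
class CohortConfig:
    """Everything the generator needs; ``default_config`` fills realistic
    values.  The treated cohort's mean is derived per observation as
    ``GRMD + f(age) * (Healthy - GRMD)`` with the treatment fraction
    ``f(age)`` decaying linearly from ``treatment_fraction_start`` at
    ``treatment_age_start_months`` to 0 at ``treatment_age_end_months``
    (clipped to [0, 1])."""

    n_healthy: int
    n_grmd: int
    n_treated: int
    schedules: dict[str, Schedule]
    trajectories: dict[str, dict[str, Trajectory]]  # cohort -> var -> traj
    covariance: np.ndarray                          # (7, 7) shared
    random_intercept_sd: dict[str, float]
    dropout_second: dict[str, float]
    age_jitter_days: float = 7.0
    repeats_per_session: int = 2
    treatment_fraction_start: float = 0.9
    treatment_age_start_months: float = 2.0
    treatment_age_end_months: float = 7.0
    #: when set, overrides the decaying fraction with a constant in [0, 1]
    treatment_fraction_constant: float | None = None
    right_truncation_days: dict[str, float] | None = None  # dog_id -> max age
    seed: int = 0

    def treatment_fraction(self, age_months) -> np.ndarray:
        if self.treatment_fraction_constant is not None:
            return np.clip(np.full_like(np.asarray(age_months, dtype=float),
                                        self.treatment_fraction_constant),
                           0.0, 1.0)
        a0, a1 = self.treatment_age_start_months, self.treatment_age_end_months
        f = self.treatment_fraction_start * (a1 - np.asarray(age_months)) / (a1 - a0)
        return np.clip(f, 0.0, 1.0)

    def validate(self) -> None:
        cov = np.asarray(self.covariance, dtype=float)
        if cov.shape != (7, 7) or not np.allclose(cov, cov.T):
            raise ConfigurationError("covariance must be a symmetric 7x7 matrix")
        if np.linalg.eigvalsh(cov).min() <= 0:
            raise ConfigurationError("covariance must be positive definite")
        if not 0 <= self.treatment_fraction_start <= 1:
            raise ConfigurationError("treatment fraction must lie in [0, 1]")
        for label, p in self.dropout_second.items():
            if not 0 <= p <= 1:
                raise ConfigurationError(f"dropout probability for {label} not in [0, 1]")


# ---------------------------------------------------------------------------
# defaults
# ---------------------------------------------------------------------------

_DEFAULT_SD = {"sf": 0.25, "reg": 35.0, "tp": 3.0,
               "ccp_tp": 0.035, "dvp_tp": 0.035, "mlp_tp": 0.030,
               "sl_hw": 0.10}

# modest cross-correlations; power fractions trade off against each other
_DEFAULT_CORR = {
    ("sf", "tp"): 0.20, ("tp", "sl_hw"): 0.40, ("reg", "tp"): 0.30,
    ("ccp_tp", "mlp_tp"): -0.50, ("ccp_tp", "dvp_tp"): -0.30,
    ("dvp_tp", "mlp_tp"): -0.30,
}


def _default_covariance() -> np.ndarray:
    k = len(GAIT_VARIABLES)
    R = np.eye(k)
    idx = {v: i for i, v in enumerate(GAIT_VARIABLES)}
    for (a, b), r in _DEFAULT_CORR.items():
        R[idx[a], idx[b]] = R[idx[b], idx[a]] = r
    d = np.array([_DEFAULT_SD[v] for v in GAIT_VARIABLES])
    return R * np.outer(d, d)


def default_config(seed: int) -> CohortConfig:
    """Default study conditions: 8 healthy and 20 GRMD dogs sampled every
    15 days (2->9.5 and 2->12 months respectively), 6 treated GRMD dogs on
    the healthy schedule, +/-7-day birth-date jitter, two sequences per
    session with dystrophic-biased dropout of the second.

    Mean trajectories encode the dystrophic gait signature: lower total
    power, regularity, stride frequency and stride length, and a
    cranio-caudal -> medio-lateral power shift, at every sampled age.  Age
    slopes are small relative to the within-group spread, so adjacent
    half-month classes overlap heavily while genotypes stay well separated.
    Only the ``seed`` field varies with the argument.
    """
    trajectories = {
        HEALTHY: {
            "sf": Trajectory(2.90, -0.050),
            "reg": Trajectory(280.0, 4.0),
            "tp": Trajectory(18.0, 2.2),
            "ccp_tp": Trajectory(0.340, 0.004),
            "dvp_tp": Trajectory(0.450, -0.002),
            "mlp_tp": Trajectory(0.210, -0.002),
            "sl_hw": Trajectory(1.15, 0.020),
        },
        GRMD: {
            "sf": Trajectory(2.40, -0.080),
            "reg": Trajectory(200.0, -8.0),
            "tp": Trajectory(11.0, 0.30),
            "ccp_tp": Trajectory(0.260, -0.003),
            "dvp_tp": Trajectory(0.440, 0.000),
            "mlp_tp": Trajectory(0.300, 0.003),
            "sl_hw": Trajectory(0.95, -0.010),
        },
    }
    # nominal sessions start at 68 d so that even a -7 d birth jitter keeps
    # the first observation in the 2.0-month class, and end just past the
    # target ages so the realized classes span 2.0-9.5 (healthy, treated)
    # and 2.0-12.0 (dystrophic) months
    schedules = {
        HEALTHY: Schedule(68.0, 296.0),
        GRMD: Schedule(68.0, 372.0),
        # treated dogs follow the healthy schedule so each of their age
        # classes has a same-age healthy reference
        TREATED: Schedule(68.0, 296.0),
    }
    return CohortConfig(
        n_healthy=8,
        n_grmd=20,
        n_treated=6,
        schedules=schedules,
        trajectories=trajectories,
        covariance=_default_covariance(),
        random_intercept_sd={"sf": 0.08, "reg": 12.0, "tp": 1.0,
                             "ccp_tp": 0.010, "dvp_tp": 0.010,
                             "mlp_tp": 0.010, "sl_hw": 0.03},
        dropout_second={HEALTHY: 0.05, GRMD: 0.35, TREATED: 0.25},
        seed=int(seed),
    )


def scaled_effect_config(seed: int, effect: float) -> CohortConfig:
    """Default config with the genotype effect scaled: GRMD (and treated)
    trajectories are moved toward the healthy ones so that the mean gap at
    every age is ``effect`` times the default gap.  ``effect=0`` makes the
    genotypes exchangeable (a null cohort); ``effect=1`` is the default."""
    cfg = default_config(seed)
    healthy = cfg.trajectories[HEALTHY]
    grmd = cfg.trajectories[GRMD]
    shrunk = {}
    for v in GAIT_VARIABLES:
        h, g = healthy[v], grmd[v]
        shrunk[v] = Trajectory(
            intercept=h.intercept + effect * (g.intercept - h.intercept),
            slope=h.slope + effect * (g.slope - h.slope),
        )
    cfg.trajectories = {HEALTHY: healthy, GRMD: shrunk}
    return cfg


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def cohort_mean(config: CohortConfig, label: str, age_months: float) -> np.ndarray:
    """Generative mean vector for a cohort at an age (months)."""
    if label == TREATED:
        h = cohort_mean(config, HEALTHY, age_months)
        g = cohort_mean(config, GRMD, age_months)
        f = float(config.treatment_fraction(age_months))
        return g + f * (h - g)
    traj = config.trajectories[label]
    return np.array([traj[v](age_months) for v in GAIT_VARIABLES])


_FRACTION_EPS = 1e-6
_POSITIVE_FLOOR = 1e-3  # sf, tp, sl_hw are physically positive


def _finalize(values: np.ndarray) -> np.ndarray:
    """Enforce row invariants: power fractions clipped to (0, 1) and
    renormalized to sum exactly 1; strictly positive sf/tp/sl_hw."""
    idx = [GAIT_VARIABLES.index(v) for v in POWER_FRACTIONS]
    frac = np.clip(values[:, idx], _FRACTION_EPS, 1 - _FRACTION_EPS)
    values[:, idx] = frac / frac.sum(axis=1, keepdims=True)
    for v in ("sf", "tp", "sl_hw"):
        j = GAIT_VARIABLES.index(v)
        values[:, j] = np.maximum(values[:, j], _POSITIVE_FLOOR)
    return values


def simulate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Draw a full longitudinal cohort.

    Returns a tidy frame with columns ``dog_id, cohort_label, age_days``
    plus the seven gait variables.  Regularity is emitted unbounded
    (Gaussian); apply :func:`apply_regularity_filter` afterwards, mirroring
    the post-hoc exclusion used on real recordings.  Bit-identical output
    for a fixed config (including seed).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    L = np.linalg.cholesky(np.asarray(config.covariance, dtype=float))
    sd_vec = np.array([config.random_intercept_sd[v] for v in GAIT_VARIABLES])
    trunc = config.right_truncation_days or {}

    counts = {HEALTHY: config.n_healthy, GRMD: config.n_grmd,
              TREATED: config.n_treated}
    prefix = {HEALTHY: "H", GRMD: "G", TREATED: "T"}
    rows = []
    for label in COHORTS:
        schedule = config.schedules[label]
        ages = schedule.nominal_ages()
        for d in range(counts[label]):
            dog_id = f"{prefix[label]}{d + 1:02d}"
            offset = rng.uniform(-config.age_jitter_days, config.age_jitter_days)
            intercept = rng.normal(0.0, 1.0, size=len(GAIT_VARIABLES)) * sd_vec
            for nominal in ages:
                age = nominal + offset
                if dog_id in trunc and age > trunc[dog_id]:
                    continue
                nreps = config.repeats_per_session
                if nreps >= 2 and rng.uniform() < config.dropout_second[label]:
                    nreps -= 1
                mean = cohort_mean(config, label, age / MONTH_DAYS) + intercept
                z = rng.standard_normal((nreps, len(GAIT_VARIABLES)))
                values = _finalize(mean + z @ L.T)
                for rep in range(nreps):
                    rows.append((dog_id, label, age, *values[rep]))
    df = pd.DataFrame(rows, columns=OBS_COLUMNS)
    return df


def apply_regularity_filter(observations: pd.DataFrame,
                            threshold: float = 70.0) -> pd.DataFrame:
    """Keep only observations with regularity strictly above ``threshold``
    (default 70); order preserved."""
    return observations[observations["reg"] > threshold]
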