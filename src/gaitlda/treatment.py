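"""Treatment evaluation on the factorial plane.

A treated cohort is projected onto the fitted model's first two canonical
axes; per half-month age class the centroid, a 95% confidence region of
the mean (standard-error ellipse — deliberately distinct from the
observation-coverage ellipses drawn around training classes), and a
traffic-light colour are computed.  The colour follows the membership rule:
mean healthy-membership probability of the class's observations > 0.95 is
green (healthy-like gait), < 0.05 red (dystrophic-like), otherwise yellow
(intermediate).  For readability a calibrated age-in-days axis is
projected onto the plane by regressing age on the (F1, F2) scores of the
training data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import lda, phenotype as ph
from .lda import Ellipse
from .models import FittedGaitModel, assign_age_group, build_design
from .synthetic import MONTH_DAYS

logger = logging.getLogger(__name__)

GREEN, YELLOW, RED = "green", "yellow", "red"


@dataclass
class CentroidTrajectory:
    cohort_label: str
    age_classes: np.ndarray        # strictly increasing, months
    centroids: np.ndarray          # (k, 2) in the (F1, F2) plane
    ellipses: list[Ellipse | None] # 95% regions of the mean (None if n < 3)
    n_obs: np.ndarray
    colors: list[str]
    mean_membership: np.ndarray


@dataclass
class AgeAxis:
    """Calibrated age axis in the factorial plane: unit ``direction``,
    ``days_per_unit`` score, intercept (predicted age at the plane origin)
    and whole-month tick positions."""

    direction: np.ndarray
    days_per_unit: float
    intercept_days: float
    ticks: list[tuple[float, np.ndarray]]  # (age_months, xy position)


def color_code(mean_membership: float,
               lower: float = ph.LOWER_THRESHOLD,
               upper: float = ph.UPPER_THRESHOLD) -> str:
    if mean_membership > upper:
        return GREEN
    if mean_membership < lower:
        return RED
    return YELLOW


def centroid_trajectory(fitted: FittedGaitModel, observations: pd.DataFrame,
                        cohort_label: str | None = None,
                        axes: tuple[int, int] = (0, 1),
                        level: float = 0.95) -> CentroidTrajectory:
    """Centroid trajectory of a cohort across half-month age classes.

    ``observations`` must carry the model's explanatory variables (with
    ``age_days``, the eighth variable of an age-augmented fit, taken from
    the table).  Age classes with fewer than 2 observations are skipped
    with a warning; the mean-confidence ellipse additionally needs >= 3.
    """
    df = observations
    if cohort_label is not None:
        df = df[df["cohort_label"] == cohort_label]
    if df.empty:
        raise ValueError(f"no observations for cohort {cohort_label!r}")
    label = cohort_label if cohort_label is not None else "cohort"
    age_cls = assign_age_group(df["age_days"].to_numpy(),
                               fitted.spec.month_length_days)
    X = df[list(fitted.spec.explanatory)].to_numpy(dtype=float)
    scores = lda.transform(fitted.model, X)[:, list(axes)]
    membership = ph.healthy_membership(fitted, X)

    classes, centroids, ellipses, ns, colors, memb = [], [], [], [], [], []
    for cls in np.unique(age_cls):
        sel = age_cls == cls
        n = int(sel.sum())
        if n < 2:
            logger.warning("skipping age class %g with %d observation(s)", cls, n)
            continue
        sc = scores[sel]
        try:
            ell = lda.confidence_ellipse(sc, level=level, of_mean=True) \
                if n >= 3 else None
        except ValueError:
            ell = None
        m = float(np.mean(membership[sel]))
        classes.append(float(cls))
        centroids.append(sc.mean(axis=0))
        ellipses.append(ell)
        ns.append(n)
        memb.append(m)
        colors.append(color_code(m))
    if not classes:
        raise ValueError("no age class has enough observations")
    return CentroidTrajectory(
        cohort_label=label,
        age_classes=np.array(classes),
        centroids=np.vstack(centroids),
        ellipses=ellipses,
        n_obs=np.array(ns),
        colors=colors,
        mean_membership=np.array(memb),
    )


def project_age_axis(fitted: FittedGaitModel,
                     training_observations: pd.DataFrame,
                     axes: tuple[int, int] = (0, 1)) -> AgeAxis:
    """Project the age-in-days axis onto the factorial plane.

    Least-squares regression of age on the (F1, F2) training scores gives
    the in-plane age gradient; the returned axis has the unit gradient
    direction, a days-per-unit-score scale, and tick positions at whole
    months spanning the training ages.  Requires an age-augmented (Model 3
    style) fit, where age genuinely lives in the plane.
    """
    data, _ = build_design(training_observations, fitted.spec)
    scores = lda.transform(fitted.model, data.X)[:, list(axes)]
    if "age_days" in data.variable_names:
        age = data.X[:, data.variable_names.index("age_days")]
    else:
        raise ValueError("age axis projection needs age_days among the "
                         "explanatory variables (a model3-style fit)")
    A = np.column_stack([np.ones(len(age)), scores])
    beta, *_ = np.linalg.lstsq(A, age, rcond=None)
    intercept, grad = float(beta[0]), beta[1:]
    norm = float(np.linalg.norm(grad))
    if norm * float(np.std(scores)) < 1e-9 * max(float(np.std(age)), 1.0):
        raise ValueError("age is orthogonal to the factorial plane; "
                         "no age axis can be projected")
    direction = grad / norm
    months = np.arange(np.ceil(age.min() / MONTH_DAYS),
                       np.floor(age.max() / MONTH_DAYS) + 1)
    ticks = [(float(m), direction * (m * MONTH_DAYS - intercept) / norm)
             for m in months]
    return AgeAxis(direction=direction, days_per_unit=norm,
                   intercept_days=intercept, ticks=ticks)


def trajectory_table(traj: CentroidTrajectory) -> pd.DataFrame:
    """Flatten a trajectory for CSV export."""
    return pd.DataFrame({
        "cohort_label": traj.cohort_label,
        "age_class_months": traj.age_classes,
        "f1": traj.centroids[:, 0],
        "f2": traj.centroids[:, 1],
        "n_obs": traj.n_obs,
        "mean_p_healthy": traj.mean_membership,
        "color": traj.colors,
    })


def plot_treatment(fitted: FittedGaitModel,
                   trajectories: list[CentroidTrajectory],
                   age_axis: AgeAxis | None = None,
                   path=None, title: str | None = None):
    """Render the treatment-evaluation figure: centroid trajectories with
    mean-confidence ellipses and traffic-light colours on the (F1, F2)
    plane, variance-explained percentages in the axis labels, and the
    calibrated age axis along the top."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Ellipse as MplEllipse

    fig, ax = plt.subplots(figsize=(7, 6))
    base_color = {"Healthy": "tab:green", "GRMD": "tab:red"}
    for traj in trajectories:
        colored = traj.cohort_label not in base_color
        line_c = base_color.get(traj.cohort_label, "0.4")
        ax.plot(traj.centroids[:, 0], traj.centroids[:, 1], "-",
                color=line_c, lw=1.2, label=traj.cohort_label, zorder=2)
        pt_colors = traj.colors if colored else [line_c] * len(traj.colors)
        ax.scatter(traj.centroids[:, 0], traj.centroids[:, 1],
                   c=pt_colors, edgecolors="k", linewidths=0.4, s=36, zorder=3)
        for ell, c in zip(traj.ellipses, pt_colors):
            if ell is None:
                continue
            ax.add_patch(MplEllipse(ell.center, 2 * ell.axes[0], 2 * ell.axes[1],
                                    angle=np.degrees(ell.orientation),
                                    facecolor="none", edgecolor=c, alpha=0.6,
                                    zorder=1))
    ve = fitted.model.variance_explained
    ax.set_xlabel(f"F1 ({100 * ve[0]:.1f}%)")
    if len(ve) > 1:
        ax.set_ylabel(f"F2 ({100 * ve[1]:.1f}%)")
    if age_axis is not None:
        xs = np.array([pos for _, pos in age_axis.ticks])
        secax = ax.plot(xs[:, 0], xs[:, 1], color="0.2", lw=0.8, zorder=1)
        del secax
        for m, pos in age_axis.ticks:
            ax.annotate(f"{m:g}", pos, textcoords="offset points",
                        xytext=(0, 6), ha="center", fontsize=7, color="0.2")
        ax.annotate("age (months)", age_axis.ticks[-1][1],
                    textcoords="offset points", xytext=(12, 14), fontsize=8)
    if title:
        ax.set_title(title)
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
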