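"""Canonical linear discriminant analysis from first principles.

Fits discriminant axes by solving the generalized eigenproblem
``S_B v = lambda S_W v`` (between- vs pooled within-group scatter) through a
numerically stable route: Cholesky-whiten by ``S_W``, then a symmetric
eigendecomposition.  At most ``g - 1`` canonical axes exist for ``g`` groups.
Group-membership probabilities follow the homoscedastic Gaussian model
(shared pooled covariance), evaluated with a log-sum-exp-stable scheme.

Conventions (constant across runs and linear-algebra backends):

* axes are scaled so the pooled within-group variance of the canonical
  scores is 1;
* each axis is flipped so its largest-magnitude coefficient is positive;
* classification ties break to the first group in the model's (sorted)
  group order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import linalg as sla
from scipy.special import softmax
from scipy.stats import chi2

MODEL_FORMAT_VERSION = 1


class FitError(ValueError):
    """Raised when a discriminant model cannot be fitted."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class LabeledMatrix:
    """Explanatory matrix with group labels.

    Parameters
    ----------
    X : (n, p) array of explanatory values, one row per observation.
    y : length-n group labels.
    variable_names : names of the p columns.
    row_ids : optional observation identifiers (e.g. ``dog@age``).
    """

    X: np.ndarray
    y: np.ndarray
    variable_names: list[str]
    row_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if len(self.y) != self.X.shape[0]:
            raise ValueError("y length does not match X rows")
        if len(self.variable_names) != self.X.shape[1]:
            raise ValueError("variable_names length does not match X columns")
        if not np.all(np.isfinite(self.X)):
            bad = np.where(~np.isfinite(self.X).all(axis=1))[0]
            raise ValueError(f"missing/non-finite values in rows {bad.tolist()}")


@dataclass
class LDAModel:
    """A fitted canonical discriminant model.

    ``coeffs`` maps centered explanatory vectors to canonical scores
    (``F1..Fr``, ``r = min(g - 1, p)``).  ``eigenvalues`` are the generalized
    eigenvalues (between/within scatter ratios); the canonical correlation of
    axis i is ``sqrt(lambda_i / (1 + lambda_i))``.
    """

    groups: list
    priors: np.ndarray            # (g,)
    means: np.ndarray             # (g, p) group centroids, original space
    pooled_cov: np.ndarray        # (p, p), divisor n - g
    coeffs: np.ndarray            # (p, r)
    eigenvalues: np.ndarray       # (r,) non-increasing, >= 0
    canonical_correlations: np.ndarray
    variance_explained: np.ndarray
    centroid_scores: np.ndarray   # (g, r)
    variable_names: list[str]
    grand_mean: np.ndarray        # (p,) training grand mean (score origin)
    counts: np.ndarray = field(default=None)  # (g,) training group sizes

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def n_axes(self) -> int:
        return self.coeffs.shape[1]


@dataclass
class ConfusionMatrix:
    labels: list
    counts: np.ndarray  # (g, g), rows = true, cols = predicted

    @property
    def misclassification_rate(self) -> float:
        total = self.counts.sum()
        if total == 0:
            return 0.0
        return float((total - np.trace(self.counts)) / total)


@dataclass
class Ellipse:
    """Coverage ellipse of a bivariate-normal fit: ``center`` in the (F1, F2)
    plane, ``axes`` the half-axis lengths (non-increasing), ``orientation``
    the angle (radians) of the major axis, ``level`` the coverage
    probability."""

    center: np.ndarray
    axes: np.ndarray
    orientation: float
    level: float


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _group_stats(X: np.ndarray, y: np.ndarray):
    groups, inverse, counts = np.unique(y, return_inverse=True, return_counts=True)
    g = len(groups)
    p = X.shape[1]
    means = np.zeros((g, p))
    np.add.at(means, inverse, X)
    means /= counts[:, None]
    return groups, inverse, counts, means


def _resolve_priors(priors, counts: np.ndarray) -> np.ndarray:
    n = counts.sum()
    if priors is None:
        return counts / n
    if isinstance(priors, str):
        if priors == "proportional":
            return counts / n
        if priors == "equal":
            return np.full(len(counts), 1.0 / len(counts))
        raise ValueError(f"unknown prior convention {priors!r}")
    pr = np.asarray(priors, dtype=float)
    if pr.shape != counts.shape or np.any(pr < 0):
        raise ValueError("priors must be a non-negative vector, one per group")
    return pr / pr.sum()


def fit_lda(data: LabeledMatrix, priors="proportional", ridge: float | None = None) -> LDAModel:
    """Fit a canonical LDA maximizing between-group relative to within-group
    variance.

    Parameters
    ----------
    data : LabeledMatrix
        Training observations; every group needs >= 2 rows and
        ``n > p + g``.
    priors : "proportional" (group sizes; default), "equal", or a vector.
    ridge : optional regularization strength; adds
        ``ridge * trace(S_W)/p * I`` to the within-group scatter.  Off by
        default: a singular pooled covariance is a hard error.
    """
    X, y = data.X, data.y
    n, p = X.shape
    groups, inverse, counts, means = _group_stats(X, y)
    g = len(groups)
    if g < 2:
        raise FitError("need at least two groups")
    if counts.min() < 2:
        small = [str(groups[i]) for i in np.where(counts < 2)[0]]
        raise FitError(f"groups with fewer than 2 observations: {small}")
    if n <= p + g:
        raise FitError(f"need n > p + g observations (n={n}, p={p}, g={g})")

    centered = X - means[inverse]
    S_W = centered.T @ centered
    if ridge is not None:
        S_W = S_W + ridge * np.trace(S_W) / p * np.eye(p)

    grand = X.mean(axis=0)
    dm = means - grand
    S_B = (dm * counts[:, None]).T @ dm

    # detect rank deficiency before factorizing: Cholesky can survive an
    # exactly collinear scatter on a tiny rounding-noise pivot.  An explicit
    # ridge is taken at face value.
    w_sw, V_sw = sla.eigh(S_W)
    if ridge is None and w_sw[0] <= w_sw[-1] * 1e-10:
        null = V_sw[:, w_sw <= w_sw[-1] * 1e-10]
        offenders = [data.variable_names[j]
                     for j in np.unique(np.argmax(np.abs(null), axis=0))]
        raise FitError(
            "singular pooled within-group covariance (collinear variables "
            f"involving {offenders}); enable ridge regularization or drop one")
    L = sla.cholesky(S_W, lower=True)

    # whiten: M = L^-1 S_B L^-T is symmetric PSD with the same eigenvalues
    # as S_W^-1 S_B
    Li_SB = sla.solve_triangular(L, S_B, lower=True)
    M = sla.solve_triangular(L, Li_SB.T, lower=True)
    M = (M + M.T) / 2.0
    evals, evecs = sla.eigh(M)
    order = np.argsort(evals)[::-1]
    r = min(g - 1, p)
    evals = np.clip(evals[order][:r], 0.0, None)
    U = evecs[:, order][:, :r]
    # back-transform whitened eigenvectors to raw coefficients
    V = sla.solve_triangular(L.T, U, lower=False)

    pooled_cov = S_W / (n - g)
    # scale: unit pooled within-group variance of scores
    scale = np.sqrt(np.einsum("ji,jk,ki->i", V, pooled_cov, V))
    scale[scale == 0] = 1.0
    V = V / scale
    # sign: largest-magnitude coefficient positive, per axis
    flip = np.sign(V[np.argmax(np.abs(V), axis=0), np.arange(r)])
    flip[flip == 0] = 1.0
    V = V * flip

    total = evals.sum()
    var_explained = evals / total if total > 0 else np.zeros(r)
    model = LDAModel(
        groups=list(groups),
        priors=_resolve_priors(priors, counts),
        means=means,
        pooled_cov=pooled_cov,
        coeffs=V,
        eigenvalues=evals,
        canonical_correlations=np.sqrt(evals / (1.0 + evals)),
        variance_explained=var_explained,
        centroid_scores=(means - grand) @ V,
        variable_names=list(data.variable_names),
        grand_mean=grand,
        counts=counts,
    )
    return model


# ---------------------------------------------------------------------------
# projection and loadings
# ---------------------------------------------------------------------------

def transform(model: LDAModel, X: np.ndarray) -> np.ndarray:
    """Project observations onto the canonical axes (centered at the
    training grand mean).  Returns an (n, r) score matrix."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != len(model.variable_names):
        raise ValueError(
            f"expected {len(model.variable_names)} variables "
            f"({model.variable_names}), got {X.shape[1]}"
        )
    return (X - model.grand_mean) @ model.coeffs


def factor_loadings(model: LDAModel, data: LabeledMatrix) -> np.ndarray:
    """Correlation of each original variable with each canonical score,
    computed on the training data.  Entry (j, i) in [-1, 1]."""
    scores = transform(model, data.X)
    Xc = data.X - data.X.mean(axis=0)
    Sc = scores - scores.mean(axis=0)
    sx = np.sqrt((Xc ** 2).sum(axis=0))
    ss = np.sqrt((Sc ** 2).sum(axis=0))
    if np.any(sx == 0):
        bad = [data.variable_names[j] for j in np.where(sx == 0)[0]]
        raise ValueError(f"zero-variance variables, correlation undefined: {bad}")
    if np.any(ss == 0):
        raise ValueError("zero-variance canonical score, correlation undefined")
    return (Xc.T @ Sc) / np.outer(sx, ss)


# ---------------------------------------------------------------------------
# membership probabilities and classification
# ---------------------------------------------------------------------------

def _log_discriminants(model: LDAModel, X: np.ndarray) -> np.ndarray:
    """Linear discriminant scores delta_k(x) = x' S^-1 mu_k
    - mu_k' S^-1 mu_k / 2 + log pi_k, vectorized over rows of X."""
    cho = sla.cho_factor(model.pooled_cov, lower=True)
    A = sla.cho_solve(cho, model.means.T)          # (p, g)
    const = -0.5 * np.einsum("kp,pk->k", model.means, A)
    with np.errstate(divide="ignore"):
        logpi = np.log(model.priors)
    return X @ A + const + logpi


def posterior_probabilities(model: LDAModel, x: np.ndarray) -> np.ndarray:
    """Group-membership probabilities under the shared-covariance Gaussian
    model.  Accepts a single p-vector (returns length-g) or an (n, p)
    matrix (returns (n, g)); rows sum to 1."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != len(model.variable_names):
        raise ValueError(f"expected {len(model.variable_names)} variables")
    post = softmax(_log_discriminants(model, X), axis=1)
    return post[0] if single else post


def classify(model: LDAModel, x: np.ndarray):
    """Assign each observation to the maximum-posterior group; ties break
    to the first group in model order."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    delta = _log_discriminants(model, np.atleast_2d(x))
    idx = np.argmax(delta, axis=1)  # first max wins on ties
    labels = [model.groups[i] for i in idx]
    return labels[0] if single else labels


# ---------------------------------------------------------------------------
# confidence ellipses
# ---------------------------------------------------------------------------

def confidence_ellipse(scores: np.ndarray, level: float = 0.95,
                       of_mean: bool = False) -> Ellipse:
    """Ellipse of the bivariate-normal fit to 2-D scores.

    By default this is the observation-coverage ellipse (contains a
    ``level`` fraction of the population).  With ``of_mean=True`` the sample
    covariance is divided by n, giving the standard-error (confidence-of-
    the-mean) ellipse used for centroid trajectories.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[1] != 2:
        raise ValueError("scores must be an (n, 2) array")
    n = scores.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points for an ellipse")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    center = scores.mean(axis=0)
    cov = np.cov(scores, rowvar=False)
    if of_mean:
        cov = cov / n
    w, V = sla.eigh(cov)
    if w.min() <= max(w.max(), 1.0) * 1e-12:
        raise ValueError("degenerate score covariance, ellipse undefined")
    q = chi2.ppf(level, df=2)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    return Ellipse(
        center=center,
        axes=np.sqrt(w * q),
        orientation=float(np.arctan2(V[1, 0], V[0, 0])),
        level=level,
    )


# ---------------------------------------------------------------------------
# leave-one-out validation
# ---------------------------------------------------------------------------

def loo_misclassification(data: LabeledMatrix, priors="proportional",
                          ridge: float | None = None) -> ConfusionMatrix:
    """Leave-one-out cross-validation: refit on n-1 rows, classify the
    held-out row, aggregate into a confusion matrix.

    The contract is exact refitting per fold (no downdating shortcuts), so
    counts are reproducible to the bit against a naive implementation.
    """
    groups, inverse, counts, _ = _group_stats(data.X, data.y)
    if counts.min() < 3:
        small = [str(groups[i]) for i in np.where(counts < 3)[0]]
        raise FitError(
            f"LOO needs >= 3 observations per group; too small: {small}")
    g = len(groups)
    index = {lab: i for i, lab in enumerate(groups)}
    cm = np.zeros((g, g), dtype=int)
    n = data.X.shape[0]
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        fold = LabeledMatrix(data.X[mask], data.y[mask], data.variable_names)
        model = fit_lda(fold, priors=priors, ridge=ridge)
        pred = classify(model, data.X[i])
        cm[inverse[i], index[pred]] += 1
        mask[i] = True
    return ConfusionMatrix(labels=list(groups), counts=cm)


def collapse_confusion_to_phenotype(cm: ConfusionMatrix,
                                    label_map: Mapping) -> ConfusionMatrix:
    """Collapse a confusion matrix by mapping each group label to a
    phenotype (e.g. ``GRMD_4.5 -> GRMD``).  The collapsed misclassification
    rate can only be <= the original's, since within-phenotype confusions
    move onto the diagonal."""
    unmapped = [lab for lab in cm.labels if lab not in label_map]
    if unmapped:
        raise KeyError(f"labels without a phenotype mapping: {unmapped}")
    out_labels: list = []
    for lab in cm.labels:
        ph = label_map[lab]
        if ph not in out_labels:
            out_labels.append(ph)
    idx = {ph: i for i, ph in enumerate(out_labels)}
    k = len(out_labels)
    out = np.zeros((k, k), dtype=cm.counts.dtype)
    for a, la in enumerate(cm.labels):
        for b, lb in enumerate(cm.labels):
            out[idx[label_map[la]], idx[label_map[lb]]] += cm.counts[a, b]
    return ConfusionMatrix(labels=out_labels, counts=out)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def model_to_dict(model: LDAModel) -> dict:
    return {
        "format_version": MODEL_FORMAT_VERSION,
        "groups": [str(gr) for gr in model.groups],
        "priors": model.priors.tolist(),
        "means": model.means.tolist(),
        "pooled_cov": model.pooled_cov.tolist(),
        "coeffs": model.coeffs.tolist(),
        "eigenvalues": model.eigenvalues.tolist(),
        "canonical_correlations": model.canonical_correlations.tolist(),
        "variance_explained": model.variance_explained.tolist(),
        "centroid_scores": model.centroid_scores.tolist(),
        "variable_names": list(model.variable_names),
        "grand_mean": model.grand_mean.tolist(),
        "counts": None if model.counts is None else model.counts.tolist(),
    }


def model_from_dict(doc: dict) -> LDAModel:
    if "format_version" not in doc:
        raise ValueError("model document lacks a format_version field")
    if doc["format_version"] != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format {doc['format_version']}")
    return LDAModel(
        groups=list(doc["groups"]),
        priors=np.asarray(doc["priors"], dtype=float),
        means=np.asarray(doc["means"], dtype=float),
        pooled_cov=np.asarray(doc["pooled_cov"], dtype=float),
        coeffs=np.asarray(doc["coeffs"], dtype=float),
        eigenvalues=np.asarray(doc["eigenvalues"], dtype=float),
        canonical_correlations=np.asarray(doc["canonical_correlations"], dtype=float),
        variance_explained=np.asarray(doc["variance_explained"], dtype=float),
        centroid_scores=np.asarray(doc["centroid_scores"], dtype=float),
        variable_names=list(doc["variable_names"]),
        grand_mean=np.asarray(doc["grand_mean"], dtype=float),
        counts=None if doc.get("counts") is None
        else np.asarray(doc["counts"], dtype=int),
    )


def save_model(model: LDAModel, path, extra: dict | None = None) -> None:
    doc = model_to_dict(model)
    if extra:
        doc.update(extra)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def load_model(path) -> tuple[LDAModel, dict]:
    with open(path) as fh:
        doc = json.load(fh)
    return model_from_dict(doc), doc
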