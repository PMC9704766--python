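"""Stepping-distribution statistics in the foot-placement plane.

The cloud of steps in the ``[z_L, z_R]`` plane is summarized by its 95%
prediction ellipse: under bivariate normality the set

    (x - mu)' C^{-1} (x - mu) <= chi2_{0.95, 2} = 5.991

contains 95% of fresh draws.  The ellipse's semi-axes are
``sqrt(5.991 * lambda_i)`` along the covariance eigenvectors, its area
is ``5.991 * pi * sqrt(lambda_1 * lambda_2)``, its shape is the
eigenvalue ratio ``lambda_1 / lambda_2``, and its orientation is the
major-axis angle measured from the constant-w* GEM (the (1,1) diagonal).

Two orientation conventions are provided.  ``orientation_verbatim``
applies the published formula ``atan2(lambda_1 - C_11, C_21) + pi/4``
(with its axis-aligned special cases) as written, which yields pi/2 for
a cloud aligned with the w* GEM.  ``orientation_w_gem`` reports the
angular deviation of the major axis from the w* GEM directly
(``theta_major - pi/4`` wrapped to (-pi/2, pi/2]), so that a
GEM-aligned cloud reads 0; analysis summaries use this convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CHI2_95_2DF",
    "PredictionEllipse",
    "fit_covariance",
    "prediction_ellipse",
    "aspect_ratio",
    "ellipse_area",
    "orientation",
    "fit_prediction_ellipse",
    "points_inside",
    "bootstrap_ci",
]

#: 95th-percentile critical value of chi-squared with 2 df (~5.991).
CHI2_95_2DF = float(stats.chi2.ppf(0.95, df=2))

#: Relative eigenvalue gap below which orientation is flagged undefined.
_ISOTROPY_RTOL = 1e-12


@dataclass(frozen=True)
class PredictionEllipse:
    """Eigendecomposition summary of a 2D stepping distribution."""

    center: tuple[float, float]
    covariance: np.ndarray
    lambda1: float
    lambda2: float
    e1: np.ndarray
    e2: np.ndarray
    aspect_ratio: float
    area: float
    orientation_verbatim: float
    orientation_w_gem: float
    n_points: int | None = None

    @property
    def orientation_defined(self) -> bool:
        return not (np.isnan(self.orientation_verbatim) or np.isnan(self.orientation_w_gem))

    def boundary(self, n: int = 361) -> np.ndarray:
        """(n, 2) boundary points: E @ [sqrt(5.991 l1) cos t, sqrt(5.991 l2) sin t]."""
        t = np.linspace(0.0, 2.0 * np.pi, n)
        axes = np.column_stack(
            [
                np.sqrt(CHI2_95_2DF * self.lambda1) * np.cos(t),
                np.sqrt(CHI2_95_2DF * self.lambda2) * np.sin(t),
            ]
        )
        E = np.column_stack([self.e1, self.e2])
        return axes @ E.T + np.asarray(self.center)


def _check_cov(C: np.ndarray) -> np.ndarray:
    C = np.asarray(C, dtype=float)
    if C.shape != (2, 2):
        raise ValueError(f"covariance must be 2x2, got shape {C.shape}")
    if not np.allclose(C, C.T, rtol=1e-8, atol=1e-12):
        raise ValueError("covariance must be symmetric")
    return C


def _eigh_desc(C: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues descending, matching unit eigenvector columns."""
    vals, vecs = np.linalg.eigh(C)
    order = np.argsort(vals)[::-1]
    return vals[order], vecs[:, order]


def fit_covariance(points: Sequence | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean and unbiased (n-1) sample covariance of 2D points.

    ``points`` is (n, 2) array-like of [z_L, z_R] pairs, n >= 3.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of [z_L, z_R] pairs")
    if pts.shape[0] < 3:
        raise ValueError(f"need at least 3 points to fit a covariance, got {pts.shape[0]}")
    center = pts.mean(axis=0)
    C = np.cov(pts.T, ddof=1)
    return center, C


def aspect_ratio(C: np.ndarray, tol: float = 1e-12) -> float:
    """Eigenvalue ratio lambda_1 / lambda_2; inf for degenerate clouds."""
    vals, _ = _eigh_desc(_check_cov(C))
    l1, l2 = float(vals[0]), float(vals[1])
    if l2 <= tol * max(l1, 1.0):
        return float("inf")
    return l1 / l2


def ellipse_area(C: np.ndarray) -> float:
    """95% prediction ellipse area A = 5.991 * pi * sqrt(lambda_1 lambda_2)."""
    vals, _ = _eigh_desc(_check_cov(C))
    prod = max(float(vals[0]) * float(vals[1]), 0.0)
    return CHI2_95_2DF * np.pi * float(np.sqrt(prod))


def orientation(C: np.ndarray) -> tuple[float, float]:
    """Major-axis orientation relative to the w* GEM, both conventions.

    Returns ``(verbatim, w_gem)`` in radians; both NaN when the
    distribution is isotropic (orientation undefined).
    """
    C = _check_cov(C)
    vals, vecs = _eigh_desc(C)
    l1, l2 = float(vals[0]), float(vals[1])
    if abs(l1 - l2) < _ISOTROPY_RTOL * max(np.trace(C), 1e-300):
        return float("nan"), float("nan")

    c11, c21, c22 = float(C[0, 0]), float(C[1, 0]), float(C[1, 1])
    if c21 == 0.0:
        verbatim = np.pi / 4.0 if c11 >= c22 else 3.0 * np.pi / 4.0
    else:
        verbatim = float(np.arctan2(l1 - c11, c21)) + np.pi / 4.0

    theta_major = float(np.arctan2(vecs[1, 0], vecs[0, 0]))  # angle from z_L axis
    dev = (theta_major - np.pi / 4.0) % np.pi
    if dev > np.pi / 2.0:
        dev -= np.pi  # wrap to (-pi/2, pi/2]
    return verbatim, dev


def prediction_ellipse(center, C: np.ndarray, n_points: int | None = None) -> PredictionEllipse:
    """Full 95% prediction-ellipse summary from a mean and covariance."""
    C = _check_cov(C)
    vals, vecs = _eigh_desc(C)
    if vals[1] < -1e-10 * max(abs(vals[0]), 1.0):
        raise ValueError("covariance must be positive semidefinite")
    l1, l2 = float(max(vals[0], 0.0)), float(max(vals[1], 0.0))
    verbatim, w_gem = orientation(C) if l1 > 0 else (float("nan"), float("nan"))
    return PredictionEllipse(
        center=(float(center[0]), float(center[1])),
        covariance=C,
        lambda1=l1,
        lambda2=l2,
        e1=vecs[:, 0],
        e2=vecs[:, 1],
        aspect_ratio=aspect_ratio(C) if l1 > 0 else float("nan"),
        area=ellipse_area(C),
        orientation_verbatim=verbatim,
        orientation_w_gem=w_gem,
        n_points=n_points,
    )


def fit_prediction_ellipse(points) -> PredictionEllipse:
    """Fit mean/covariance to points and summarize the 95% ellipse."""
    pts = np.asarray(points, dtype=float)
    center, C = fit_covariance(pts)
    return prediction_ellipse(center, C, n_points=pts.shape[0])


def points_inside(points, center, C: np.ndarray) -> np.ndarray:
    """Boolean mask: squared Mahalanobis distance <= chi2_{0.95, 2}.

    Degenerate covariances use the pseudo-inverse, so a point ellipse
    contains only its center.
    """
    C = _check_cov(C)
    pts = np.asarray(points, dtype=float) - np.asarray(center, dtype=float)
    vals, vecs = _eigh_desc(C)
    tol = 1e-12 * max(float(vals[0]), 1e-300)
    proj = pts @ vecs  # coordinates along the eigenvectors
    d2 = np.zeros(pts.shape[0])
    in_range = np.ones(pts.shape[0], dtype=bool)
    for i in range(2):
        if vals[i] > tol:
            d2 += proj[:, i] ** 2 / vals[i]
        else:
            in_range &= np.abs(proj[:, i]) <= 1e-12
    return in_range & (d2 <= CHI2_95_2DF)


def bootstrap_ci(
    samples: Sequence,
    statistic: Callable,
    n_resamples: int = 1000,
    level: float = 0.95,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Percentile bootstrap CI of ``statistic`` over unit-level resampling.

    ``samples`` is a sequence of exchangeable units (e.g. one entry per
    maneuver); each resample draws len(samples) units with replacement
    and applies ``statistic`` to the resampled list.
    """
    n = len(samples)
    if n < 2:
        raise ValueError("need at least 2 samples to bootstrap")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    rng = np.random.default_rng(seed)
    arr = samples if isinstance(samples, (list, tuple)) else list(samples)
    reps = np.empty(n_resamples)
    for b in range(n_resamples):
        idx = rng.integers(0, n, size=n)
        reps[b] = statistic([arr[i] for i in idx])
    lo = float(np.percentile(reps, 100.0 * (1.0 - level) / 2.0))
    hi = float(np.percentile(reps, 100.0 * (1.0 + level) / 2.0))
    return lo, hi
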