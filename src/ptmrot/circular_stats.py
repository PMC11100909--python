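"""Circular statistics on torsion angles.

The estimation core of the library builder: von Mises kernels, adaptive
kernel density estimation on the phi/psi torus (sample-point bandwidths that
shrink in dense regions and widen in sparse ones), Nadaraya-Watson kernel
regression for smoothed chi circular means and standard deviations, and the
Bayes-rule conversion of per-rotamer densities into rotamer probabilities.

Conventions: all angles are degrees in [-180, 180); densities are per radian
(circle) or per radian squared (torus).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import i0e

logger = logging.getLogger(__name__)

__all__ = [
    "von_mises_density",
    "AdaptiveKDEModel",
    "fit_adaptive_kde",
    "kde_density",
    "rotamer_posterior",
    "RegressionEstimate",
    "nw_regress_circular",
    "circular_mean_std",
]


def von_mises_density(x, mu, kappa):
    """von Mises density f(x) = exp(kappa cos(x - mu)) / (2 pi I0(kappa)).

    ``x`` and ``mu`` in degrees; the density is per radian, so kappa = 0
    gives the uniform value 1/(2 pi).  Uses the exponentially scaled Bessel
    function so large concentrations do not overflow.
    """
    kappa = float(kappa)
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    delta = np.radians(np.asarray(x, dtype=float) - np.asarray(mu, dtype=float))
    # exp(k cos d)/(2 pi I0(k)) = exp(k (cos d - 1)) / (2 pi I0e(k))
    return np.exp(kappa * (np.cos(delta) - 1.0)) / (2.0 * np.pi * i0e(kappa))


def _torus_kernel_matrix(queries, points, kappas):
    """Product von Mises kernel values K(q_phi - p_phi) K(q_psi - p_psi).

    ``queries``: (m, 2); ``points``: (n, 2); ``kappas``: scalar or (n,).
    Returns (m, n).
    """
    queries = np.atleast_2d(np.asarray(queries, dtype=float))
    points = np.atleast_2d(np.asarray(points, dtype=float))
    kappas = np.broadcast_to(np.asarray(kappas, dtype=float), (points.shape[0],))
    dphi = np.radians(queries[:, None, 0] - points[None, :, 0])
    dpsi = np.radians(queries[:, None, 1] - points[None, :, 1])
    log_k = kappas[None, :] * ((np.cos(dphi) - 1.0) + (np.cos(dpsi) - 1.0))
    norm = (2.0 * np.pi * i0e(kappas)) ** 2
    return np.exp(log_k) / norm[None, :]


@dataclass
class AdaptiveKDEModel:
    """Fitted adaptive KDE: sample points with per-point bandwidth factors."""

    points: np.ndarray  # (n, 2) phi/psi degrees
    kappa0: float
    alpha: float
    lambdas: np.ndarray  # (n,) local bandwidth factors, > 0
    geometric_mean_pilot: float

    @property
    def n(self) -> int:
        return self.points.shape[0]

    @property
    def kappas(self) -> np.ndarray:
        """Per-point concentrations kappa_i = kappa0 / lambda_i^2."""
        return self.kappa0 / self.lambdas**2


def adaptive_lambdas(points, kappa0: float = 50.0, alpha: float = 0.5,
                     eval_points=None):
    """Sample-point bandwidth factors lambda_i = (g / f~(x_i))^alpha.

    The fixed-concentration pilot estimate f~ is built from ``points``; g is
    the geometric mean of its values over the same sample.  When
    ``eval_points`` is given, lambdas are returned for those points instead
    (bandwidths driven by the pooled sample's local density) along with g.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if kappa0 <= 0:
        raise ValueError("kappa0 must be positive")
    pilot_at_sample = _torus_kernel_matrix(points, points, kappa0).mean(axis=1)
    g = float(np.exp(np.mean(np.log(pilot_at_sample))))
    if eval_points is None:
        pilot = pilot_at_sample
    else:
        eval_points = np.atleast_2d(np.asarray(eval_points, dtype=float))
        pilot = _torus_kernel_matrix(eval_points, points, kappa0).mean(axis=1)
    return (g / pilot) ** alpha, g


def fit_adaptive_kde(points, kappa0: float = 50.0, alpha: float = 0.5) -> AdaptiveKDEModel:
    """Fit a sample-point adaptive von Mises KDE on the phi/psi torus.

    A fixed-concentration pilot estimate f~ is evaluated at every sample
    point; the local bandwidth factor is lambda_i = (g / f~(x_i))^alpha with
    g the geometric mean of the pilot values, and the per-point concentration
    is kappa0 / lambda_i^2.  Dense regions (pilot above the geometric mean)
    get lambda < 1, i.e. narrower kernels; sparse regions get broader ones.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[0] < 2:
        raise ValueError("adaptive KDE requires at least 2 points")
    lambdas, g = adaptive_lambdas(points, kappa0=kappa0, alpha=alpha)
    return AdaptiveKDEModel(
        points=points,
        kappa0=float(kappa0),
        alpha=float(alpha),
        lambdas=lambdas,
        geometric_mean_pilot=g,
    )


def kde_density(model: AdaptiveKDEModel, query) -> np.ndarray | float:
    """Adaptive KDE density at one query point or an (m, 2) array of them.

    Per radian squared; integrates to 1 over the torus.
    """
    single = np.asarray(query).ndim == 1
    values = _torus_kernel_matrix(query, model.points, model.kappas).mean(axis=1)
    return float(values[0]) if single else values


def rotamer_posterior(priors, densities):
    """Bayes' rule: P(r | phi, psi) from state priors and per-state densities.

    Falls back to the priors (with a log message) when every density
    underflows to zero at the query point.
    """
    priors = np.asarray(priors, dtype=float)
    densities = np.asarray(densities, dtype=float)
    if np.any(densities < 0):
        raise ValueError("densities must be non-negative")
    if not np.isclose(priors.sum(), 1.0, atol=1e-6):
        raise ValueError("priors must sum to 1")
    joint = priors * densities
    total = joint.sum()
    if total <= 0.0:
        logger.info("all rotamer densities zero at query; falling back to priors")
        return priors.copy()
    return joint / total


@dataclass
class RegressionEstimate:
    """Kernel-regression estimate of a chi angle at one backbone location."""

    circ_mean: float  # degrees
    circ_std: float  # degrees, >= floor
    eff_n: float  # Kish effective sample size of the kernel weights


def circular_mean_std(values, weights=None, period: float = 360.0,
                      std_floor: float = 0.0):
    """Weighted circular mean and standard deviation on a circle of ``period``.

    The standard deviation is sqrt(-2 ln Rbar) rescaled to degrees of the
    target period; constant data gives the floor.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("no values")
    if weights is None:
        weights = np.ones_like(values)
    weights = np.asarray(weights, dtype=float)
    scale = 360.0 / period
    theta = np.radians(values * scale)
    wsum = weights.sum()
    if wsum <= 0:
        raise ValueError("weights sum to zero")
    c = np.sum(weights * np.cos(theta)) / wsum
    s = np.sum(weights * np.sin(theta)) / wsum
    rbar = min(np.hypot(c, s), 1.0)
    mean = np.degrees(np.arctan2(s, c)) / scale
    if rbar >= 1.0 - 1e-15:
        std = 0.0
    else:
        std = np.degrees(np.sqrt(-2.0 * np.log(rbar))) / scale
    mean = (mean + period / 2.0) % period - period / 2.0
    return float(mean), float(max(std, std_floor))


def nw_regress_circular(points, values, query, kappa_reg: float = 50.0,
                        std_floor: float = 3.0, period: float = 360.0) -> RegressionEstimate:
    """Nadaraya-Watson circular regression of chi at a backbone query point.

    Observations are weighted by a product von Mises kernel centered at the
    query on the phi/psi torus; the weighted circular mean and standard
    deviation of the chi values (on a circle of ``period`` degrees, 120 for
    3-fold terminal rotors) form the estimate.  Adding a constant to every
    value shifts the mean by that constant and leaves the spread unchanged.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    values = np.asarray(values, dtype=float)
    if points.shape[0] == 0:
        raise ValueError("no observations; caller must backfill from the BI library")
    if points.shape[0] != values.shape[0]:
        raise ValueError("points and values length mismatch")
    weights = _torus_kernel_matrix(query, points, kappa_reg)[0]
    if weights.sum() <= 0.0 or not np.isfinite(weights.sum()):
        weights = np.ones_like(weights)
    mean, std = circular_mean_std(values, weights, period=period, std_floor=std_floor)
    eff_n = float(weights.sum() ** 2 / np.sum(weights**2))
    return RegressionEstimate(circ_mean=mean, circ_std=std, eff_n=eff_n)
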