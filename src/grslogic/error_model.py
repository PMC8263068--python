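"""Time-value error model for replicated stimulus-response timecourses.

Observed variance at a timecourse point is decomposed into a
mean-dependent *value* component and a slope-dependent *temporal*
component::

    sigma^2_total = alpha0 + alpha1*mu + alpha2*mu^2 + Slope^2 * sigma_t^2

The temporal term is first-order error propagation of a Gaussian timing
uncertainty (sd sigma_t) through the local slope of the response curve.
Low-expression (background) points, mu <= eta, are modelled with a gamma
distribution whose mode matches the mean estimate and whose variance is a
dedicated background parameter sigma_bg^2; induced points are Gaussian.

The five global parameters xi = (sigma_bg^2, alpha0, alpha1, alpha2,
sigma_t^2) are fitted by pooled maximum likelihood over all genes,
conditions and timepoints, bias-corrected by N/(N-1), and then serve as an
empirical-Bayes prior for stabilized per-point estimates.  The
conventional error model is the degenerate case sigma_t^2 = 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import minimize
from scipy.special import gammaln

from .errors import (
    ConfigurationError,
    EstimationFailureError,
    InsufficientDataError,
    InvalidInputError,
)

__all__ = [
    "ErrorModelParams",
    "PointStats",
    "estimate_slopes",
    "total_variance",
    "point_nll",
    "fit_global_error_params",
    "posterior_point_params",
    "posterior_variances",
]

#: Floor (RPKM^2) applied to any computed variance inside likelihoods.
VARIANCE_FLOOR = 1e-8
#: Floor applied to observed values inside the gamma log-density.
VALUE_FLOOR = 1e-6
#: Default background/induced threshold (RPKM).
DEFAULT_ETA = 3.0
#: Default shrinkage prior variance; small = prior (global trend) dominated,
#: the recommended setting for two replicates.
DEFAULT_PRIOR_VARIANCE = 1e-5

_PARAM_NAMES = ("sigma_bg2", "alpha0", "alpha1", "alpha2", "sigma_t2")


@dataclass(frozen=True)
class ErrorModelParams:
    """Global error-model parameters xi plus fitting metadata."""

    sigma_bg2: float
    alpha0: float
    alpha1: float
    alpha2: float
    sigma_t2: float
    eta: float = DEFAULT_ETA
    prior_variance: float = DEFAULT_PRIOR_VARIANCE
    n_replicates: int = 2
    mode: str = "time_value"  # time_value | conventional

    def __post_init__(self) -> None:
        if self.mode not in ("time_value", "conventional"):
            raise ConfigurationError(f"unknown error-model mode {self.mode!r}")
        for name in ("sigma_bg2", "sigma_t2", "prior_variance"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.eta <= 0:
            raise ConfigurationError("eta must be > 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.sigma_bg2, self.alpha0, self.alpha1,
                         self.alpha2, self.sigma_t2])

    def with_values(self, xi: np.ndarray) -> "ErrorModelParams":
        return replace(self, **dict(zip(_PARAM_NAMES, map(float, xi))))

    def to_json(self) -> str:
        payload = {name: getattr(self, name) for name in _PARAM_NAMES}
        payload.update(eta=self.eta, prior_variance=self.prior_variance,
                       n_replicates=self.n_replicates, mode=self.mode)
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ErrorModelParams":
        return cls(**json.loads(text))


@dataclass(frozen=True)
class PointStats:
    """Per-point replicate means and interpolated slopes."""

    mu: np.ndarray = field(repr=False)      # (..., T)
    slope: np.ndarray = field(repr=False)   # (..., T)
    timepoints: tuple[float, ...] = ()
    sigma_t_hat: float = 0.0


# ---------------------------------------------------------------------------
# Slope estimation
# ---------------------------------------------------------------------------


def estimate_slopes(mean_values: np.ndarray, timepoints: Iterable[float],
                    sigma_t_hat: float) -> np.ndarray:
    """Central-difference slopes of a shape-preserving interpolant.

    The replicate-mean series is interpolated with a piecewise cubic
    Hermite (PCHIP) function extended flat to 80 min, and the slope at
    each nominal timepoint is the central difference over a window
    Delta_t = 2 * sigma_t_hat (clipped to [0, 80]; the window is widened
    when timing uncertainty is high).  The slope at t = 0 is fixed to 0:
    that sample comes from unstimulated cells at steady state.
    """
    if sigma_t_hat <= 0:
        raise InvalidInputError("sigma_t_hat must be > 0")
    tp = np.asarray(list(timepoints), dtype=float)
    if tp.size < 3:
        raise InsufficientDataError("need >= 3 timepoints for slope estimation")
    vals = np.asarray(mean_values, dtype=float)
    if vals.shape[-1] != tp.size:
        raise InvalidInputError("values and timepoints disagree in length")
    t_ext = tp if tp[-1] >= 80.0 else np.append(tp, 80.0)
    lo = np.clip(tp - sigma_t_hat, 0.0, 80.0)
    hi = np.clip(tp + sigma_t_hat, 0.0, 80.0)
    width = hi - lo
    flat = vals.reshape(-1, tp.size)
    out = np.empty_like(flat)
    for i, row in enumerate(flat):
        ext = row if t_ext.size == tp.size else np.append(row, row[-1])
        interp = PchipInterpolator(t_ext, ext, extrapolate=False)
        out[i] = (interp(hi) - interp(lo)) / width
    out[:, tp == 0.0] = 0.0
    return out.reshape(vals.shape)


# ---------------------------------------------------------------------------
# Densities
# ---------------------------------------------------------------------------


def _gamma_mode_params(mu, sigma_bg2):
    """Shape/scale with mode at mu and variance sigma_bg^2.

    Solves (k-1)*theta = mu, k*theta^2 = sigma_bg^2; the positive root of
    theta^2 + mu*theta - sigma_bg^2 = 0 always yields k > 1 for mu > 0
    (k = 1, an exponential, in the mu = 0 limit).
    """
    mu = np.asarray(mu, dtype=float)
    s2 = np.maximum(np.asarray(sigma_bg2, dtype=float), VARIANCE_FLOOR)
    theta = 0.5 * (-mu + np.sqrt(mu * mu + 4.0 * s2))
    k = 1.0 + mu / theta
    return k, theta


def _gamma_nll(y, mu, sigma_bg2):
    k, theta = _gamma_mode_params(mu, sigma_bg2)
    yc = np.maximum(y, VALUE_FLOOR)
    return -( (k - 1.0) * np.log(yc) - yc / theta - k * np.log(theta) - gammaln(k) )


def _normal_nll(y, mu, var):
    v = np.maximum(var, VARIANCE_FLOOR)
    return 0.5 * (np.log(2.0 * np.pi * v) + (y - mu) ** 2 / v)


def total_variance(mu, slope, params: ErrorModelParams,
                   mode: str | None = None) -> np.ndarray | float:
    """Predicted total variance at a point (induced branch).

    ``time_value``: alpha0 + alpha1*mu + alpha2*mu^2 + slope^2*sigma_t^2;
    ``conventional`` drops the temporal term.
    """
    mode = mode or params.mode
    if mode not in ("time_value", "conventional"):
        raise ConfigurationError(f"unknown mode {mode!r}")
    mu = np.asarray(mu, dtype=float)
    var = params.alpha0 + params.alpha1 * mu + params.alpha2 * mu**2
    if mode == "time_value":
        var = var + np.asarray(slope, dtype=float) ** 2 * params.sigma_t2
    var = np.maximum(var, VARIANCE_FLOOR)
    if var.ndim == 0:
        return float(var)
    return var


def point_nll(observed, mu, slope, params: ErrorModelParams,
              mode: str | None = None) -> np.ndarray | float:
    """Negative log likelihood of observed values at one or more points.

    Background points (mu <= eta) use the mode-matched gamma with variance
    sigma_bg^2; induced points use a normal with the time-value (or
    conventional) variance.  Everything broadcasts.
    """
    y = np.asarray(observed, dtype=float)
    if np.any(y < 0):
        raise InvalidInputError("observed expression must be >= 0")
    mu_a = np.asarray(mu, dtype=float)
    bg = mu_a <= params.eta
    var = total_variance(mu_a, slope, params, mode=mode)
    nll = np.where(
        bg,
        _gamma_nll(y, mu_a, params.sigma_bg2),
        _normal_nll(y, mu_a, np.asarray(var)),
    )
    if nll.ndim == 0:
        return float(nll)
    return nll


# ---------------------------------------------------------------------------
# Global (pooled) fit
# ---------------------------------------------------------------------------


def _pooled_nll(xi_log10: np.ndarray, y, mu, slope, eta, mode) -> float:
    xi = 10.0 ** xi_log10
    sigma_bg2, alpha0, alpha1, alpha2 = xi[0], xi[1], xi[2], xi[3]
    sigma_t2 = xi[4] if mode == "time_value" else 0.0
    bg = mu <= eta
    var = alpha0 + alpha1 * mu + alpha2 * mu * mu + slope * slope * sigma_t2
    nll_bg = _gamma_nll(y, mu[..., None], sigma_bg2)
    nll_ind = _normal_nll(y, mu[..., None], var[..., None])
    total = np.where(bg[..., None], nll_bg, nll_ind)
    return float(np.sum(total))


def _heuristic_init(y, mu, eta):
    raw_var = y.var(axis=-1, ddof=1)
    bg = mu <= eta
    s_bg = float(np.median(raw_var[bg])) if bg.any() else 0.1
    ind = ~bg
    if ind.any():
        a2 = float(np.median(raw_var[ind] / np.maximum(mu[ind] ** 2, 1e-6)))
    else:
        a2 = 0.01
    return np.array([max(s_bg, 1e-4), max(0.1 * s_bg, 1e-4), 1e-3,
                     max(a2, 1e-5), 25.0])


def fit_global_error_params(
    values: np.ndarray,
    timepoints: Iterable[float],
    mode: str = "time_value",
    eta: float = DEFAULT_ETA,
    prior_variance: float = DEFAULT_PRIOR_VARIANCE,
    n_starts: int = 4,
    seed: int = 0,
) -> tuple[ErrorModelParams, PointStats]:
    """Pooled MLE of the global error parameters xi (the shrinkage prior).

    ``values`` has shape (genes, conditions, timepoints, replicates) with
    >= 2 replicates.  Slopes are computed from replicate-mean curves with
    the window initialized at the sampling interval and refined once from
    the first-pass temporal-uncertainty estimate.  Variance-type
    parameters are bias-corrected by N/(N-1) after optimization.
    """
    y = np.asarray(values, dtype=float)
    if y.ndim != 4:
        raise InvalidInputError("values must be (genes, conds, times, reps)")
    N = y.shape[3]
    if N < 2:
        raise InsufficientDataError("global fit needs >= 2 replicates")
    tp = np.asarray(list(timepoints), dtype=float)
    mu = y.mean(axis=3)

    def _fit(slope):
        x0 = np.log10(_heuristic_init(y, mu, eta))
        rng = np.random.default_rng(seed)
        bounds = [(-8.0, 4.0)] * 5
        best = None
        starts = [x0] + [x0 + rng.normal(0.0, 0.7, size=5) for _ in range(n_starts - 1)]
        for x_start in starts:
            res = minimize(
                _pooled_nll, np.clip(x_start, -8, 4),
                args=(y, mu, slope, eta, mode),
                method="L-BFGS-B", bounds=bounds,
                options={"maxiter": 500},
            )
            if best is None or res.fun < best.fun:
                best = res
        if best is None or not np.isfinite(best.fun):
            raise EstimationFailureError("global error-model fit did not converge")
        return 10.0 ** best.x

    # pass 1: slope window from the sampling interval
    dt0 = float(np.median(np.diff(tp)))
    slope = estimate_slopes(mu, tp, sigma_t_hat=dt0 / 2.0)
    xi = _fit(slope)
    sigma_t_hat = float(np.sqrt(max(xi[4] * N / (N - 1.0), VARIANCE_FLOOR))) \
        if mode == "time_value" else dt0 / 2.0
    if mode == "time_value" and abs(2.0 * sigma_t_hat - dt0) > 1e-9:
        # pass 2: recompute slopes with the data-driven window and refit
        slope = estimate_slopes(mu, tp, sigma_t_hat=max(sigma_t_hat, 0.5))
        xi = _fit(slope)

    xi = xi * (N / (N - 1.0))
    if mode == "conventional":
        xi[4] = 0.0
    params = ErrorModelParams(
        *map(float, xi), eta=eta, prior_variance=prior_variance,
        n_replicates=N, mode=mode,
    )
    return params, PointStats(mu=mu, slope=slope, timepoints=tuple(tp),
                              sigma_t_hat=sigma_t_hat)


# ---------------------------------------------------------------------------
# Empirical-Bayes per-point posterior
# ---------------------------------------------------------------------------


def posterior_point_params(
    observed: np.ndarray,
    mu: float,
    slope: float,
    xi_prior: ErrorModelParams,
    prior_variance: float | None = None,
) -> tuple[np.ndarray, float]:
    """MAP estimate of the per-point parameters xi_i under a normal prior.

    Maximizes point-likelihood x prior; as the prior variance -> 0 the
    posterior collapses onto the global trend, and as it -> infinity it
    approaches the point MLE.  Only the parameters the point's branch is
    informative about are optimized (the rest are prior-pinned exactly).
    Returns (xi_posterior, sigma2_total at the point).
    """
    pv = xi_prior.prior_variance if prior_variance is None else prior_variance
    if pv <= 0:
        raise ConfigurationError("prior variance must be > 0")
    y = np.asarray(observed, dtype=float)
    prior = xi_prior.as_array()
    bg = mu <= xi_prior.eta
    if bg:
        free = [0]
    elif xi_prior.mode == "time_value":
        free = [1, 2, 3, 4]
    else:
        free = [1, 2, 3]

    def objective(x_free):
        xi = prior.copy()
        xi[free] = x_free
        p = xi_prior.with_values(xi)
        nll = float(np.sum(point_nll(y, mu, slope, p)))
        return nll + float(np.sum((x_free - prior[free]) ** 2)) / (2.0 * pv)

    res = minimize(objective, prior[free], method="L-BFGS-B",
                   bounds=[(0.0, None)] * len(free), options={"maxiter": 200})
    xi_post = prior.copy()
    xi_post[free] = res.x
    p_post = xi_prior.with_values(xi_post)
    s2 = p_post.sigma_bg2 if bg else float(total_variance(mu, slope, p_post))
    return xi_post, s2


def posterior_variances(
    values: np.ndarray,
    params: ErrorModelParams,
    stats: PointStats,
    prior_variance: float | None = None,
) -> np.ndarray:
    """Per-point posterior total-variance estimates for a whole dataset."""
    y = np.asarray(values, dtype=float)
    mu, slope = stats.mu, stats.slope
    out = np.empty(mu.shape)
    flat_y = y.reshape(-1, y.shape[-1])
    flat_mu = mu.reshape(-1)
    flat_slope = slope.reshape(-1)
    flat_out = out.reshape(-1)
    for i in range(flat_mu.size):
        _, flat_out[i] = posterior_point_params(
            flat_y[i], float(flat_mu[i]), float(flat_slope[i]), params,
            prior_variance=prior_variance,
        )
    return out
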