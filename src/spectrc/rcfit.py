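"""Three-parameter logistic recovery-curve fit with bootstrap bands.

The recovery coefficient as a function of sphere volume V is modelled by a
sigmoid in log-volume with a free asymptote,

    RC(V) = A / (1 + (V50 / V)^gamma)

where A is the large-volume asymptote (free, not pinned to 1), V50 the
volume at which RC reaches A/2 and gamma the steepness.  Goodness of fit
is the squared Pearson correlation between observed and fitted RC.
Confidence and prediction bands come from a seeded residual bootstrap.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

logger = logging.getLogger("spectrc")


def logistic_rc(volume_ml, A: float, V50: float, gamma: float):
    """RC(V) = A / (1 + (V50/V)^gamma), evaluated stably in log space."""
    v = np.asarray(volume_ml, dtype=float)
    if np.any(v <= 0):
        raise ValueError("volume must be > 0")
    z = np.clip(gamma * (np.log(V50) - np.log(v)), -700.0, 700.0)
    out = A / (1.0 + np.exp(z))
    return out if out.ndim else float(out)


@dataclass
class RCFit:
    """Fitted logistic recovery curve."""

    A: float
    V50: float  # ml
    gamma: float
    r_squared: float
    covariance: np.ndarray  # 3x3, (A, V50, gamma)
    volumes: np.ndarray
    rc_values: np.ndarray
    fitted: np.ndarray
    ci_level: float = 0.95

    def predict(self, volume_ml):
        return logistic_rc(volume_ml, self.A, self.V50, self.gamma)

    @property
    def residuals(self) -> np.ndarray:
        return self.rc_values - self.fitted


def _fit_log_params(volumes, rc, p0_log, weights=None):
    def model(v, la, lv, lg):
        return logistic_rc(v, np.exp(la), np.exp(lv), np.exp(lg))

    sigma = None if weights is None else 1.0 / np.sqrt(np.asarray(weights, dtype=float))
    with warnings.catch_warnings():
        # zero-noise data makes the covariance singular; the parameters are
        # still valid, so keep the fit quiet
        warnings.simplefilter("ignore", optimize.OptimizeWarning)
        popt, pcov = optimize.curve_fit(model, volumes, rc, p0=p0_log, sigma=sigma,
                                        maxfev=20000)
    resid = rc - model(volumes, *popt)
    return popt, pcov, float(resid @ resid)


def fit_logistic(volumes, rc_values, weights=None, ci_level: float = 0.95) -> RCFit:
    """Nonlinear least-squares fit of the 3-parameter logistic curve.

    Parameters are box-constrained positive via a log transform.
    Initialization is multi-start over gamma0 in {0.5, 1, 2} with
    A0 = max(RC) and V50_0 = median volume; the best residual wins, so the
    fit is deterministic given the data.  At least four distinct volumes
    are required for three parameters.
    """
    v = np.asarray(volumes, dtype=float)
    rc = np.asarray(rc_values, dtype=float)
    if v.shape != rc.shape or v.ndim != 1:
        raise ValueError("volumes and rc_values must be 1-D and the same length")
    order = np.argsort(v, kind="stable")
    v, rc = v[order], rc[order]
    w = None if weights is None else np.asarray(weights, dtype=float)[order]
    if np.unique(v).size < 4:
        raise ValueError("need at least 4 distinct volumes for a 3-parameter fit")
    if np.any(v <= 0):
        raise ValueError("volumes must be > 0")
    a0 = max(float(rc.max()), 1e-6)
    v50_0 = float(np.median(v))
    best = None
    best_err = None
    for g0 in (0.5, 1.0, 2.0):
        p0 = [np.log(a0), np.log(v50_0), np.log(g0)]
        try:
            popt, pcov, ss = _fit_log_params(v, rc, p0, w)
        except (RuntimeError, optimize.OptimizeWarning):
            continue
        if best is None or ss < best[2]:
            best = (popt, pcov, ss)
        best_err = ss if best_err is None else min(best_err, ss)
    if best is None:
        raise RuntimeError("logistic fit failed to converge from every start")
    popt, pcov_log, _ = best
    A, V50, gamma = np.exp(popt)
    fitted = logistic_rc(v, A, V50, gamma)
    # delta method: cov of exp(p) = diag(exp(p)) @ cov_log @ diag(exp(p))
    J = np.diag(np.exp(popt))
    with np.errstate(invalid="ignore"):
        cov = J @ pcov_log @ J
    if np.std(fitted) == 0 or np.std(rc) == 0:
        r2 = 1.0 if np.allclose(fitted, rc) else 0.0
    else:
        r2 = float(np.corrcoef(rc, fitted)[0, 1] ** 2)
    return RCFit(A=float(A), V50=float(V50), gamma=float(gamma), r_squared=r2,
                 covariance=cov, volumes=v, rc_values=rc, fitted=fitted,
                 ci_level=ci_level)


def fit_bands(fit: RCFit, volume_grid, level: float = 0.95, n_boot: int = 1000,
              seed: int = 0) -> pd.DataFrame:
    """Smoothed residual-bootstrap confidence and prediction bands.

    Gaussian noise with the residual scale (variance SSR/(n - p), the
    unbiased estimate) is added onto the fitted curve and the model
    refitted per replicate; the CI band is the percentile envelope of the
    refitted curves, the prediction band additionally adds observation
    noise at each grid point.  The smoothed (parametric-residual) variant
    is used because a recovery curve has only ~6 points: the empirical
    residual distribution is too coarse for 95% tail quantiles.
    Reproducible under the seed.
    """
    if n_boot < 100:
        warnings.warn("n_boot < 100 gives unstable bands", stacklevel=2)
    grid = np.asarray(volume_grid, dtype=float)
    rng = np.random.default_rng(seed)
    n = len(fit.residuals)
    dof = max(n - 3, 1)
    s = float(np.sqrt(np.sum(fit.residuals**2) / dof))
    preds = np.empty((n_boot, grid.size))
    noise = np.empty((n_boot, grid.size))
    p0 = [np.log(fit.A), np.log(fit.V50), np.log(fit.gamma)]
    for b in range(n_boot):
        # propagate the uncertainty of the residual scale itself (few
        # degrees of freedom -> t-like tails): draw s_b from its chi^2
        # sampling distribution around the point estimate
        s_b = s * np.sqrt(dof / rng.chisquare(dof))
        rc_b = fit.fitted + rng.normal(0.0, s_b, size=n)
        try:
            popt, _, _ = _fit_log_params(fit.volumes, rc_b, p0)
            preds[b] = logistic_rc(grid, *np.exp(popt))
        except RuntimeError:
            preds[b] = fit.predict(grid)
        noise[b] = rng.normal(0.0, s_b, size=grid.size)
    alpha = (1.0 - level) / 2.0
    ci_lo, ci_hi = np.quantile(preds, [alpha, 1 - alpha], axis=0)
    pi_lo, pi_hi = np.quantile(preds + noise, [alpha, 1 - alpha], axis=0)
    rc_hat = fit.predict(grid)
    # prediction interval contains the confidence interval by construction;
    # enforce the pointwise ordering against quantile-estimation jitter
    pi_lo = np.minimum(pi_lo, ci_lo)
    pi_hi = np.maximum(pi_hi, ci_hi)
    return pd.DataFrame({"V": grid, "rc_hat": rc_hat, "ci_lo": ci_lo, "ci_hi": ci_hi,
                         "pi_lo": pi_lo, "pi_hi": pi_hi})


def fit_to_dict(fit: RCFit, bands: pd.DataFrame | None = None) -> dict:
    """JSON-ready view of a fit (and optional bands)."""
    out = {"A": fit.A, "V50_ml": fit.V50, "gamma": fit.gamma, "r2": fit.r_squared,
           "ci_level": fit.ci_level}
    if bands is not None:
        out["bands"] = bands.to_dict(orient="records")
    return out
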