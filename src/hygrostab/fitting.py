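"""Shared nonlinear-fitting and root-finding utilities.

Every model fit in the package goes through :func:`fit_curve`, which wraps
:func:`scipy.optimize.curve_fit` with bounded restarts and returns a
:class:`FitDiagnostics` record (RMSE as sqrt(mean squared residual), per-point
residuals, standard errors from the residual covariance).  Root finding is
plain bisection — deterministic and derivative-free.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .exceptions import DomainError, FitError

__all__ = ["FitDiagnostics", "fit_curve", "bisect_root", "fit_record"]


@dataclass(frozen=True)
class FitDiagnostics:
    """Goodness-of-fit record attached to every parameter estimate."""

    rmse: float
    n_obs: int
    converged: bool
    residuals: np.ndarray
    param_names: tuple[str, ...] = ()
    standard_errors: tuple[float, ...] = ()

    def __post_init__(self):
        if self.rmse < 0:
            raise DomainError("rmse must be non-negative")


def _jitter(p0, lo, hi, rng):
    p = np.asarray(p0, float) * rng.uniform(0.5, 1.5, size=len(p0))
    return np.clip(p, lo + 1e-12, hi - 1e-12 if np.all(np.isfinite(hi)) else p)


def fit_curve(model, x, y, p0, bounds, param_names, n_restarts=5):
    """Bounded least squares with deterministic restarts.

    Parameters
    ----------
    model : callable(x, *params) -> y
    p0 : initial parameter vector
    bounds : (lower, upper) sequences
    param_names : names reported in diagnostics and JSON fit records
    n_restarts : perturbed re-starts attempted after a failed first try

    Returns
    -------
    (params: ndarray, FitDiagnostics)

    Raises
    ------
    FitError if no start converges.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    lo = np.asarray(bounds[0], float)
    hi = np.asarray(bounds[1], float)
    p0 = np.clip(np.asarray(p0, float), lo, hi)
    rng = np.random.default_rng(0)  # restart jitter only; fit itself is deterministic
    last_err = None
    for attempt in range(n_restarts + 1):
        start = p0 if attempt == 0 else _jitter(p0, lo, hi, rng)
        try:
            popt, pcov = curve_fit(
                model, x, y, p0=start, bounds=(lo, hi), maxfev=20000,
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
        except (RuntimeError, ValueError) as err:
            last_err = err
            continue
        resid = y - model(x, *popt)
        rmse = float(np.sqrt(np.mean(resid ** 2)))
        with np.errstate(invalid="ignore"):
            se = tuple(float(s) for s in np.sqrt(np.diag(pcov)))
        diag = FitDiagnostics(
            rmse=rmse, n_obs=len(y), converged=True, residuals=resid,
            param_names=tuple(param_names), standard_errors=se,
        )
        return popt, diag
    raise FitError(f"fit did not converge after {n_restarts + 1} starts: {last_err}")


def bisect_root(f, lo, hi, tol=1e-6, max_iter=200):
    """Bisection root of a continuous scalar function on [lo, hi].

    Requires a sign change over the bracket; returns the midpoint once the
    bracket width falls below ``tol``.
    """
    flo, fhi = f(lo), f(hi)
    if flo == 0.0:
        return lo
    if fhi == 0.0:
        return hi
    if np.sign(flo) == np.sign(fhi):
        raise DomainError(f"no sign change on [{lo}, {hi}]")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        fm = f(mid)
        if fm == 0.0 or (hi - lo) < tol:
            return mid
        if np.sign(fm) == np.sign(flo):
            lo, flo = mid, fm
        else:
            hi, fhi = mid, fm
    return 0.5 * (lo + hi)


def fit_record(params: dict, diagnostics: FitDiagnostics) -> dict:
    """JSON-serialisable fit record: estimates, standard errors, RMSE, n_obs."""
    se = dict(zip(diagnostics.param_names, diagnostics.standard_errors))
    return {
        "parameters": {k: float(v) for k, v in params.items()},
        "standard_errors": {k: (None if not np.isfinite(v) else float(v))
                            for k, v in se.items()},
        "rmse": float(diagnostics.rmse),
        "n_obs": int(diagnostics.n_obs),
        "converged": bool(diagnostics.converged),
    }


def fit_record_json(params: dict, diagnostics: FitDiagnostics) -> str:
    return json.dumps(fit_record(params, diagnostics), indent=2)
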