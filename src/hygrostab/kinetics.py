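"""Empirical storage-kinetics models and time-to-threshold solvers.

Three laws cover the monitored responses of a stored powder:

* moisture uptake (wet-basis %, days) and dissolution absorbance (420 nm,
  seconds) both follow an asymptotic first-order approach to equilibrium,
  Y(t) = Yinf − (Yinf − Y0)·exp(−k·t);
* brew pH follows a pseudo-first-order decay, pH(t) = pH0·exp(−k·t).

Fits are plain nonlinear least squares on the original scale.  The inverse
problems (time until a response first reaches a level) have closed forms.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DomainError, FitError, NeverReachedError, UnitError
from .fitting import FitDiagnostics, fit_curve

__all__ = [
    "ResponseKind", "KineticSeries", "AsymptoticFirstOrderParams",
    "ExponentialDecayParams", "asymptotic_first_order",
    "fit_asymptotic_first_order", "exp_decay", "fit_exp_decay",
    "time_to_level_asymptotic", "time_to_level_decay", "read_kinetics_csv",
]


class ResponseKind(str, enum.Enum):
    MOISTURE = "moisture"   # wet-basis %, time in days
    ABS420 = "abs420"       # absorbance at 420 nm, time in seconds
    PH = "ph"               # brew pH, time in days


_EXPECTED_UNIT = {ResponseKind.MOISTURE: "days",
                  ResponseKind.ABS420: "seconds",
                  ResponseKind.PH: "days"}


@dataclass(frozen=True)
class KineticSeries:
    """One replicate time series of a monitored response."""

    times: np.ndarray
    values: np.ndarray
    response_kind: ResponseKind
    condition: str = ""        # ERH % label, e.g. "65"
    replicate: str = "r1"
    time_unit: str = ""

    def __post_init__(self):
        t = np.asarray(self.times, float)
        v = np.asarray(self.values, float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        kind = ResponseKind(self.response_kind)
        object.__setattr__(self, "response_kind", kind)
        unit = self.time_unit or _EXPECTED_UNIT[kind]
        object.__setattr__(self, "time_unit", unit)
        if unit != _EXPECTED_UNIT[kind]:
            raise UnitError(
                f"{kind.value} series must use {_EXPECTED_UNIT[kind]}, got '{unit}'")
        if t.ndim != 1 or t.shape != v.shape:
            raise DomainError("times and values must be equal-length 1-D arrays")
        if np.any(t < 0):
            raise DomainError("times must be non-negative")
        if np.any(np.diff(t) <= 0):
            raise DomainError("times must be strictly increasing within a replicate")
        if kind is ResponseKind.PH and np.any((v <= 0) | (v >= 14)):
            raise DomainError("pH values must lie in (0, 14)")
        if kind is ResponseKind.ABS420 and np.any(v < 0):
            raise DomainError("absorbance must be non-negative")


@dataclass(frozen=True)
class AsymptoticFirstOrderParams:
    """Y0 (response at t=0), Yinf (equilibrium), rate k (> 0).

    Yinf below Y0 describes a drying/decreasing series.
    """

    Y0: float
    Yinf: float
    k: float

    def __post_init__(self):
        if self.k <= 0:
            raise DomainError(f"rate k must be > 0: {self.k}")
        if self.Y0 == self.Yinf:
            raise DomainError("Y0 == Yinf makes the rate unidentifiable")


@dataclass(frozen=True)
class ExponentialDecayParams:
    """Initial pH and per-day decay rate (k = 0 means no decay)."""

    pH0: float
    k: float

    def __post_init__(self):
        if self.pH0 <= 0:
            raise DomainError(f"pH0 must be > 0: {self.pH0}")
        if self.k < 0:
            raise DomainError(f"decay rate must be >= 0: {self.k}")


def asymptotic_first_order(p: AsymptoticFirstOrderParams, t):
    """Y(t) = Yinf − (Yinf − Y0)·exp(−k·t) for t >= 0."""
    t = np.asarray(t, float)
    if np.any(t < 0):
        raise DomainError("t must be >= 0")
    out = p.Yinf - (p.Yinf - p.Y0) * np.exp(-p.k * t)
    return float(out) if out.ndim == 0 else out


def exp_decay(p: ExponentialDecayParams, t):
    """pH(t) = pH0·exp(−k·t) for t >= 0 (t in days)."""
    t = np.asarray(t, float)
    if np.any(t < 0):
        raise DomainError("t must be >= 0")
    out = p.pH0 * np.exp(-p.k * t)
    return float(out) if out.ndim == 0 else out


def _afo(t, Y0, Yinf, k):
    return Yinf - (Yinf - Y0) * np.exp(-k * t)


def _initial_rate_guess(t, v):
    """k0 = ln 2 / (time of first half-range crossing); robust fallback."""
    half = 0.5 * (v[0] + v[-1])
    rising = v[-1] >= v[0]
    crossed = np.nonzero(v >= half if rising else v <= half)[0]
    crossed = crossed[t[crossed] > 0]
    t_half = t[crossed[0]] if len(crossed) else np.median(t[t > 0])
    return np.log(2.0) / max(t_half, np.finfo(float).tiny)


def fit_asymptotic_first_order(
    s: KineticSeries,
) -> tuple[AsymptoticFirstOrderParams, FitDiagnostics]:
    """Least-squares fit of the asymptotic first-order law to one series."""
    t, v = s.times, s.values
    if len(np.unique(t)) < 4:
        raise DomainError(f"need >= 4 distinct time points, got {len(t)}")
    if np.ptp(v) < 1e-12 or np.std(v) < 1e-12:
        raise FitError("unidentifiable: series is flat (no response change)")
    p0 = (v[0], v[-1], _initial_rate_guess(t, v))
    bounds = ([-np.inf, -np.inf, 1e-8], [np.inf, np.inf, 1e3])
    popt, diag = fit_curve(_afo, t, v, p0, bounds, ("Y0", "Yinf", "k"))
    return AsymptoticFirstOrderParams(*popt), diag


def fit_exp_decay(s: KineticSeries) -> tuple[ExponentialDecayParams, FitDiagnostics]:
    """Least-squares pseudo-first-order decay fit on the original pH scale."""
    t, v = s.times, s.values
    if len(t) < 3:
        raise DomainError(f"need >= 3 points, got {len(t)}")
    if np.any(v <= 0):
        raise DomainError("pH values must be positive")
    # log-linear slope seeds the rate; the fit itself is not log-linearised
    slope = -np.polyfit(t, np.log(v), 1)[0]
    p0 = (v[0], max(slope, 1e-8))
    bounds = ([1e-6, 0.0], [14.0, 1e3])
    popt, diag = fit_curve(lambda tt, pH0, k: pH0 * np.exp(-k * tt),
                           t, v, p0, bounds, ("pH0", "k"))
    return ExponentialDecayParams(*popt), diag


def time_to_level_asymptotic(p: AsymptoticFirstOrderParams, level: float) -> float:
    """Time until the asymptotic first-order curve reaches ``level``.

    Closed form t = −ln((Yinf − level)/(Yinf − Y0)) / k.  ``level`` must lie
    between Y0 (inclusive, giving t = 0) and Yinf (exclusive).
    """
    if level == p.Y0:
        return 0.0
    lo, hi = min(p.Y0, p.Yinf), max(p.Y0, p.Yinf)
    if not (lo < level < hi):
        raise NeverReachedError(
            f"level {level} outside ({lo}, {hi}): never reached by this curve")
    return -np.log((p.Yinf - level) / (p.Yinf - p.Y0)) / p.k


def time_to_level_decay(p: ExponentialDecayParams, level: float) -> float:
    """Days until the pH decay curve falls to ``level``: t = ln(pH0/level)/k."""
    if level <= 0:
        raise DomainError(f"level must be > 0: {level}")
    if level >= p.pH0:
        warnings.warn(f"level {level} >= pH0 {p.pH0}; already below at t=0",
                      stacklevel=2)
        return 0.0
    if p.k == 0:
        raise NeverReachedError("k = 0: pH never decays to the requested level")
    return float(np.log(p.pH0 / level) / p.k)


def read_kinetics_csv(path) -> list[KineticSeries]:
    """Read a tidy kinetics CSV: ``time,value,unit,response,erh,replicate``.

    Returns one :class:`KineticSeries` per (response, erh, replicate) group,
    sorted by time.  Mixed time units within a group are a hard error.
    """
    df = pd.read_csv(path)
    required = {"time", "value", "unit", "response", "erh", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise DomainError(f"kinetics CSV missing columns: {sorted(missing)}")
    out = []
    for (resp, erh, rep), g in df.groupby(["response", "erh", "replicate"],
                                          sort=True):
        units = g["unit"].unique()
        if len(units) != 1:
            raise UnitError(
                f"mixed time units {sorted(units)} in series ({resp}, {erh}, {rep})")
        g = g.sort_values("time")
        out.append(KineticSeries(
            times=g["time"].to_numpy(float), values=g["value"].to_numpy(float),
            response_kind=ResponseKind(resp), condition=str(erh),
            replicate=str(rep), time_unit=str(units[0])))
    return out
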