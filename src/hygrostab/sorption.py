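"""Moisture accounting and water-vapour sorption modelling.

Moisture of a hygroscopic powder can be stated on a wet basis (percent of
total mass, as a gravimetric oven assay reports it) or a dry basis
(g water / g dry solids, the convention for sorption modelling).  This module
converts between the two, evaluates and fits the three-parameter
Guggenheim–Anderson–de Boer (GAB) sorption isotherm

    M(a_w) = m0 * b * C * a_w / [(1 - b*a_w) * (1 - b*a_w + C*b*a_w)]

where ``m0`` is the monolayer moisture (g/g db) and ``C``, ``b`` are the
energy constant and correction factor, derives the water activity at which
the isotherm crosses the monolayer, and implements the dynamic-vapour-
sorption (DVS) equilibrium rule (mass variation below a relative threshold
over a sliding time window).

All model-facing moisture is dry basis; wet-basis percentages are converted
at ingestion.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import DomainError, FitError
from .fitting import FitDiagnostics, bisect_root, fit_curve

__all__ = [
    "Basis", "MoistureValue", "IsothermData", "GABParams", "FitDiagnostics",
    "moisture_wb_from_weights", "convert_basis", "gab_moisture", "fit_gab",
    "monolayer_activity", "invert_gab", "detect_equilibrium",
    "read_isotherm_csv", "read_dvs_csv",
]

AW_MAX = 0.95  # upper edge of the modelled water-activity range


class Basis(str, enum.Enum):
    WET_PERCENT = "wet_percent"   # % of total mass
    DRY_RATIO = "dry_ratio"       # g water / g dry solids


@dataclass(frozen=True)
class MoistureValue:
    """A moisture quantity with an explicit basis."""

    value: float
    basis: Basis

    def __post_init__(self):
        b = Basis(self.basis)
        object.__setattr__(self, "basis", b)
        if b is Basis.WET_PERCENT and not (0.0 <= self.value < 100.0):
            raise DomainError(f"wet-basis moisture must be in [0, 100): {self.value}")
        if b is Basis.DRY_RATIO and self.value < 0.0:
            raise DomainError(f"dry-basis moisture must be >= 0: {self.value}")


@dataclass(frozen=True)
class IsothermData:
    """Equilibrium sorption points (a_w, dry-basis moisture), a_w increasing."""

    aw: np.ndarray
    moisture_db: np.ndarray

    def __post_init__(self):
        aw = np.asarray(self.aw, float)
        m = np.asarray(self.moisture_db, float)
        object.__setattr__(self, "aw", aw)
        object.__setattr__(self, "moisture_db", m)
        if aw.shape != m.shape or aw.ndim != 1:
            raise DomainError("aw and moisture_db must be equal-length 1-D arrays")
        if np.any(aw < 0) or np.any(aw > AW_MAX):
            raise DomainError(f"a_w must lie within [0, {AW_MAX}]")
        if np.any(np.diff(aw) <= 0):
            raise DomainError("a_w values must be strictly increasing")
        if np.any(m < 0):
            raise DomainError("moisture must be non-negative")

    def __len__(self):
        return len(self.aw)


@dataclass(frozen=True)
class GABParams:
    """GAB isotherm parameters: monolayer m0 (g/g db), C, b."""

    m0: float
    C: float
    b: float

    def __post_init__(self):
        if self.m0 <= 0:
            raise DomainError(f"m0 must be > 0: {self.m0}")
        if self.C <= 0:
            raise DomainError(f"C must be > 0: {self.C}")
        if not (0.0 < self.b < 1.0):
            raise DomainError(f"b must be in (0, 1): {self.b}")


def moisture_wb_from_weights(w_i: float, w_f: float) -> float:
    """Wet-basis moisture % from initial and oven-dry sample weights.

    M% = (w_i - w_f) / w_i * 100.
    """
    if w_i <= 0:
        raise DomainError(f"w_i must be positive: {w_i}")
    if w_f <= 0:
        raise DomainError(f"w_f must be positive: {w_f}")
    if w_f > w_i:
        raise DomainError(f"w_f ({w_f}) exceeds w_i ({w_i}); weights inverted?")
    return (w_i - w_f) / w_i * 100.0


def convert_basis(m: MoistureValue, target: Basis) -> MoistureValue:
    """Convert moisture between wet-basis % and dry-basis g/g.

    wet -> dry: M_db = (M_wb/100) / (1 - M_wb/100); dry -> wet is the
    inverse; same-basis conversion is the identity.
    """
    target = Basis(target)
    if m.basis is target:
        return m
    if m.basis is Basis.WET_PERCENT:
        frac = m.value / 100.0
        return MoistureValue(frac / (1.0 - frac), Basis.DRY_RATIO)
    return MoistureValue(m.value / (1.0 + m.value) * 100.0, Basis.WET_PERCENT)


def _gab(aw, m0, C, b):
    denom = (1.0 - b * aw) * (1.0 - b * aw + C * b * aw)
    return m0 * b * C * aw / denom


def gab_moisture(p: GABParams, a_w):
    """Dry-basis equilibrium moisture at water activity ``a_w``.

    ``a_w`` may be a scalar or array; must lie below the 1/b pole.
    """
    aw = np.asarray(a_w, float)
    if np.any(aw < 0):
        raise DomainError("a_w must be non-negative")
    if np.any(aw >= 1.0 / p.b):
        raise DomainError(f"a_w must be < 1/b = {1.0 / p.b:.4f} (isotherm pole)")
    out = _gab(aw, p.m0, p.C, p.b)
    return float(out) if np.isscalar(a_w) else out


def fit_gab(data: IsothermData) -> tuple[GABParams, FitDiagnostics]:
    """Least-squares GAB fit of an isotherm.

    Needs at least 4 points (3 free parameters).  Initialisation: m0 from the
    mid-grid moisture, C = 1, b = 0.9; bounds keep b away from its pole.
    """
    if len(data) < 4:
        raise DomainError(f"need >= 4 isotherm points, got {len(data)}")
    if float(np.max(data.moisture_db)) <= 0.0:
        raise FitError("degenerate isotherm: all moisture values are zero")
    mid = len(data) // 2
    p0 = (max(data.moisture_db[mid], 1e-4), 1.0, 0.9)
    bounds = ([1e-9, 1e-9, 1e-9], [1.0, 1e4, 0.9999])
    popt, diag = fit_curve(_gab, data.aw, data.moisture_db, p0, bounds,
                           ("m0", "C", "b"))
    return GABParams(*popt), diag


def monolayer_activity(p: GABParams, tol: float = 1e-9) -> float:
    """Water activity where the isotherm crosses the monolayer moisture m0.

    Solved by bisection on (0, 0.95]; raises if the isotherm never reaches m0
    within the range.
    """
    top = gab_moisture(p, AW_MAX)
    if top < p.m0:
        raise DomainError("isotherm never reaches the monolayer on (0, 0.95]")
    return bisect_root(lambda a: gab_moisture(p, a) - p.m0, 1e-9, AW_MAX, tol=tol)


def invert_gab(p: GABParams, M: float, tol: float = 1e-12) -> float:
    """Water activity at which the isotherm equals dry-basis moisture ``M``."""
    if M < 0:
        raise DomainError(f"moisture must be >= 0: {M}")
    if M == 0:
        return 0.0
    if M > gab_moisture(p, AW_MAX):
        raise DomainError(f"moisture {M} above attainable range on [0, {AW_MAX}]")
    return bisect_root(lambda a: gab_moisture(p, a) - M, 0.0, AW_MAX, tol=tol)


def detect_equilibrium(
    times: Sequence[float],
    masses: Sequence[float],
    rel_threshold: float = 0.0001,
    window: float = 8.5,
) -> tuple[bool, Optional[float]]:
    """DVS step-equilibrium detection.

    Scans candidate start times (the sample times); equilibrium is declared
    at the earliest time t such that the relative mass variation
    (max - min) / mass(t) over the inclusive window [t, t + window] is below
    ``rel_threshold``.  The value at the right window edge is obtained by
    linear interpolation.  Times are hours.

    Returns ``(True, t_eq)`` or ``(False, None)``.
    """
    t = np.asarray(times, float)
    m = np.asarray(masses, float)
    if t.ndim != 1 or t.shape != m.shape or len(t) < 2:
        raise DomainError("need matching 1-D time and mass series of length >= 2")
    if np.any(np.diff(t) <= 0):
        raise DomainError("times must be strictly increasing")
    if np.any(m <= 0):
        raise DomainError("masses must be positive")
    if t[-1] - t[0] < window:
        raise DomainError(
            f"series spans {t[-1] - t[0]:.3g} h, shorter than the {window} h window")
    for i in range(len(t)):
        right = t[i] + window
        if right > t[-1]:
            break
        sel = (t >= t[i]) & (t <= right)
        vals = m[sel]
        edge = float(np.interp(right, t, m))
        w_max = max(vals.max(), edge)
        w_min = min(vals.min(), edge)
        if (w_max - w_min) / m[i] < rel_threshold:
            return True, float(t[i])
    return False, None


def read_isotherm_csv(path) -> IsothermData:
    """Read an isotherm CSV with columns ``aw,moisture_db``."""
    df = pd.read_csv(path)
    for col in ("aw", "moisture_db"):
        if col not in df.columns:
            raise DomainError(f"isotherm CSV missing column '{col}'")
    return IsothermData(df["aw"].to_numpy(float), df["moisture_db"].to_numpy(float))


def read_dvs_csv(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a DVS mass trace CSV with columns ``time_h,mass_g``."""
    df = pd.read_csv(path)
    for col in ("time_h", "mass_g"):
        if col not in df.columns:
            raise DomainError(f"DVS CSV missing column '{col}'")
    return df["time_h"].to_numpy(float), df["mass_g"].to_numpy(float)
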