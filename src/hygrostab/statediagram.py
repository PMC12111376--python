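"""Glass-transition modelling and the modified state diagram.

Water plasticises amorphous food solids: the glass-transition temperature
T_g of a solids–water blend drops as the water mass fraction W rises,
following the Gordon–Taylor mixing rule

    T_g(W) = (k*Tgi + eps*W*Tgw) / (k + eps*W),      k = 1 - W,

with Tgi the anhydrous-solids T_g, Tgw = −135 °C the T_g of amorphous water,
and eps the single interaction parameter.  Chaining the rule through a
sorption isotherm gives T_g as a function of water activity — the modified
state diagram — from which the critical water activity (where T_g equals the
storage temperature) and the matching critical moisture follow, along with a
glassy / transition / rubbery classification of a storage condition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DomainError
from .fitting import FitDiagnostics, bisect_root, fit_curve
from .sorption import AW_MAX, GABParams, gab_moisture, invert_gab

__all__ = [
    "TGW_DEFAULT", "GordonTaylorParams", "CompositionFractions", "StateDiagram",
    "StateLabel", "water_fraction_from_dry", "gordon_taylor_tg",
    "fit_gordon_taylor", "tg_at_aw", "critical_aw", "critical_moisture",
    "classify_state", "read_tg_csv", "state_diagram_table", "plot_state_diagram",
]

TGW_DEFAULT = -135.0  # °C, glass transition of amorphous water


@dataclass(frozen=True)
class GordonTaylorParams:
    """Gordon–Taylor parameters: anhydrous Tgi (°C), parameter eps, water Tgw."""

    Tgi: float
    epsilon: float
    Tgw: float = TGW_DEFAULT

    def __post_init__(self):
        if self.Tgi <= self.Tgw:
            raise DomainError(f"Tgi ({self.Tgi}) must exceed Tgw ({self.Tgw})")
        if self.epsilon <= 0:
            raise DomainError(f"epsilon must be > 0: {self.epsilon}")


@dataclass(frozen=True)
class CompositionFractions:
    """Water and solids mass fractions of a blend (sum to 1)."""

    W: float
    k: float

    def __post_init__(self):
        if not (0.0 <= self.W <= 1.0 and 0.0 <= self.k <= 1.0):
            raise DomainError("fractions must lie in [0, 1]")
        if abs(self.W + self.k - 1.0) > 1e-9:
            raise DomainError(f"W + k must equal 1, got {self.W + self.k}")

    @classmethod
    def from_water(cls, W: float) -> "CompositionFractions":
        return cls(W=W, k=1.0 - W)


@dataclass(frozen=True)
class StateDiagram:
    """Sorption isotherm + Gordon–Taylor curve at a storage temperature."""

    gab: GABParams
    gt: GordonTaylorParams
    T_storage: float  # °C


@dataclass(frozen=True)
class StateLabel:
    """Physical-state call for a storage condition.

    glassy:     deltaT < 0
    transition: 0 <= deltaT <= band (default 5 °C; a ΔT this small is not
                enough for a complete glass–rubber transition)
    rubbery:    deltaT > band
    """

    label: str
    deltaT: float


def water_fraction_from_dry(M_db: float) -> float:
    """Total-mass water fraction W from dry-basis moisture: W = M/(1+M)."""
    if M_db < 0:
        raise DomainError(f"dry-basis moisture must be >= 0: {M_db}")
    return M_db / (1.0 + M_db)


def gordon_taylor_tg(gt: GordonTaylorParams, comp: CompositionFractions) -> float:
    """Blend T_g (°C) from the Gordon–Taylor mixing rule."""
    denom = comp.k + gt.epsilon * comp.W
    if denom == 0:
        raise DomainError("k + epsilon*W is zero")
    return (comp.k * gt.Tgi + gt.epsilon * comp.W * gt.Tgw) / denom


def _gt_curve(W, Tgi, eps, Tgw):
    k = 1.0 - W
    return (k * Tgi + eps * W * Tgw) / (k + eps * W)


def fit_gordon_taylor(
    data, Tgw: float = TGW_DEFAULT
) -> tuple[GordonTaylorParams, FitDiagnostics]:
    """Least-squares (Tgi, eps) fit of T_g-vs-water-fraction data, Tgw fixed.

    ``data``: sequence of (W, Tg °C) pairs, W in [0, 0.5]; needs >= 3 points.
    """
    arr = np.asarray(data, float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise DomainError("need >= 3 (W, Tg) points")
    W, Tg = arr[:, 0], arr[:, 1]
    if np.any((W < 0) | (W > 0.5)):
        raise DomainError("water fractions must lie in [0, 0.5]")
    p0 = (float(Tg.max()), 5.0)
    bounds = ([Tgw + 1e-6, 1e-6], [500.0, 1e3])
    popt, diag = fit_curve(lambda w, Tgi, eps: _gt_curve(w, Tgi, eps, Tgw),
                           W, Tg, p0, bounds, ("Tgi", "epsilon"))
    return GordonTaylorParams(Tgi=popt[0], epsilon=popt[1], Tgw=Tgw), diag


def tg_at_aw(sd: StateDiagram, a_w: float) -> float:
    """T_g at a water activity: isotherm moisture -> W -> Gordon–Taylor."""
    if not (0.0 <= a_w <= AW_MAX):
        raise DomainError(f"a_w must lie in [0, {AW_MAX}]")
    M = gab_moisture(sd.gab, a_w)
    W = water_fraction_from_dry(M)
    return gordon_taylor_tg(sd.gt, CompositionFractions.from_water(W))


def critical_aw(sd: StateDiagram, tol: float = 1e-9) -> float:
    """Water activity at which T_g falls to the storage temperature.

    The chained T_g(a_w) curve is strictly decreasing, so the crossing is
    unique; raised errors state the direction when there is no crossing.
    """
    hi_tg = tg_at_aw(sd, 0.0)
    lo_tg = tg_at_aw(sd, AW_MAX)
    if sd.T_storage >= hi_tg:
        raise DomainError(
            f"T_storage {sd.T_storage} °C >= T_g at a_w=0 ({hi_tg:.2f} °C): always rubbery")
    if sd.T_storage <= lo_tg:
        raise DomainError(
            f"T_storage {sd.T_storage} °C <= T_g at a_w={AW_MAX} ({lo_tg:.2f} °C): always glassy")
    return bisect_root(lambda a: tg_at_aw(sd, a) - sd.T_storage, 0.0, AW_MAX, tol=tol)


def critical_moisture(sd: StateDiagram) -> float:
    """Dry-basis moisture at the critical water activity."""
    return gab_moisture(sd.gab, critical_aw(sd))


def classify_state(T: float, Tg: float, transition_band: float = 5.0) -> StateLabel:
    """Classify a storage condition by ΔT = T − T_g (closed transition band)."""
    if not (np.isfinite(T) and np.isfinite(Tg)):
        raise DomainError("temperatures must be finite")
    dT = T - Tg
    if dT < 0:
        label = "glassy"
    elif dT <= transition_band:
        label = "transition"
    else:
        label = "rubbery"
    return StateLabel(label=label, deltaT=dT)


def read_tg_csv(path, gab: GABParams | None = None):
    """Read T_g data as (W, Tg) pairs.

    Accepts ``water_fraction,tg_c`` directly, or ``aw,tg_c`` — the latter
    needs a GAB parameterisation to map a_w to a water fraction.
    """
    df = pd.read_csv(path)
    if "tg_c" not in df.columns:
        raise DomainError("T_g CSV missing column 'tg_c'")
    if "water_fraction" in df.columns:
        W = df["water_fraction"].to_numpy(float)
    elif "aw" in df.columns:
        if gab is None:
            raise DomainError("aw-keyed T_g CSV requires GAB parameters")
        W = np.array([water_fraction_from_dry(gab_moisture(gab, a))
                      for a in df["aw"].to_numpy(float)])
    else:
        raise DomainError("T_g CSV needs a 'water_fraction' or 'aw' column")
    return np.column_stack([W, df["tg_c"].to_numpy(float)])


def state_diagram_table(sd: StateDiagram, aw_grid=None) -> pd.DataFrame:
    """Sample both state-diagram curves on an a_w grid (for export/plotting)."""
    if aw_grid is None:
        aw_grid = np.round(np.arange(0.0, AW_MAX + 1e-9, 0.05), 10)
    aw = np.asarray(aw_grid, float)
    M = gab_moisture(sd.gab, aw)
    tg = np.array([tg_at_aw(sd, a) for a in aw])
    return pd.DataFrame({"aw": aw, "moisture_db": M, "tg_c": tg})


def plot_state_diagram(sd: StateDiagram, aw_grid=None, ax=None):
    """Optional matplotlib rendering of the modified state diagram."""
    import matplotlib.pyplot as plt

    tbl = state_diagram_table(sd, aw_grid)
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(tbl["aw"], tbl["tg_c"], color="tab:orange", label="T_g (°C)")
    ax.axhline(sd.T_storage, ls="--", color="grey", lw=0.8,
               label=f"T_storage = {sd.T_storage} °C")
    ax.set_xlabel("water activity a_w")
    ax.set_ylabel("T_g (°C)")
    ax2 = ax.twinx()
    ax2.plot(tbl["aw"], tbl["moisture_db"], color="tab:blue",
             label="moisture (g/g db)")
    ax2.set_ylabel("moisture (g/g db)")
    ax.legend(loc="lower left")
    return ax
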