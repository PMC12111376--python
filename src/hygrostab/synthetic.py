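"""Seeded synthetic-data generators emulating the storage study design.

The study layout being emulated: bulk instant coffee held at 20 °C under
three environmental relative humidities (11, 32, 65 % ERH), monitored in
triplicate for wet-basis moisture (days), dissolution absorbance at 420 nm
(seconds), and brew pH (days); a dynamic-vapour-sorption isotherm over
a_w 0–0.9 in 0.1 steps; glass-transition points at seven salt-conditioned
ERH levels (1, 11, 23, 32, 43, 54, 65 %); and powder photographs whose
in-range pixel fraction declines as the simulated moisture rises.

Generating parameters default to the published fitted values (see
``StudyConfig``); noise is additive Gaussian at the printed measurement-SD
scale, independent across replicates and time points.  Every generator is a
pure function of (parameters, seed) — reruns are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .exceptions import DomainError
from .imaging import RGBRanges
from .kinetics import (AsymptoticFirstOrderParams, ExponentialDecayParams,
                       KineticSeries, ResponseKind, asymptotic_first_order,
                       exp_decay)
from .sorption import GABParams, IsothermData, gab_moisture
from .statediagram import (CompositionFractions, GordonTaylorParams,
                           StateDiagram, gordon_taylor_tg, tg_at_aw,
                           water_fraction_from_dry)

__all__ = [
    "GAB_PUBLISHED", "GT_PUBLISHED", "MOISTURE_KINETICS", "DISSOLUTION_KINETICS",
    "PH_KINETICS", "PH_RATE_SCALE", "SALT_ERH_LEVELS", "StudyConfig",
    "gen_isotherm", "gen_tg_points", "gen_kinetic_series", "gen_powder_images",
    "gen_study",
]

# Published fitted parameters used as generating truths.
GAB_PUBLISHED = GABParams(m0=0.06, C=1.10, b=0.99)
GT_PUBLISHED = GordonTaylorParams(Tgi=47.8, epsilon=7.2)

# Moisture uptake (wet-basis %, per day), by ERH %.  The 11 % condition dries.
MOISTURE_KINETICS = {
    11: AsymptoticFirstOrderParams(Y0=3.5, Yinf=2.8, k=0.08),
    32: AsymptoticFirstOrderParams(Y0=3.5, Yinf=5.8, k=0.18),
    65: AsymptoticFirstOrderParams(Y0=3.3, Yinf=14.7, k=0.15),
}
# Dissolution absorbance at 420 nm (per second), by ERH %.
DISSOLUTION_KINETICS = {
    11: AsymptoticFirstOrderParams(Y0=0.008, Yinf=0.124, k=0.13),
    32: AsymptoticFirstOrderParams(Y0=0.005, Yinf=0.118, k=0.08),
    65: AsymptoticFirstOrderParams(Y0=0.002, Yinf=0.101, k=0.07),
}
# Brew pH decay, by ERH %.  Rates are the published table magnitudes; the
# physically consistent display scale is k x 1e-4 per day (PH_RATE_SCALE).
PH_KINETICS = {
    11: ExponentialDecayParams(pH0=5.07, k=0.38),
    32: ExponentialDecayParams(pH0=5.07, k=0.72),
    65: ExponentialDecayParams(pH0=5.08, k=2.11),
}
PH_RATE_SCALE = 1e-4  # day^-1 per table unit

SALT_ERH_LEVELS = (1, 11, 23, 32, 43, 54, 65)  # % ERH of the salt series

DEFAULT_TIMEPOINTS = {
    ResponseKind.MOISTURE: {11: tuple(range(0, 20)), 32: tuple(range(0, 20)),
                            65: tuple(range(0, 31))},
    ResponseKind.ABS420: {erh: (3, 10, 20, 30, 45, 60, 120)
                          for erh in (11, 32, 65)},
    ResponseKind.PH: {erh: tuple(range(0, 181, 15)) for erh in (11, 32, 65)},
}

DEFAULT_NOISE_SD = {ResponseKind.MOISTURE: 0.11, ResponseKind.ABS420: 0.004,
                    ResponseKind.PH: 0.03}

# Logistic link tying the in-range image fraction to wet-basis moisture %:
# fraction = 1 / (1 + exp(slope * (M - midpoint))).  Midpoint/slope are set
# so the worst-case condition loses ~70 % of fresh pixels within one week
# while the dry conditions stay near 100 %.
IMAGE_LINK_MIDPOINT = 9.7   # wet-basis moisture %
IMAGE_LINK_SLOPE = 0.8      # per moisture %
DEFAULT_IMAGE_DAYS = (0, 1, 3, 7, 14)


@dataclass(frozen=True)
class StudyConfig:
    """Complete parameterisation of a synthetic storage study."""

    seed: int
    erh_levels: tuple = (11, 32, 65)
    T_storage: float = 20.0
    replicates: int = 3
    gab: GABParams = GAB_PUBLISHED
    gt: GordonTaylorParams = GT_PUBLISHED
    moisture_kinetics: dict = field(default_factory=lambda: dict(MOISTURE_KINETICS))
    dissolution_kinetics: dict = field(
        default_factory=lambda: dict(DISSOLUTION_KINETICS))
    ph_kinetics: dict = field(default_factory=lambda: dict(PH_KINETICS))
    ph_rate_scale: float = PH_RATE_SCALE
    noise_sd: dict = field(default_factory=lambda: dict(DEFAULT_NOISE_SD))
    isotherm_noise_sd: float = 0.002   # g/g db
    tg_noise_sd: float = 1.0           # °C
    isotherm_aw_grid: tuple = tuple(np.round(np.arange(0.0, 0.91, 0.1), 10))
    salt_erh_levels: tuple = SALT_ERH_LEVELS
    image_days: tuple = DEFAULT_IMAGE_DAYS
    image_size: tuple = (64, 64)
    baseline_ranges: RGBRanges = RGBRanges()

    def __post_init__(self):
        if self.seed is None:
            raise DomainError("a seed is mandatory for stochastic generation")
        if any(not (0 < e < 100) for e in self.erh_levels):
            raise DomainError("ERH levels must lie in (0, 100)")
        if self.replicates < 1:
            raise DomainError("replicates must be >= 1")
        for name, sd in [("isotherm_noise_sd", self.isotherm_noise_sd),
                         ("tg_noise_sd", self.tg_noise_sd),
                         *((str(k), v) for k, v in self.noise_sd.items())]:
            if float(sd) < 0:
                raise DomainError(f"noise SD '{name}' must be >= 0")

    def to_json_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["baseline_ranges"] = dataclasses.asdict(self.baseline_ranges)
        d["noise_sd"] = {k.value if isinstance(k, ResponseKind) else str(k): v
                         for k, v in self.noise_sd.items()}
        for key in ("moisture_kinetics", "dissolution_kinetics", "ph_kinetics"):
            d[key] = {str(erh): p for erh, p in d[key].items()}
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_json_dict(), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()


def gen_isotherm(gab: GABParams, aw_grid=None, noise_sd: float = 0.0,
                 seed: int = 0) -> IsothermData:
    """Synthetic equilibrium isotherm on an a_w grid, Gaussian moisture noise
    truncated at zero.  noise_sd = 0 returns exact model values."""
    if aw_grid is None:
        aw_grid = np.round(np.arange(0.0, 0.91, 0.1), 10)
    aw = np.asarray(aw_grid, float)
    if np.any((aw < 0) | (aw > 0.95)):
        raise DomainError("a_w grid must lie within [0, 0.95]")
    M = gab_moisture(gab, aw)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        M = np.maximum(M + rng.normal(0.0, noise_sd, size=len(aw)), 0.0)
    return IsothermData(aw=aw, moisture_db=np.asarray(M, float))


def gen_tg_points(gt: GordonTaylorParams, gab: GABParams,
                  erh_levels=SALT_ERH_LEVELS, noise_sd: float = 0.0,
                  seed: int = 0) -> np.ndarray:
    """(W, Tg) points at salt-conditioned ERH levels via the chained
    state-diagram curve, with Gaussian Tg noise."""
    aw = np.asarray(erh_levels, float) / 100.0
    M = gab_moisture(gab, aw)
    W = M / (1.0 + M)
    Tg = np.array([gordon_taylor_tg(gt, CompositionFractions.from_water(w))
                   for w in W])
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        Tg = Tg + rng.normal(0.0, noise_sd, size=len(Tg))
    return np.column_stack([W, Tg])


def _forward(params, t, response_kind):
    if response_kind is ResponseKind.PH:
        return exp_decay(params, t)
    return asymptotic_first_order(params, t)


def gen_kinetic_series(params, times, noise_sd: float, replicates: int,
                       seed: int, response_kind, condition: str = "",
                       ) -> list[KineticSeries]:
    """Replicate kinetic series from a forward model plus Gaussian noise.

    pH series are clipped into (0, 14); replicate noise draws are
    independent.  For pH the generating rate is taken at face value in
    day^-1 — callers pick the time grid accordingly.
    """
    kind = ResponseKind(response_kind)
    t = np.asarray(times, float)
    clean = _forward(params, t, kind)
    rng = np.random.default_rng(seed)
    out = []
    for r in range(replicates):
        v = np.asarray(clean, float).copy()
        if noise_sd > 0:
            v = v + rng.normal(0.0, noise_sd, size=len(t))
        if kind is ResponseKind.PH:
            v = np.clip(v, 1e-6, 14.0 - 1e-6)
        if kind is ResponseKind.ABS420:
            v = np.maximum(v, 0.0)
        out.append(KineticSeries(times=t, values=v, response_kind=kind,
                                 condition=str(condition), replicate=f"r{r + 1}"))
    return out


def moisture_to_fresh_fraction(m_wet_pct, midpoint=IMAGE_LINK_MIDPOINT,
                               slope=IMAGE_LINK_SLOPE):
    """Logistic link from wet-basis moisture % to the in-range pixel fraction."""
    m = np.asarray(m_wet_pct, float)
    return 1.0 / (1.0 + np.exp(slope * (m - midpoint)))


def gen_powder_images(baseline_ranges: RGBRanges, in_range_fraction_schedule,
                      size=(64, 64), seed: int = 0) -> list[np.ndarray]:
    """Image series with exactly round(fraction * n_total) in-range pixels.

    The first schedule entry must be 1.0 (the fresh baseline).  In-range
    pixels are drawn uniformly inside the baseline ranges; the remainder are
    brightened out of range (each channel above its upper bound), emulating
    the optical change of a caking powder while keeping the freshness index
    analytically known: index_t = 100 * fraction_t.
    """
    sched = list(in_range_fraction_schedule)
    if not sched:
        raise DomainError("fraction schedule must be non-empty")
    if any(not (0.0 <= f <= 1.0) for f in sched):
        raise DomainError("fractions must lie in [0, 1]")
    if sched[0] != 1.0:
        raise DomainError("first schedule entry must be 1.0 (fresh baseline)")
    if baseline_ranges.highs.max() >= 255:
        raise DomainError("ranges touching 255 leave no out-of-range headroom")
    h, w = size
    n_total = h * w
    rng = np.random.default_rng(seed)
    lows, highs = baseline_ranges.lows, baseline_ranges.highs
    images = []
    for frac in sched:
        n_in = int(round(frac * n_total))
        flat = np.empty((n_total, 3), dtype=np.uint8)
        for c in range(3):
            flat[:n_in, c] = rng.integers(lows[c], highs[c] + 1, size=n_in)
            flat[n_in:, c] = rng.integers(highs[c] + 1, 256, size=n_total - n_in)
        perm = rng.permutation(n_total)
        images.append(flat[perm].reshape(h, w, 3))
    return images


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def gen_study(cfg: StudyConfig, out_dir) -> dict:
    """Write a complete synthetic study dataset to ``out_dir``.

    Layout: ``isotherm.csv`` (aw,moisture_db), ``tg.csv``
    (water_fraction,tg_c), ``kinetics.csv`` (tidy time,value,unit,response,
    erh,replicate), ``images/erh{E}_d{day}.png``, and ``manifest.json``
    recording the seed, config hash and per-file SHA-256 checksums.
    Deterministic: the same config yields byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "images").mkdir(exist_ok=True)
    base = int(cfg.seed)

    iso = gen_isotherm(cfg.gab, cfg.isotherm_aw_grid, cfg.isotherm_noise_sd,
                       seed=base * 1000 + 1)
    pd.DataFrame({"aw": iso.aw, "moisture_db": iso.moisture_db}).to_csv(
        out / "isotherm.csv", index=False)

    tg = gen_tg_points(cfg.gt, cfg.gab, cfg.salt_erh_levels, cfg.tg_noise_sd,
                       seed=base * 1000 + 2)
    pd.DataFrame({"water_fraction": tg[:, 0], "tg_c": tg[:, 1]}).to_csv(
        out / "tg.csv", index=False)

    rows = []
    param_maps = {ResponseKind.MOISTURE: cfg.moisture_kinetics,
                  ResponseKind.ABS420: cfg.dissolution_kinetics,
                  ResponseKind.PH: cfg.ph_kinetics}
    for ki, (kind, params_by_erh) in enumerate(param_maps.items()):
        for ei, erh in enumerate(cfg.erh_levels):
            params = params_by_erh[erh]
            if kind is ResponseKind.PH:
                # table magnitudes are only physical at the 1e-4/day scale;
                # the storage series spans months, so generate on that scale
                params = dataclasses.replace(params,
                                             k=params.k * cfg.ph_rate_scale)
            times = DEFAULT_TIMEPOINTS[kind].get(erh,
                                                 next(iter(DEFAULT_TIMEPOINTS[kind].values())))
            series = gen_kinetic_series(
                params, times, cfg.noise_sd[kind], cfg.replicates,
                seed=base * 1000 + 10 + ki * 10 + ei,
                response_kind=kind, condition=str(erh))
            for s in series:
                for t, v in zip(s.times, s.values):
                    rows.append({"time": t, "value": v, "unit": s.time_unit,
                                 "response": kind.value, "erh": erh,
                                 "replicate": s.replicate})
    pd.DataFrame(rows).to_csv(out / "kinetics.csv", index=False)

    image_index = []
    for ei, erh in enumerate(cfg.erh_levels):
        mk = cfg.moisture_kinetics[erh]
        m_t = asymptotic_first_order(mk, np.asarray(cfg.image_days, float))
        sched = [1.0] + list(moisture_to_fresh_fraction(m_t[1:]))
        imgs = gen_powder_images(cfg.baseline_ranges, sched, cfg.image_size,
                                 seed=base * 1000 + 500 + ei)
        for day, img in zip(cfg.image_days, imgs):
            name = f"images/erh{erh}_d{day}.png"
            Image.fromarray(img, mode="RGB").save(out / name)
            image_index.append({"erh": erh, "day": day, "file": name})

    manifest = {
        "schema_version": 1,
        "seed": cfg.seed,
        "config": cfg.to_json_dict(),
        "config_hash": cfg.config_hash(),
        "images": image_index,
        "files": {},
    }
    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest["files"][str(p.relative_to(out))] = _sha256(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=list))
    return manifest
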