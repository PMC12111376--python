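"""End-to-end study orchestration: fits, state diagram, shelf-life clocks,
freshness, and group statistics, emitted as a structured report.

Stages (each isolated — a failure marks the report partial without killing
the rest):

1. GAB isotherm fit -> monolayer moisture and activity;
2. Gordon–Taylor fit -> state diagram, critical a_w / moisture at the
   storage temperature, per-condition T_g and physical-state call at
   a_w = ERH/100 (equilibrium assumption);
3. kinetic fits per condition (moisture, dissolution absorbance, pH);
4. failure clocks: time for moisture to reach the monolayer-equivalent
   wet-basis level, and time for brew pH to fall below 5.0 and 5.1 (the pH
   rates are interpreted on the 1e-4 day^-1 physical scale; the raw fitted
   magnitudes are reported alongside);
5. freshness-index trajectories and their correlation with moisture;
6. ANOVA + Tukey letters (uppercase across conditions at a shared time,
   lowercase across times within a condition).

No single "shelf life = X days" figure is produced: the three failure
clocks are reported side by side.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .exceptions import DomainError, HygrostabError, NeverReachedError
from .fitting import fit_record
from .groupstats import GroupData, tukey_between, tukey_repeated
from .imaging import RGBRanges, freshness_index, fresh_mask, load_image, pearson_r
from .kinetics import (ResponseKind, asymptotic_first_order,
                       fit_asymptotic_first_order, fit_exp_decay,
                       read_kinetics_csv, time_to_level_asymptotic,
                       time_to_level_decay)
from .sorption import (Basis, MoistureValue, convert_basis, fit_gab,
                       monolayer_activity, read_isotherm_csv)
from .statediagram import (StateDiagram, classify_state, critical_aw,
                           critical_moisture, fit_gordon_taylor, read_tg_csv,
                           tg_at_aw)
from .synthetic import PH_RATE_SCALE, StudyConfig

log = logging.getLogger("hygrostab.pipeline")

__all__ = ["ShelfLifeReport", "run_study", "export_report"]

REPORT_SCHEMA_VERSION = 1


@dataclass
class ShelfLifeReport:
    """Structured outcome of a full study run."""

    stages: dict = field(default_factory=dict)      # stage -> "ok" | error text
    isotherm: dict = field(default_factory=dict)
    state: dict = field(default_factory=dict)
    kinetics: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)
    freshness: dict = field(default_factory=dict)
    statistics: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    @property
    def partial(self) -> bool:
        return any(v != "ok" for v in self.stages.values())


def _stage(report, name):
    class _Ctx:
        def __enter__(self):
            self.t0 = _time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = _time.perf_counter() - self.t0
            if exc is None:
                report.stages[name] = "ok"
                log.info("stage %-12s ok (%.2f s)", name, dt)
                return False
            report.stages[name] = f"failed: {exc}"
            log.warning("stage %-12s FAILED (%.2f s): %s", name, dt, exc)
            return True  # swallow; report marked partial

    return _Ctx()


def _clock(fn, *args):
    import warnings

    try:
        with warnings.catch_warnings():
            # a threshold already passed at t=0 returns 0 by convention
            warnings.simplefilter("ignore", UserWarning)
            return float(fn(*args))
    except (NeverReachedError, DomainError):
        return None


def run_study(config: StudyConfig, data_dir) -> ShelfLifeReport:
    """Run every analysis stage on a study dataset directory."""
    data = Path(data_dir)
    report = ShelfLifeReport()
    report.provenance = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "data_dir": str(data),
    }
    manifest = None
    mpath = data / "manifest.json"
    if mpath.exists():
        manifest = json.loads(mpath.read_text())
        report.provenance["data_config_hash"] = manifest.get("config_hash")

    gab = None
    with _stage(report, "isotherm"):
        iso = read_isotherm_csv(data / "isotherm.csv")
        gab, diag = fit_gab(iso)
        aw0 = monolayer_activity(gab)
        m0_wet = convert_basis(MoistureValue(gab.m0, Basis.DRY_RATIO),
                               Basis.WET_PERCENT).value
        report.isotherm = {
            "fit": fit_record({"m0": gab.m0, "C": gab.C, "b": gab.b}, diag),
            "monolayer_aw": float(aw0),
            "monolayer_moisture_db": float(gab.m0),
            "monolayer_moisture_wet_pct": float(m0_wet),
        }

    sd = None
    with _stage(report, "state"):
        if gab is None:
            raise DomainError("isotherm stage did not produce GAB parameters")
        gt_data = read_tg_csv(data / "tg.csv", gab=gab)
        gt, gt_diag = fit_gordon_taylor(gt_data)
        sd = StateDiagram(gab=gab, gt=gt, T_storage=config.T_storage)
        aw_c = critical_aw(sd)
        per_erh = {}
        for erh in config.erh_levels:
            aw = erh / 100.0
            tg = tg_at_aw(sd, aw)
            lab = classify_state(config.T_storage, tg)
            per_erh[str(erh)] = {"aw": aw, "tg_c": float(tg),
                                 "state": lab.label,
                                 "deltaT_c": float(lab.deltaT)}
        report.state = {
            "fit": fit_record({"Tgi": gt.Tgi, "epsilon": gt.epsilon}, gt_diag),
            "Tgw_c": gt.Tgw,
            "T_storage_c": config.T_storage,
            "critical_aw": float(aw_c),
            "critical_moisture_db": float(critical_moisture(sd)),
            "per_erh": per_erh,
        }

    series = None
    fits = {}
    with _stage(report, "kinetics"):
        series = read_kinetics_csv(data / "kinetics.csv")
        for kind in ResponseKind:
            fits[kind] = {}
            for erh in config.erh_levels:
                grp = [s for s in series
                       if s.response_kind is kind and s.condition == str(erh)]
                if not grp:
                    continue
                # fit the replicate-pooled mean trajectory
                times = grp[0].times
                values = np.mean([s.values for s in grp], axis=0)
                pooled = dataclasses.replace(grp[0], values=values,
                                             replicate="pooled")
                if kind is ResponseKind.PH:
                    p, d = fit_exp_decay(pooled)
                    rec = fit_record({"pH0": p.pH0, "k": p.k}, d)
                    # fitted k is day^-1; also report the table-unit magnitude
                    rec["parameters"]["k_table_units"] = p.k / PH_RATE_SCALE
                else:
                    p, d = fit_asymptotic_first_order(pooled)
                    rec = fit_record({"Y0": p.Y0, "Yinf": p.Yinf, "k": p.k}, d)
                fits[kind][erh] = (p, rec)
            report.kinetics[kind.value] = {str(e): r for e, (_, r)
                                           in fits[kind].items()}

    with _stage(report, "thresholds"):
        if gab is None or not fits:
            raise DomainError("needs isotherm and kinetics stages")
        m0_wet = report.isotherm["monolayer_moisture_wet_pct"]
        out = {}
        for erh in config.erh_levels:
            entry = {}
            pm = fits.get(ResponseKind.MOISTURE, {}).get(erh)
            entry["time_to_monolayer_days"] = (
                _clock(time_to_level_asymptotic, pm[0], m0_wet) if pm else None)
            pp = fits.get(ResponseKind.PH, {}).get(erh)
            if pp:
                for lim in (5.0, 5.1):
                    entry[f"time_to_ph_below_{lim}_days"] = (
                        _clock(time_to_level_decay, pp[0], lim)
                        if pp[0].k > 0 else None)
            out[str(erh)] = entry
        report.thresholds = out

    with _stage(report, "freshness"):
        if manifest is None or not manifest.get("images"):
            raise DomainError("no image index in manifest")
        ranges = config.baseline_ranges
        traj = {}
        for erh in config.erh_levels:
            entries = [e for e in manifest["images"] if e["erh"] == erh]
            if not entries:
                continue
            entries.sort(key=lambda e: e["day"])
            baseline = load_image(data / entries[0]["file"])
            base_count = int(fresh_mask(baseline, ranges).sum())
            rows = []
            for e in entries:
                res = freshness_index(load_image(data / e["file"]), ranges,
                                      base_count)
                rows.append({"day": e["day"], "index_pct": res.index,
                             "n_in_range": res.n_in_range,
                             "n_total": res.n_total})
            rec = {"trajectory": rows}
            pm = fits.get(ResponseKind.MOISTURE, {}).get(erh)
            if pm is not None and len(rows) >= 3:
                days = np.array([r["day"] for r in rows], float)
                idx = np.array([r["index_pct"] for r in rows], float)
                try:
                    rec["r_moisture_vs_index"] = pearson_r(
                        asymptotic_first_order(pm[0], days), idx)
                except DomainError:
                    rec["r_moisture_vs_index"] = None
            traj[str(erh)] = rec
        report.freshness = {"ranges": dataclasses.asdict(ranges), **traj}

    with _stage(report, "statistics"):
        if series is None:
            raise DomainError("kinetics series unavailable")
        stats_out = {}
        for kind in ResponseKind:
            kind_series = [s for s in series if s.response_kind is kind]
            if not kind_series:
                continue
            entry = {"between_erh": {}, "within_erh": {}}
            # across-condition comparison at each shared time (uppercase)
            frames = {}
            for s in kind_series:
                for t, v in zip(s.times, s.values):
                    frames.setdefault(t, {}).setdefault(s.condition, []).append(v)
            shared = [t for t, g in sorted(frames.items())
                      if len(g) >= 2 and all(len(v) >= 2 for v in g.values())]
            for t in shared[-1:]:  # final shared timepoint
                data_t = GroupData({c: np.asarray(v) for c, v
                                    in frames[t].items()}, design="between")
                try:
                    res = tukey_between(data_t)
                    entry["between_erh"][str(t)] = {
                        k: v.upper() for k, v in res.letters.items()}
                except (DomainError, ValueError) as err:
                    entry["between_erh"][str(t)] = f"failed: {err}"
            # across-time comparison within each condition (lowercase)
            for erh in sorted({s.condition for s in kind_series}):
                reps = sorted([s for s in kind_series if s.condition == erh],
                              key=lambda s: s.replicate)
                if len(reps) < 2:
                    continue
                groups = {f"t{t:g}": np.array([s.values[i] for s in reps])
                          for i, t in enumerate(reps[0].times)}
                # limit to a handful of spread-out times to keep k modest
                keys = list(groups)
                if len(keys) > 5:
                    pick = [keys[i] for i in
                            np.linspace(0, len(keys) - 1, 5).astype(int)]
                    groups = {k: groups[k] for k in pick}
                try:
                    res = tukey_repeated(GroupData(groups, design="repeated"))
                    entry["within_erh"][erh] = res.letters
                except (DomainError, ValueError) as err:
                    entry["within_erh"][erh] = f"failed: {err}"
            stats_out[kind.value] = entry
        report.statistics = stats_out

    return report


def _to_jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def report_to_dict(report: ShelfLifeReport) -> dict:
    d = dataclasses.asdict(report)
    d["partial"] = report.partial
    return _to_jsonable(d)


def export_report(report: ShelfLifeReport, fmt: str, out_dir) -> list[Path]:
    """Write a report as ``json``, ``csv-bundle`` or ``markdown``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    d = report_to_dict(report)
    written = []
    if fmt == "json":
        p = out / "report.json"
        p.write_text(json.dumps(d, indent=2))
        written.append(p)
    elif fmt == "csv-bundle":
        for resp, by_erh in d.get("kinetics", {}).items():
            rows = []
            for erh, rec in by_erh.items():
                row = {"erh": erh, **rec.get("parameters", {}),
                       "rmse": rec.get("rmse"), "n_obs": rec.get("n_obs")}
                rows.append(row)
            if rows:
                p = out / f"kinetics_{resp}.csv"
                pd.DataFrame(rows).to_csv(p, index=False)
                written.append(p)
        if d.get("state"):
            rows = [{"erh": e, **rec} for e, rec
                    in d["state"].get("per_erh", {}).items()]
            p = out / "state.csv"
            pd.DataFrame(rows).to_csv(p, index=False)
            written.append(p)
        if d.get("thresholds"):
            rows = [{"erh": e, **rec} for e, rec in d["thresholds"].items()]
            p = out / "thresholds.csv"
            pd.DataFrame(rows).to_csv(p, index=False)
            written.append(p)
        status = out / "status.csv"
        pd.DataFrame([{"stage": k, "status": v}
                      for k, v in d["stages"].items()]).to_csv(status, index=False)
        written.append(status)
    elif fmt == "markdown":
        lines = ["# Shelf-life study report", ""]
        if d["partial"]:
            lines.append("**PARTIAL REPORT** — some stages failed:")
            lines += [f"- {k}: {v}" for k, v in d["stages"].items()
                      if v != "ok"]
            lines.append("")
        iso = d.get("isotherm", {})
        if iso:
            lines.append(
                f"Monolayer: m0 = {iso['monolayer_moisture_db']:.4f} g/g db "
                f"({iso['monolayer_moisture_wet_pct']:.2f} % wet basis) at "
                f"a_w = {iso['monolayer_aw']:.3f}.")
        st = d.get("state", {})
        if st:
            lines.append(
                f"Critical a_w at {st['T_storage_c']:g} °C: "
                f"{st['critical_aw']:.3f} "
                f"(critical moisture {st['critical_moisture_db']:.4f} g/g db).")
            for erh, rec in st.get("per_erh", {}).items():
                lines.append(f"- {erh}% ERH: T_g = {rec['tg_c']:.1f} °C, "
                             f"state = {rec['state']} (ΔT = {rec['deltaT_c']:.1f} °C)")
        th = d.get("thresholds", {})
        if th:
            lines.append("")
            lines.append("Failure clocks (days; blank = never reached):")
            for erh, rec in th.items():
                parts = [f"{k.replace('_', ' ')}: "
                         f"{('%.1f' % v) if v is not None else '—'}"
                         for k, v in rec.items()]
                lines.append(f"- {erh}% ERH: " + "; ".join(parts))
        p = out / "report.md"
        p.write_text("\n".join(lines) + "\n")
        written.append(p)
    else:
        raise DomainError(f"unknown export format '{fmt}'")
    return written
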