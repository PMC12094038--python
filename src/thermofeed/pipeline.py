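"""End-to-end pipeline: validate → QC → phenotypes → meals → RFI → THI → associations.

Reads the CSV input schema (temperatures, visits, dmi_daily, milk_weekly,
bw, weather, cows), runs every analysis stage in dependency order, writes
all intermediate tables to the output directory, and emits a
``manifest.json`` (versions, seed, row counts, QC exclusions, criterion
used, stage status) that makes reruns byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import (
    compare_rfi_models,
    daily_mixed_model,
    partial_correlation,
    regress_trait,
)
from .energy import build_efficiency_records, compute_rfi
from .errors import DataError, ThermofeedError
from .meals import (
    cow_post_meal_trait,
    extract_intervals,
    fit_interval_mixture,
    largest_meal_per_day,
    meal_criterion,
    merge_visits_to_meals,
)
from .phenotypes import TemperatureTrace, phenotype_tables, qc_trace
from .thi import daily_thi, window_thi

log = logging.getLogger("thermofeed")

__all__ = [
    "PipelineConfig",
    "ValidationReport",
    "validate_inputs",
    "run_pipeline",
    "trial_association_frame",
    "daily_association_frame",
]

#: required columns per input file; visits.csv is optional
SCHEMA: dict[str, dict] = {
    "temperatures.csv": {"cow_id": str, "timestamp": "datetime", "temp_c": float},
    "visits.csv": {"cow_id": str, "start": "datetime", "end": "datetime", "intake_kg": float},
    "dmi_daily.csv": {"cow_id": str, "date": "date", "dmi_kg": float},
    "milk_weekly.csv": {
        "cow_id": str, "week": int, "fat_pct": float, "protein_pct": float,
        "lactose_pct": float, "milk_kg": float,
    },
    "bw.csv": {"cow_id": str, "day": int, "bw_kg": float},
    "weather.csv": {"station": str, "date": "date", "t_mean_c": float, "rh_pct": float},
    "cows.csv": {
        "cow_id": str, "station": str, "cohort": str, "lact_number": int, "midpoint_dim": float,
    },
}
OPTIONAL_FILES = {"visits.csv"}


@dataclass
class PipelineConfig:
    input_dir: str
    output_dir: str
    min_days: int = 7
    sd_limit: float = 3.0
    n_components: int = 2
    criterion_override: float | None = None  # minutes; skips mixture fitting
    dim_range: tuple = (60, 195)
    thi_pad: int = 3
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if Path(self.input_dir).resolve() == Path(self.output_dir).resolve():
            raise DataError("input and output directories must be distinct")
        if self.min_days < 1 or self.sd_limit <= 0 or self.thi_pad < 0:
            raise DataError("QC thresholds and THI pad must be positive")


@dataclass
class ValidationReport:
    passed: bool
    messages: list[str] = field(default_factory=list)


def _check_numeric(df: pd.DataFrame, col: str, fname: str, messages: list[str]) -> None:
    coerced = pd.to_numeric(df[col], errors="coerce")
    bad = df.index[coerced.isna() & df[col].notna()]
    if len(bad):
        rows = ", ".join(str(i + 2) for i in bad[:5])  # +2: header + 1-based
        messages.append(f"{fname}: column {col!r} non-numeric at file line(s) {rows}")


def validate_inputs(directory) -> ValidationReport:
    """Schema and cross-file key checks; returns a report, never raises."""
    d = Path(directory)
    messages: list[str] = []
    frames: dict[str, pd.DataFrame] = {}
    for fname, cols in SCHEMA.items():
        path = d / fname
        if not path.exists():
            if fname not in OPTIONAL_FILES:
                messages.append(f"missing required input file: {fname}")
            continue
        try:
            df = pd.read_csv(path, dtype=str)
        except Exception as exc:  # noqa: BLE001 - report, don't raise
            messages.append(f"{fname}: unreadable ({exc})")
            continue
        missing = set(cols) - set(df.columns)
        if missing:
            messages.append(f"{fname}: missing column(s) {sorted(missing)}")
            continue
        for col, typ in cols.items():
            if typ in (float, int):
                _check_numeric(df, col, fname, messages)
            elif typ in ("datetime", "date"):
                parsed = pd.to_datetime(df[col], errors="coerce", format="ISO8601")
                bad = df.index[parsed.isna() & df[col].notna()]
                if len(bad):
                    rows = ", ".join(str(i + 2) for i in bad[:5])
                    messages.append(f"{fname}: column {col!r} unparseable timestamps at line(s) {rows}")
        frames[fname] = df
    if "cows.csv" in frames:
        known = set(frames["cows.csv"]["cow_id"])
        for fname in ("temperatures.csv", "visits.csv", "dmi_daily.csv", "milk_weekly.csv", "bw.csv"):
            if fname in frames:
                stray = sorted(set(frames[fname]["cow_id"]) - known)
                if stray:
                    messages.append(
                        f"{fname}: cow_id(s) absent from cows.csv: {stray[:5]}"
                        + ("..." if len(stray) > 5 else "")
                    )
    return ValidationReport(passed=not messages, messages=messages)


def _load_traces(temperatures: pd.DataFrame) -> dict[str, TemperatureTrace]:
    traces = {}
    for cid, grp in temperatures.groupby("cow_id", sort=True):
        grp = grp.sort_values("timestamp")
        traces[str(cid)] = TemperatureTrace(
            cow_id=str(cid),
            times=pd.DatetimeIndex(grp["timestamp"]),
            values=grp["temp_c"].to_numpy(dtype=float),
        )
    return traces


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the manifest (also written to the output dir)."""
    config.validate()
    logging.basicConfig(level=config.log_level)
    indir, outdir = Path(config.input_dir), Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "thermofeed_version": __version__,
        "pandas_version": pd.__version__,
        "numpy_version": np.__version__,
        "seed": config.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in dataclasses.asdict(config).items()},
        "stages": {},
        "row_counts": {},
    }

    report = validate_inputs(indir)
    manifest["stages"]["validate"] = "ok" if report.passed else "failed"
    if not report.passed:
        manifest["validation_messages"] = report.messages
        _write_manifest(manifest, outdir)
        raise DataError("input validation failed:\n" + "\n".join(report.messages))

    temperatures = pd.read_csv(indir / "temperatures.csv", parse_dates=["timestamp"])
    cows = pd.read_csv(indir / "cows.csv")
    dmi_daily = pd.read_csv(indir / "dmi_daily.csv", parse_dates=["date"])
    milk_weekly = pd.read_csv(indir / "milk_weekly.csv")
    bw = pd.read_csv(indir / "bw.csv")
    weather = pd.read_csv(indir / "weather.csv", parse_dates=["date"])
    visits_path = indir / "visits.csv"
    visits = pd.read_csv(visits_path, parse_dates=["start", "end"]) if visits_path.exists() else None
    manifest["row_counts"]["inputs"] = {
        "temperatures": len(temperatures), "cows": len(cows), "dmi_daily": len(dmi_daily),
        "milk_weekly": len(milk_weekly), "bw": len(bw), "weather": len(weather),
        "visits": (len(visits) if visits is not None else None),
    }

    # --- QC ---------------------------------------------------------------
    raw_traces = _load_traces(temperatures)
    cleaned, qc_reports = {}, []
    for cid, tr in raw_traces.items():
        ctr, rep = qc_trace(tr, min_days=config.min_days, sd_limit=config.sd_limit)
        qc_reports.append(rep.to_dict())
        if not rep.excluded:
            cleaned[cid] = ctr
    with open(outdir / "qc_report.json", "w") as fh:
        json.dump(qc_reports, fh, indent=1)
    n_excluded = sum(r["excluded"] for r in qc_reports)
    manifest["qc"] = {
        "cows_in": len(raw_traces), "cows_excluded": n_excluded,
        "records_removed": int(sum(r["n_removed"] for r in qc_reports)),
    }
    manifest["stages"]["qc"] = "ok"

    # --- temperature phenotypes -------------------------------------------
    trial_phen, daily_phen = phenotype_tables(cleaned)
    trial_phen.to_csv(outdir / "phenotypes_trial.csv", index=False)
    daily_phen.to_csv(outdir / "phenotypes_daily.csv", index=False)
    manifest["row_counts"]["phenotypes_trial"] = len(trial_phen)
    manifest["row_counts"]["phenotypes_daily"] = len(daily_phen)
    manifest["stages"]["phenotypes"] = "ok"

    # --- THI ---------------------------------------------------------------
    wx = daily_thi(weather.assign(date=weather["date"].dt.date))
    wx.to_csv(outdir / "thi_daily.csv", index=False)
    station_of = cows.set_index("cow_id")["station"]
    thi_rows = []
    for cid, tr in cleaned.items():
        start, end = tr.times[0].date(), tr.times[-1].date()
        try:
            val = window_thi(wx, station_of.get(cid), start, end, pad=config.thi_pad)
        except DataError as exc:
            log.warning("THI covariate unavailable for %s: %s", cid, exc)
            val = float("nan")
        thi_rows.append({"cow_id": cid, "thi": val})
    thi_cow = pd.DataFrame(thi_rows)
    thi_cow.to_csv(outdir / "thi_cow.csv", index=False)
    manifest["stages"]["thi"] = "ok"

    # --- meals & post-meal trait -------------------------------------------
    postmeal = pd.DataFrame(columns=["cow_id", "postmeal_delta", "n_meals"])
    if visits is None:
        manifest["stages"]["meals"] = "skipped: visits.csv absent"
        manifest["criterion"] = None
    else:
        try:
            if config.criterion_override is not None:
                criterion = float(config.criterion_override)
                manifest["criterion"] = {"minutes": criterion, "source": "fixed"}
                mixture_info = None
            else:
                intervals = extract_intervals(visits)
                fit = fit_interval_mixture(intervals, n_components=config.n_components, seed=config.seed)
                criterion = meal_criterion(fit)
                manifest["criterion"] = {"minutes": criterion, "source": "mixture_fit"}
                mixture_info = fit.to_dict()
            with open(outdir / "mixture.json", "w") as fh:
                json.dump({"criterion_min": criterion, "fit": mixture_info}, fh, indent=1)
            meals = largest_meal_per_day(merge_visits_to_meals(visits, criterion))
            meals.to_csv(outdir / "meals.csv", index=False)
            manifest["row_counts"]["meals"] = len(meals)
            pm_rows = []
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                for cid, tr in cleaned.items():
                    trait, deltas = cow_post_meal_trait(tr, meals)
                    if np.isfinite(trait):
                        pm_rows.append({"cow_id": cid, "postmeal_delta": trait, "n_meals": len(deltas)})
            postmeal = pd.DataFrame(pm_rows, columns=["cow_id", "postmeal_delta", "n_meals"])
            manifest["stages"]["meals"] = "ok"
        except ThermofeedError as exc:
            manifest["stages"]["meals"] = f"failed: {exc}"
            log.error("meal stage failed: %s", exc)
    postmeal.to_csv(outdir / "postmeal_deltas.csv", index=False)

    # --- energy & RFI ------------------------------------------------------
    trial_days = int(bw["day"].max()) + 1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        records = build_efficiency_records(dmi_daily, milk_weekly, bw, cows, trial_days)
        rfi_fit = compute_rfi(records)
    eff = records.copy()
    eff["rfi"] = rfi_fit.residuals.to_numpy()
    eff.to_csv(outdir / "efficiency_traits.csv", index=False)
    with open(outdir / "rfi_model.json", "w") as fh:
        json.dump(rfi_fit.to_dict(), fh, indent=1)
    manifest["row_counts"]["efficiency_traits"] = len(eff)
    manifest["stages"]["rfi"] = "ok"

    # --- associations -------------------------------------------------------
    meta = cows.set_index("cow_id")
    base = trial_phen.merge(thi_cow, on="cow_id", how="left")
    base = base.merge(eff[["cow_id", "dmi", "milke", "mbw", "rfi", "cohort"]], on="cow_id", how="inner")
    base["station"] = base["cow_id"].map(meta["station"])
    if len(postmeal):
        base = base.merge(postmeal[["cow_id", "postmeal_delta"]], on="cow_id", how="left")
    else:
        base["postmeal_delta"] = np.nan

    assoc_rows, pc_rows = [], []
    temp_traits = ["mean_temp", "logvar", "postmeal_delta"]
    responses = ["dmi", "milke", "mbw", "rfi"]
    for tt in temp_traits:
        for resp in responses:
            sub = base.dropna(subset=[tt, resp])
            if len(sub) < 10 or sub[tt].std() == 0:
                continue
            try:
                res = regress_trait(
                    sub.rename(columns={tt: "temp_trait", resp: "response"}), resp, tt
                )
                assoc_rows.append(
                    {"response": resp, "temp_trait": tt, "slope": res.slope, "se": res.se,
                     "p_value": res.p_value, "n": res.n, "model": res.model}
                )
            except ThermofeedError as exc:
                log.warning("association %s ~ %s failed: %s", resp, tt, exc)
            try:
                pc = partial_correlation(sub[tt], sub[resp], sub["cohort"], tt, resp)
                pc_rows.append({"x": tt, "y": resp, "r": pc.r, "p_value": pc.p_value, "n": pc.n})
            except ThermofeedError as exc:
                log.warning("partial correlation %s / %s failed: %s", resp, tt, exc)
    pd.DataFrame(assoc_rows).to_csv(outdir / "associations.csv", index=False)
    pd.DataFrame(pc_rows).to_csv(outdir / "partial_correlations.csv", index=False)

    # daily mixed models: daily DMI on daily temperature traits
    daily = daily_phen.copy()
    daily["date"] = pd.to_datetime(daily["date"]).dt.date
    dmi_d = dmi_daily.assign(date=dmi_daily["date"].dt.date)
    daily = daily.merge(dmi_d, on=["cow_id", "date"], how="inner")
    daily["cohort"] = daily["cow_id"].map(meta["cohort"])
    daily["station"] = daily["cow_id"].map(meta["station"])
    wx_idx = wx.assign(date=pd.to_datetime(wx["date"]).dt.date).set_index(["station", "date"])["thi"]
    daily["thi"] = [
        wx_idx.get((st, d), np.nan) for st, d in zip(daily["station"], daily["date"])
    ]
    mixed_rows = []
    for tt in ("mean_temp", "logvar"):
        sub = daily.dropna(subset=[tt, "dmi_kg", "thi"])
        if len(sub) >= 20 and sub[tt].std() > 0:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = daily_mixed_model(
                        sub.rename(columns={tt: "temp_trait", "dmi_kg": "response"}), "daily_dmi", f"daily_{tt}"
                    )
                mixed_rows.append(
                    {"response": "daily_dmi", "temp_trait": f"daily_{tt}", "slope": res.slope,
                     "se": res.se, "p_value": res.p_value, "n": res.n, "model": res.model}
                )
            except ThermofeedError as exc:
                log.warning("daily mixed model for %s failed: %s", tt, exc)
    pd.DataFrame(mixed_rows).to_csv(outdir / "associations_daily.csv", index=False)

    # adjusted-R² comparison of RFI model with/without temperature traits
    comparisons = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for tt in temp_traits:
            series = base.set_index("cow_id")[tt].dropna()
            if len(series) < 10 or series.std() == 0:
                continue
            cmp_res = compare_rfi_models(records, series, tt)
            comparisons[tt] = {
                "base_adj_r2": cmp_res.base_adj_r2, "augmented_adj_r2": cmp_res.augmented_adj_r2,
                "n": cmp_res.n, "notes": cmp_res.notes,
            }
    with open(outdir / "model_comparisons.json", "w") as fh:
        json.dump(comparisons, fh, indent=1)
    manifest["stages"]["associations"] = "ok"

    _write_manifest(manifest, outdir)
    return manifest


def trial_association_frame(ds, min_days: int = 7, sd_limit: float = 3.0, thi_pad: int = 3) -> pd.DataFrame:
    """Cow-level analysis frame from an in-memory synthetic dataset.

    Runs QC, trial phenotypes, efficiency records/RFI and the per-cow THI
    covariate, and returns one row per retained cow with columns mean_temp,
    logvar, dmi, milke, mbw, rfi, cohort, station, thi.
    """
    cleaned = {}
    for cid, tr in ds.traces.items():
        ctr, rep = qc_trace(tr, min_days=min_days, sd_limit=sd_limit)
        if not rep.excluded:
            cleaned[cid] = ctr
    trial_phen, _ = phenotype_tables(cleaned)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        records = build_efficiency_records(
            ds.dmi_daily, ds.milk_weekly, ds.bw, ds.cows, ds.config.trial_days
        )
        fit = compute_rfi(records)
    eff = records.copy()
    eff["rfi"] = fit.residuals.to_numpy()
    wx = daily_thi(ds.weather)
    station_of = ds.cows.set_index("cow_id")["station"]
    thi_rows = []
    for cid, tr in cleaned.items():
        try:
            val = window_thi(wx, station_of.get(cid), tr.times[0].date(), tr.times[-1].date(), pad=thi_pad)
        except DataError:
            val = float("nan")
        thi_rows.append({"cow_id": cid, "thi": val})
    out = trial_phen.merge(pd.DataFrame(thi_rows), on="cow_id", how="left")
    out = out.merge(eff[["cow_id", "dmi", "milke", "mbw", "rfi", "cohort"]], on="cow_id", how="inner")
    out["station"] = out["cow_id"].map(station_of)
    return out


def daily_association_frame(ds, min_days: int = 7, sd_limit: float = 3.0) -> pd.DataFrame:
    """Cow-day analysis frame: daily phenotypes joined to daily DMI and daily THI."""
    cleaned = {}
    for cid, tr in ds.traces.items():
        ctr, rep = qc_trace(tr, min_days=min_days, sd_limit=sd_limit)
        if not rep.excluded:
            cleaned[cid] = ctr
    _, daily_phen = phenotype_tables(cleaned)
    daily_phen["date"] = pd.to_datetime(daily_phen["date"]).dt.date
    dmi = ds.dmi_daily.copy()
    dmi["date"] = pd.to_datetime(dmi["date"]).dt.date
    out = daily_phen.merge(dmi, on=["cow_id", "date"], how="inner")
    meta = ds.cows.set_index("cow_id")
    out["cohort"] = out["cow_id"].map(meta["cohort"])
    out["station"] = out["cow_id"].map(meta["station"])
    wx = daily_thi(ds.weather)
    wx_idx = wx.assign(date=pd.to_datetime(wx["date"]).dt.date).set_index(["station", "date"])["thi"]
    out["thi"] = [wx_idx.get((s, d), np.nan) for s, d in zip(out["station"], out["date"])]
    return out


def _write_manifest(manifest: dict, outdir: Path) -> None:
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
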