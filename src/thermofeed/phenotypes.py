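"""Quality control and phenotyping of high-frequency body-temperature traces.

Each cow carries a vaginal temperature logger sampling every few minutes for
about two weeks. Two phenotypes summarise a trace:

* mean body temperature (°C), at trial or daily resolution;
* consistency, ``ln(100 · var)`` where ``var`` is the variance of the
  deviations of individual records from the cow's trial mean — smaller
  values mean a steadier temperature.

QC excludes cows with too few recording days and removes records further
than a fixed number of standard deviations from the cow's raw mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = [
    "TemperatureTrace",
    "QCReport",
    "ZeroVarianceWarning",
    "qc_trace",
    "mean_temperature",
    "consistency",
    "phenotype_tables",
]


class ZeroVarianceWarning(UserWarning):
    """Consistency is undefined for a trace with zero deviation variance."""


@dataclass
class TemperatureTrace:
    """One cow's timestamped temperature series.

    ``times`` must be strictly increasing and ``values`` finite, in °C.
    ``qc_state`` is ``"raw"`` until :func:`qc_trace` has run.
    """

    cow_id: str
    times: pd.DatetimeIndex
    values: np.ndarray
    qc_state: str = "raw"

    def __post_init__(self) -> None:
        self.times = pd.DatetimeIndex(self.times)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.times) != len(self.values):
            raise DataError("times and values differ in length")
        if len(self.times) == 0:
            raise DataError(f"empty temperature trace for cow {self.cow_id!r}")
        if not self.times.is_monotonic_increasing or self.times.has_duplicates:
            raise DataError(f"timestamps not strictly increasing for cow {self.cow_id!r}")
        if not np.all(np.isfinite(self.values)):
            raise DataError(f"non-finite temperature values for cow {self.cow_id!r}")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def n_days(self) -> int:
        """Number of distinct calendar days with at least one record."""
        return len(np.unique(self.times.date))

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.times, name=self.cow_id)


@dataclass
class QCReport:
    cow_id: str
    excluded: bool
    reason: str | None
    n_raw: int
    n_removed: int
    n_days: int
    raw_mean: float
    raw_sd: float

    def to_dict(self) -> dict:
        return {
            "cow_id": self.cow_id,
            "excluded": self.excluded,
            "reason": self.reason,
            "n_raw": self.n_raw,
            "n_removed": self.n_removed,
            "n_days": self.n_days,
            "raw_mean": self.raw_mean,
            "raw_sd": self.raw_sd,
        }


def qc_trace(
    trace: TemperatureTrace, min_days: int = 7, sd_limit: float = 3.0
) -> tuple[TemperatureTrace, QCReport]:
    """Apply the two QC rules and return (cleaned trace, report).

    A cow with fewer than ``min_days`` distinct recording days is flagged
    excluded (her trace is returned untouched). Otherwise records whose
    absolute deviation from the raw mean exceeds ``sd_limit`` raw standard
    deviations are removed in a single pass.
    """
    n_raw = len(trace)
    raw_mean = float(np.mean(trace.values))
    raw_sd = float(np.std(trace.values, ddof=1)) if n_raw > 1 else 0.0
    n_days = trace.n_days
    if n_days < min_days:
        report = QCReport(trace.cow_id, True, "insufficient_days", n_raw, 0, n_days, raw_mean, raw_sd)
        return trace, report
    keep = np.abs(trace.values - raw_mean) <= sd_limit * raw_sd
    cleaned = replace(trace, times=trace.times[keep], values=trace.values[keep], qc_state="cleaned")
    report = QCReport(
        trace.cow_id, False, None, n_raw, int(n_raw - keep.sum()), n_days, raw_mean, raw_sd
    )
    return cleaned, report


def mean_temperature(trace: TemperatureTrace, resolution: str = "trial"):
    """Arithmetic mean temperature at ``"trial"`` (scalar) or ``"daily"`` (Series) resolution."""
    if resolution == "trial":
        return float(np.mean(trace.values))
    if resolution == "daily":
        s = trace.to_series()
        daily = s.groupby(s.index.date).mean()
        daily.index.name = "date"
        return daily
    raise ValueError(f"unknown resolution {resolution!r}")


def consistency(trace: TemperatureTrace, resolution: str = "trial", daily_baseline: str = "trial"):
    """Consistency phenotype ``ln(100 · var)`` of deviations from the cow's trial mean.

    At daily resolution the variance is the mean squared deviation of the
    day's records from the *trial* mean (denominator n−1), so a day that is
    level-shifted from the cow's norm scores as inconsistent. Set
    ``daily_baseline="day"`` to deviate from the day's own mean instead.
    Zero variance yields NaN with a :class:`ZeroVarianceWarning`.
    """
    trial_mean = float(np.mean(trace.values))
    if resolution == "trial":
        if len(trace) < 2:
            raise DataError("consistency needs at least 2 records")
        # identical records accumulate rounding noise in np.var; force exact zero
        var = 0.0 if np.ptp(trace.values) == 0 else float(np.var(trace.values, ddof=1))
        return _logvar(var, trace.cow_id)
    if resolution == "daily":
        s = trace.to_series()
        out = {}
        for day, grp in s.groupby(s.index.date):
            if len(grp) < 2:
                continue
            if daily_baseline == "trial":
                dev = grp.to_numpy() - trial_mean
                var = 0.0 if np.ptp(dev) == 0 and dev[0] == 0 else float(np.sum(dev**2) / (len(dev) - 1))
            elif daily_baseline == "day":
                var = 0.0 if np.ptp(grp.to_numpy()) == 0 else float(np.var(grp.to_numpy(), ddof=1))
            else:
                raise ValueError(f"unknown daily_baseline {daily_baseline!r}")
            out[day] = _logvar(var, trace.cow_id, day)
        ser = pd.Series(out, dtype=float)
        ser.index.name = "date"
        return ser
    raise ValueError(f"unknown resolution {resolution!r}")


def _logvar(var: float, cow_id: str, day=None) -> float:
    if var <= 0.0:
        where = f" on {day}" if day is not None else ""
        warnings.warn(
            f"zero_variance: consistency undefined for cow {cow_id!r}{where}",
            ZeroVarianceWarning,
            stacklevel=3,
        )
        return float("nan")
    return float(np.log(100.0 * var))


def phenotype_tables(traces: dict[str, TemperatureTrace]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Trial-level and daily phenotype tables for a set of cleaned traces.

    Returns ``(trial, daily)``: trial has one row per cow (mean_temp,
    logvar, n_records, n_days); daily one row per retained cow-day.
    """
    trial_rows, daily_rows = [], []
    for cow_id, tr in traces.items():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ZeroVarianceWarning)
            lv = consistency(tr, "trial") if len(tr) > 1 else float("nan")
            dlv = consistency(tr, "daily")
        trial_rows.append(
            {
                "cow_id": cow_id,
                "mean_temp": mean_temperature(tr, "trial"),
                "logvar": lv,
                "n_records": len(tr),
                "n_days": tr.n_days,
            }
        )
        dm = mean_temperature(tr, "daily")
        for day in dm.index:
            daily_rows.append(
                {
                    "cow_id": cow_id,
                    "date": day,
                    "mean_temp": float(dm.loc[day]),
                    "logvar": float(dlv.get(day, np.nan)),
                }
            )
    trial = pd.DataFrame(trial_rows)
    daily = pd.DataFrame(daily_rows)
    return trial, daily
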