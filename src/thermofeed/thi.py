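"""Temperature-humidity index (THI) and per-cow environmental covariates.

The THI combines mean air temperature (°C, ~2 m above ground) and mean
relative humidity (%) into a single heat-load score:

    THI = (1.8 t + 32) − (0.55 − 0.0055 rh) (1.8 t − 26)

The per-cow covariate used in the association models is the unweighted mean
of daily THI at the cow's station over her temperature-recording window
padded by a few days on each side.
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd

from .errors import DataError, ParameterError

__all__ = ["thi", "daily_thi", "window_thi"]


def thi(t_c, rh_pct):
    """Temperature-humidity index from air temperature (°C) and relative humidity (%).

    Accepts scalars or arrays; relative humidity must lie in [0, 100].
    """
    t = np.asarray(t_c, dtype=float)
    rh = np.asarray(rh_pct, dtype=float)
    if np.any(rh < 0) or np.any(rh > 100):
        raise ParameterError("relative humidity must be within [0, 100] %")
    out = (1.8 * t + 32.0) - (0.55 - 0.0055 * rh) * (1.8 * t - 26.0)
    if out.ndim == 0:
        return float(out)
    return out


def daily_thi(weather: pd.DataFrame) -> pd.DataFrame:
    """Append a ``thi`` column to a station weather table.

    ``weather`` needs columns station, date, t_mean_c, rh_pct; one row per
    station-day.
    """
    required = {"station", "date", "t_mean_c", "rh_pct"}
    missing = required - set(weather.columns)
    if missing:
        raise DataError(f"weather table missing columns: {sorted(missing)}")
    out = weather.copy()
    out["thi"] = thi(out["t_mean_c"].to_numpy(), out["rh_pct"].to_numpy())
    return out


def window_thi(
    weather: pd.DataFrame,
    station,
    window_start: dt.date,
    window_end: dt.date,
    pad: int = 3,
) -> float:
    """Mean daily THI at ``station`` over [start − pad, end + pad] days.

    Raises :class:`DataError` listing any calendar day in the padded window
    with no weather row.
    """
    if pad < 0:
        raise ParameterError("pad must be non-negative")
    w = daily_thi(weather) if "thi" not in weather.columns else weather
    w = w[w["station"] == station]
    dates = pd.to_datetime(w["date"]).dt.date
    lo = window_start - dt.timedelta(days=pad)
    hi = window_end + dt.timedelta(days=pad)
    wanted = pd.date_range(lo, hi, freq="D").date
    have = set(dates)
    gaps = [d.isoformat() for d in wanted if d not in have]
    if gaps:
        raise DataError(f"weather missing for station {station!r} on: {', '.join(gaps)}")
    mask = (dates >= lo) & (dates <= hi)
    return float(w.loc[mask.to_numpy(), "thi"].mean())
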