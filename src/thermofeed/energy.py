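"""Milk energy, metabolic body weight, body-weight change and residual feed intake.

Residual feed intake (RFI) is the residual of a linear model of trial-average
dry matter intake on its energy sinks and management structure:

    DMI = DIM + Lact + Cohort + b1·MilkE + b2·mBW + b3·ΔBW + e

with DIM the midpoint days-in-milk class (nine 15-d bins over 60–195 DIM),
Lact the lactation-number class (1, 2, 3, 4+), Cohort the trial-treatment
group, MilkE the secreted milk energy (Mcal/d), mBW the metabolic body
weight (kg^0.75) and ΔBW the body-weight change over the trial (kg). The
residual e is each cow's RFI; a lower value means a more efficient cow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import DataError, ModelError, ParameterError

__all__ = [
    "milk_energy",
    "impute_bw",
    "metabolic_bw",
    "delta_bw",
    "dim_class",
    "lact_class",
    "build_efficiency_records",
    "compute_rfi",
    "RFIModelFit",
]

#: Mcal/kg milk per percentage point of each component
MILKE_COEF_FAT = 0.0929
MILKE_COEF_PROTEIN = 0.0585
MILKE_COEF_LACTOSE = 0.0395

DIM_MIN, DIM_MAX, DIM_BIN = 60, 195, 15


def milk_energy(fat_pct, protein_pct, lactose_pct, milk_yield):
    """Secreted milk energy (Mcal/d).

    MilkE = (0.0929·fat% + 0.0585·true protein% + 0.0395·lactose%) · milk yield (kg/d).
    Inputs may be scalars or arrays; all must be non-negative.
    """
    fat = np.asarray(fat_pct, dtype=float)
    prot = np.asarray(protein_pct, dtype=float)
    lact = np.asarray(lactose_pct, dtype=float)
    yld = np.asarray(milk_yield, dtype=float)
    if any(np.any(a < 0) for a in (fat, prot, lact, yld)):
        raise ParameterError("milk components and yield must be non-negative")
    out = (MILKE_COEF_FAT * fat + MILKE_COEF_PROTEIN * prot + MILKE_COEF_LACTOSE * lact) * yld
    return float(out) if out.ndim == 0 else out


def impute_bw(days, bw_kg, trial_days: int) -> np.ndarray:
    """Daily BW series over days 0..trial_days−1 from sparse measurements.

    Ordinary least squares of BW on day of trial fills unmeasured days;
    measured days keep their measured value (averaged if replicated).
    """
    days = np.asarray(days, dtype=float)
    bw = np.asarray(bw_kg, dtype=float)
    if days.shape != bw.shape or days.size == 0:
        raise DataError("days and bw_kg must be equal-length, non-empty")
    uniq = np.unique(days)
    if uniq.size < 2:
        raise DataError("BW imputation needs measurements on at least 2 distinct days")
    slope, intercept = np.polyfit(days, bw, 1)
    grid = np.arange(trial_days, dtype=float)
    series = intercept + slope * grid
    for d in uniq:
        if 0 <= d < trial_days and float(d).is_integer():
            series[int(d)] = bw[days == d].mean()
    return series


def metabolic_bw(bw_series) -> float:
    """Metabolic BW: the cow's average BW raised to the 0.75 power (kg^0.75)."""
    bw = np.asarray(bw_series, dtype=float)
    if np.any(bw <= 0):
        raise DataError("body weights must be positive")
    return float(np.mean(bw) ** 0.75)


def delta_bw(bw_series) -> float:
    """BW change over the trial: last-day minus first-day fitted/imputed BW (kg)."""
    bw = np.asarray(bw_series, dtype=float)
    if bw.size < 1 or not np.all(np.isfinite(bw)):
        raise DataError("BW series must be non-empty and finite at both endpoints")
    return float(bw[-1] - bw[0])


def dim_class(midpoint_dim) -> int:
    """15-d midpoint days-in-milk class over 60–195 DIM.

    Class k covers [60+15(k−1), 60+15k) for k=1..8; class 9 covers [180, 195].
    Values outside [60, 195] are rejected.
    """
    d = float(midpoint_dim)
    if not DIM_MIN <= d <= DIM_MAX:
        raise ParameterError(f"midpoint DIM {d} outside the supported range [{DIM_MIN}, {DIM_MAX}]")
    return min(int((d - DIM_MIN) // DIM_BIN) + 1, 9)


def lact_class(lactation_number) -> str:
    """Lactation class with the 4-plus collapse: '1', '2', '3' or '4+'."""
    n = int(lactation_number)
    if n < 1:
        raise ParameterError("lactation number must be >= 1")
    return str(n) if n <= 3 else "4+"


def build_efficiency_records(
    dmi_daily: pd.DataFrame,
    milk_weekly: pd.DataFrame,
    bw: pd.DataFrame,
    cows: pd.DataFrame,
    trial_days: int,
) -> pd.DataFrame:
    """Assemble one efficiency record per cow from the raw input tables.

    dmi: trial mean of daily DMI; milke: unweighted mean of weekly MilkE;
    mbw/delta_bw from the OLS-imputed daily BW series; dim_class/lact_class
    from metadata. Cows lacking any ingredient are dropped with a warning.
    """
    dmi_mean = dmi_daily.groupby("cow_id")["dmi_kg"].mean()
    mw = milk_weekly.copy()
    mw["milke"] = milk_energy(
        mw["fat_pct"].to_numpy(),
        mw["protein_pct"].to_numpy(),
        mw["lactose_pct"].to_numpy(),
        mw["milk_kg"].to_numpy(),
    )
    milke_mean = mw.groupby("cow_id")["milke"].mean()

    rows, dropped = [], []
    for _, cow in cows.iterrows():
        cid = cow["cow_id"]
        bwc = bw[bw["cow_id"] == cid]
        if cid not in dmi_mean.index or cid not in milke_mean.index or len(bwc) < 2:
            dropped.append(cid)
            continue
        try:
            series = impute_bw(bwc["day"].to_numpy(), bwc["bw_kg"].to_numpy(), trial_days)
            rows.append(
                {
                    "cow_id": cid,
                    "dmi": float(dmi_mean.loc[cid]),
                    "milke": float(milke_mean.loc[cid]),
                    "mbw": metabolic_bw(series),
                    "delta_bw": delta_bw(series),
                    "dim_class": dim_class(cow["midpoint_dim"]),
                    "lact_class": lact_class(cow["lact_number"]),
                    "cohort": cow["cohort"],
                }
            )
        except (DataError, ParameterError) as exc:
            dropped.append(cid)
            warnings.warn(f"cow {cid!r} dropped from efficiency records: {exc}", stacklevel=2)
    if dropped:
        warnings.warn(f"{len(dropped)} cow(s) lacked complete efficiency inputs", stacklevel=2)
    return pd.DataFrame(rows)


@dataclass
class RFIModelFit:
    """Fitted RFI model: coefficients, per-cow residuals (RFI) and fit quality."""

    params: pd.Series
    bse: pd.Series
    residuals: pd.Series  # indexed by cow_id; this is RFI, kg/d
    adj_r2: float
    r2: float
    n_cows: int
    rank: int
    dropped_columns: list[str]

    def coef(self, name: str) -> float:
        return float(self.params[name])

    def se(self, name: str) -> float:
        return float(self.bse[name])

    def to_dict(self) -> dict:
        return {
            "coefficients": {k: float(v) for k, v in self.params.items()},
            "standard_errors": {k: float(v) for k, v in self.bse.items()},
            "adj_r2": float(self.adj_r2),
            "r2": float(self.r2),
            "n_cows": int(self.n_cows),
            "rank": int(self.rank),
            "dropped_columns": list(self.dropped_columns),
        }


def design_matrix(
    records: pd.DataFrame, extra: list[str] | None = None
) -> tuple[pd.DataFrame, list[str]]:
    """Full-rank RFI design: intercept, class dummies (reference coding), covariates.

    Aliased columns are dropped in column order (earlier columns win) and
    returned in the second element.
    """
    parts = [pd.Series(1.0, index=records.index, name="Intercept")]
    for col in ("dim_class", "lact_class", "cohort"):
        dum = pd.get_dummies(records[col].astype(str), prefix=col, drop_first=True, dtype=float)
        parts.append(dum)
    for col in ["milke", "mbw", "delta_bw"] + (extra or []):
        parts.append(records[col].astype(float).rename(col))
    X = pd.concat(parts, axis=1)
    return drop_aliased(X)


def drop_aliased(X: pd.DataFrame, tol: float = 1e-8) -> tuple[pd.DataFrame, list[str]]:
    """Greedy rank filter: keep each column only if it adds rank, in order."""
    Q: list[np.ndarray] = []
    keep, dropped = [], []
    for col in X.columns:
        c = X[col].to_numpy(dtype=float)
        r = c.copy()
        for q in Q:
            r = r - np.dot(q, c) * q
        norm_c = np.linalg.norm(c)
        if norm_c > 0 and np.linalg.norm(r) > tol * norm_c:
            keep.append(col)
            Q.append(r / np.linalg.norm(r))
        else:
            dropped.append(col)
    return X[keep], dropped


def compute_rfi(records: pd.DataFrame, extra: list[str] | None = None) -> RFIModelFit:
    """Fit the RFI model by OLS and return coefficients plus per-cow residuals.

    ``records`` needs columns cow_id, dmi, milke, mbw, delta_bw, dim_class,
    lact_class, cohort. ``extra`` names additional covariate columns (used
    for the with/without-temperature model comparison).
    """
    required = {"cow_id", "dmi", "milke", "mbw", "delta_bw", "dim_class", "lact_class", "cohort"}
    missing = required - set(records.columns)
    if missing:
        raise DataError(f"efficiency records missing columns: {sorted(missing)}")
    records = records.reset_index(drop=True)
    X, dropped = design_matrix(records, extra)
    if dropped:
        warnings.warn(f"aliased design columns dropped: {dropped}", stacklevel=2)
    if len(records) <= X.shape[1]:
        raise ModelError(
            f"{len(records)} cows cannot identify {X.shape[1]} parameters in the RFI model"
        )
    res = sm.OLS(records["dmi"].to_numpy(dtype=float), X).fit()
    residuals = pd.Series(np.asarray(res.resid), index=records["cow_id"], name="rfi")
    return RFIModelFit(
        params=res.params,
        bse=res.bse,
        residuals=residuals,
        adj_r2=float(res.rsquared_adj),
        r2=float(res.rsquared),
        n_cows=len(records),
        rank=X.shape[1],
        dropped_columns=dropped,
    )
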