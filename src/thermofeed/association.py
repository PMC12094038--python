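"""Associations between body-temperature phenotypes and feed-efficiency traits.

Four analyses mirror the study design:

* trial-level OLS of an efficiency trait on a temperature trait, adjusting
  for cohort, the cow's mean THI over her recording window, and the
  THI × station interaction (station main effect included whenever the
  interaction is);
* daily linear mixed models of daily DMI on a daily temperature trait with
  cohort, daily THI and THI × station as fixed effects and cow as a random
  intercept (REML);
* partial correlations between trait pairs controlling for cohort
  (residual-on-residual Pearson correlation);
* adjusted-R² comparison of the RFI model with and without a temperature
  trait as an extra covariate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .energy import compute_rfi, drop_aliased
from .errors import DataError, ModelError

__all__ = [
    "AssociationResult",
    "PartialCorrelationResult",
    "ModelComparison",
    "regress_trait",
    "daily_mixed_model",
    "partial_correlation",
    "compare_rfi_models",
]


@dataclass
class AssociationResult:
    response: str
    predictor: str
    slope: float
    se: float
    p_value: float
    n: int
    model: str
    notes: list[str] = field(default_factory=list)


@dataclass
class PartialCorrelationResult:
    x: str
    y: str
    r: float
    p_value: float
    n: int
    controlled: str = "cohort"


@dataclass
class ModelComparison:
    base_adj_r2: float
    augmented_adj_r2: float
    added_trait: str
    n: int
    notes: list[str] = field(default_factory=list)

    def display(self) -> str:
        """Two-decimal rendering of the adjusted R² pair."""
        return (
            f"adj R2 without {self.added_trait}: {self.base_adj_r2:.2f}; "
            f"with: {self.augmented_adj_r2:.2f}"
        )


def _association_design(
    df: pd.DataFrame, temp_col: str, with_station_terms: bool = True
) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Design: intercept + temp + cohort dummies + THI (+ station, THI×station)."""
    parts = [
        pd.Series(1.0, index=df.index, name="Intercept"),
        df[temp_col].astype(float).rename("temp_trait"),
    ]
    parts.append(pd.get_dummies(df["cohort"].astype(str), prefix="cohort", drop_first=True, dtype=float))
    if "thi" in df.columns:
        parts.append(df["thi"].astype(float).rename("thi"))
        if with_station_terms and "station" in df.columns:
            st = pd.get_dummies(df["station"].astype(str), prefix="station", drop_first=True, dtype=float)
            parts.append(st)
            for col in st.columns:
                parts.append((st[col] * df["thi"].astype(float)).rename(f"thi:{col}"))
    X = pd.concat(parts, axis=1)
    Xk, dropped = drop_aliased(X)
    notes = [f"aliased terms dropped: {dropped}"] if dropped else []
    if "temp_trait" in dropped:
        raise ModelError("temperature trait has zero variance (or is aliased); no slope estimable")
    return Xk, dropped, notes


def regress_trait(
    df: pd.DataFrame,
    response: str,
    temp_trait: str,
    temp_col: str = "temp_trait",
    response_col: str = "response",
) -> AssociationResult:
    """Trial-level OLS of one efficiency trait on one temperature trait.

    ``df`` has one row per cow with columns ``response_col``, ``temp_col``,
    ``cohort`` and optionally ``thi`` and ``station``. Reports the
    temperature-trait slope with its SE and two-sided t-test p-value.
    """
    data = df.dropna(subset=[response_col, temp_col]).reset_index(drop=True)
    X, dropped, notes = _association_design(data, temp_col)
    if len(data) < X.shape[1] + 2:
        raise ModelError(f"only {len(data)} complete cases for {X.shape[1]} parameters")
    res = sm.OLS(data[response_col].to_numpy(dtype=float), X).fit()
    fixed = [c for c in X.columns if c != "temp_trait"]
    return AssociationResult(
        response=response,
        predictor=temp_trait,
        slope=float(res.params["temp_trait"]),
        se=float(res.bse["temp_trait"]),
        p_value=float(res.pvalues["temp_trait"]),
        n=len(data),
        model=f"OLS: {response} ~ {temp_trait} + {' + '.join(fixed)}",
        notes=notes,
    )


def daily_mixed_model(
    df: pd.DataFrame,
    response: str,
    temp_trait: str,
    temp_col: str = "temp_trait",
    response_col: str = "response",
) -> AssociationResult:
    """Daily mixed model: response on daily temperature trait, cow as random intercept.

    ``df`` has one row per cow-day with columns ``cow_id``, ``response_col``,
    ``temp_col``, ``cohort`` and optionally ``thi``/``station`` (daily THI).
    Fitted by REML. If every cow contributes a single record the random
    intercept is unidentifiable and the model falls back to pooled OLS with a
    note; a singular random-effect variance also only attaches a note.
    """
    data = df.dropna(subset=[response_col, temp_col]).reset_index(drop=True)
    X, dropped, notes = _association_design(data, temp_col)
    y = data[response_col].to_numpy(dtype=float)
    groups = data["cow_id"].to_numpy()
    fixed = [c for c in X.columns if c != "temp_trait"]
    desc = f"LMM (REML): {response} ~ {temp_trait} + {' + '.join(fixed)} + (1|cow)"

    max_per_cow = data.groupby("cow_id").size().max()
    if max_per_cow <= 1:
        res = sm.OLS(y, X).fit()
        notes = notes + ["one record per cow: random intercept unidentifiable, pooled OLS used"]
        return AssociationResult(
            response, temp_trait,
            float(res.params["temp_trait"]), float(res.bse["temp_trait"]),
            float(res.pvalues["temp_trait"]), len(data), desc + " [degenerate→OLS]", notes,
        )

    res = None
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        for method in ("lbfgs", "powell"):
            try:
                res = sm.MixedLM(y, X, groups=groups).fit(reml=True, method=method)
                break
            except (np.linalg.LinAlgError, ValueError) as exc:
                notes = notes + [f"refit note: {method} failed ({exc})"]
    if res is None:
        # variance component on the boundary: pooled OLS is the limiting model
        ols = sm.OLS(y, X).fit()
        notes = notes + ["refit note: random-intercept variance singular, pooled OLS used"]
        return AssociationResult(
            response, temp_trait,
            float(ols.params["temp_trait"]), float(ols.bse["temp_trait"]),
            float(ols.pvalues["temp_trait"]), len(data), desc + " [singular→OLS]", notes,
        )
    for w in caught:
        if "singular" in str(w.message).lower() or "converge" in str(w.message).lower():
            notes = notes + [f"refit note: {w.message}"]
    return AssociationResult(
        response=response,
        predictor=temp_trait,
        slope=float(res.params["temp_trait"]),
        se=float(res.bse["temp_trait"]),
        p_value=float(res.pvalues["temp_trait"]),
        n=len(data),
        model=desc,
        notes=notes,
    )


def partial_correlation(x, y, cohort, x_name: str = "x", y_name: str = "y") -> PartialCorrelationResult:
    """Pearson correlation of x and y after removing cohort means from each.

    Both variables are regressed on cohort indicators (with intercept); the
    correlation of the residuals is tested with a t statistic on
    n − (#cohorts) − 1 degrees of freedom. With a single cohort this is the
    plain Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    cohort = np.asarray(cohort)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y, cohort = x[mask], y[mask], cohort[mask]
    levels, codes = np.unique(cohort, return_inverse=True)
    g = len(levels)
    n = len(x)
    if n < g + 3:
        raise DataError(f"need at least {g + 3} complete cases for {g} cohorts, got {n}")
    counts = np.bincount(codes)
    if np.any(counts < 2):
        warnings.warn(
            "cohort(s) with a single cow contribute zero within-cohort deviation",
            stacklevel=2,
        )
    # residualize on cohort means (equivalent to regression on indicators + intercept)
    rx = x - np.bincount(codes, weights=x)[codes] / counts[codes]
    ry = y - np.bincount(codes, weights=y)[codes] / counts[codes]
    denom = np.sqrt(np.sum(rx**2) * np.sum(ry**2))
    if denom == 0:
        raise DataError("zero within-cohort variance in x or y")
    r = float(np.sum(rx * ry) / denom)
    df = n - g - 1
    t = r * np.sqrt(df / max(1e-300, 1.0 - r * r))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return PartialCorrelationResult(x_name, y_name, r, p, n)


def compare_rfi_models(records: pd.DataFrame, temp_trait: pd.Series, trait_name: str) -> ModelComparison:
    """Adjusted R² of the RFI model with and without a temperature trait.

    ``temp_trait`` is indexed by cow_id; cows missing the trait are dropped
    from *both* fits so the comparison uses a common cow set (noted).
    """
    rec = records.copy()
    rec[trait_name] = rec["cow_id"].map(temp_trait)
    notes = []
    n_all = len(rec)
    rec = rec.dropna(subset=[trait_name]).reset_index(drop=True)
    if len(rec) < n_all:
        notes.append(f"both models refit on the {len(rec)} cows with {trait_name}")
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        base = compute_rfi(rec)
        aug = compute_rfi(rec, extra=[trait_name])
    for w in caught:
        if "aliased" in str(w.message):
            notes.append(str(w.message))
    return ModelComparison(
        base_adj_r2=base.adj_r2,
        augmented_adj_r2=aug.adj_r2,
        added_trait=trait_name,
        n=len(rec),
        notes=notes,
    )
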