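"""Meal-criterion estimation, visit-to-meal merging and post-meal temperature change.

Feeder visits cluster into meals: the distribution of log10 inter-visit
intervals is bimodal, with a short within-meal component and a long
between-meal component. Fitting a two-component Gaussian mixture to
log10(interval) by maximum likelihood and locating the point where the two
weighted component densities cross yields the *meal criterion*: visits
separated by less than it belong to the same meal.

The post-meal phenotype is the body temperature 20 min after the end of the
day's largest meal minus the temperature at the start of the meal, each
taken as the average of 3 consecutive records.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq
from sklearn.mixture import GaussianMixture

from .errors import CriterionError, DataError
from .phenotypes import TemperatureTrace

__all__ = [
    "MixtureFit",
    "PostMealDelta",
    "fit_interval_mixture",
    "meal_criterion",
    "merge_visits_to_meals",
    "largest_meal_per_day",
    "post_meal_delta",
    "cow_post_meal_trait",
]

#: minimum number of intervals for a stable mixture fit
MIN_INTERVALS = 50


@dataclass
class MixtureFit:
    """Gaussian mixture on the log10-minute scale, components sorted by mean."""

    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    log_likelihood: float
    n_intervals: int
    converged: bool

    @property
    def n_components(self) -> int:
        return len(self.weights)

    def to_dict(self) -> dict:
        return {
            "weights": [float(w) for w in self.weights],
            "means_log10_min": [float(m) for m in self.means],
            "sds_log10_min": [float(s) for s in self.sds],
            "log_likelihood": float(self.log_likelihood),
            "n_intervals": int(self.n_intervals),
            "converged": bool(self.converged),
        }


@dataclass
class PostMealDelta:
    """Temperature change around one meal: ``delta = post_temp - pre_temp``."""

    cow_id: str
    date: object
    delta: float
    pre_temp: float
    post_temp: float


def fit_interval_mixture(
    intervals, n_components: int = 2, seed: int = 0, n_init: int = 8
) -> MixtureFit:
    """ML fit of an ``n_components`` Gaussian mixture to log10(interval minutes).

    Multiple random restarts; the best-likelihood solution is returned with
    components sorted by mean. Degenerate input (all intervals identical)
    returns a fit flagged ``converged=False``.
    """
    x = np.asarray(intervals, dtype=float)
    if x.size < MIN_INTERVALS:
        raise DataError(f"need at least {MIN_INTERVALS} intervals, got {x.size}")
    if np.any(x <= 0) or not np.all(np.isfinite(x)):
        raise DataError("intervals must be positive and finite")
    logx = np.log10(x)
    if np.ptp(logx) == 0.0:
        return MixtureFit(
            weights=np.ones(n_components) / n_components,
            means=np.full(n_components, logx[0]),
            sds=np.zeros(n_components),
            log_likelihood=float("inf"),
            n_intervals=x.size,
            converged=False,
        )
    gm = GaussianMixture(
        n_components=n_components,
        covariance_type="full",
        n_init=n_init,
        max_iter=500,
        reg_covar=1e-6,
        random_state=int(seed) % (2**31),
    )
    X = logx.reshape(-1, 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gm.fit(X)
    order = np.argsort(gm.means_.ravel())
    weights = gm.weights_[order]
    means = gm.means_.ravel()[order]
    sds = np.sqrt(gm.covariances_.reshape(-1)[order])
    loglik = float(gm.score(X) * X.shape[0])
    return MixtureFit(weights, means, sds, loglik, x.size, bool(gm.converged_))


def meal_criterion(fit: MixtureFit) -> float:
    """Extract the meal criterion (minutes) from a converged mixture fit.

    The criterion is ``10**x*`` where ``x*`` is the point between the two
    component means at which the weighted component densities are equal.
    With more than two components the two longest-interval components are
    used. Found by a bracketed root solve.
    """
    if not fit.converged:
        raise CriterionError("mixture fit did not converge; no criterion extracted")
    if fit.n_components < 2:
        raise CriterionError("criterion needs at least two components")
    a, b = fit.n_components - 2, fit.n_components - 1
    wa, ma, sa = fit.weights[a], fit.means[a], fit.sds[a]
    wb, mb, sb = fit.weights[b], fit.means[b], fit.sds[b]
    if not ma < mb:
        raise CriterionError("component means are not separated")

    def f(x: float) -> float:
        return wa * stats.norm.pdf(x, ma, sa) - wb * stats.norm.pdf(x, mb, sb)

    eps = 1e-9 * max(1.0, abs(ma), abs(mb))
    lo, hi = ma + eps, mb - eps
    flo, fhi = f(lo), f(hi)
    if flo <= 0 or fhi >= 0:
        raise CriterionError(
            "no density intersection between component means "
            f"(f({lo:.3f})={flo:.3g}, f({hi:.3f})={fhi:.3g}); one component dominates"
        )
    xstar = brentq(f, lo, hi, xtol=1e-12)
    return float(10.0**xstar)


def extract_intervals(visits: pd.DataFrame) -> np.ndarray:
    """Pooled inter-visit intervals (minutes), end of one visit to start of the next."""
    v = _check_visits(visits)
    gaps = []
    for _, grp in v.groupby("cow_id", sort=False):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        if len(grp) > 1:
            g = (starts[1:] - ends[:-1]) / np.timedelta64(1, "m")
            gaps.append(g.astype(float))
    if not gaps:
        return np.empty(0)
    out = np.concatenate(gaps)
    return out[out > 0]


def _check_visits(visits: pd.DataFrame) -> pd.DataFrame:
    required = {"cow_id", "start", "end", "intake_kg"}
    missing = required - set(visits.columns)
    if missing:
        raise DataError(f"visit log missing columns: {sorted(missing)}")
    v = visits.copy()
    v["start"] = pd.to_datetime(v["start"])
    v["end"] = pd.to_datetime(v["end"])
    if (v["end"] < v["start"]).any():
        raise DataError("visit with end before start")
    if (v["intake_kg"] < 0).any():
        raise DataError("negative visit intake")
    v = v.sort_values(["cow_id", "start"], kind="mergesort").reset_index(drop=True)
    prev_end = v.groupby("cow_id")["end"].shift()
    if ((v["start"] - prev_end) < pd.Timedelta(0)).any():
        raise DataError("overlapping visits within a cow")
    return v


def merge_visits_to_meals(visits: pd.DataFrame, criterion: float) -> pd.DataFrame:
    """Merge consecutive visits with end-to-start gap strictly below ``criterion`` minutes.

    Returns one row per meal: cow_id, start, end, intake_kg, n_visits.
    A gap exactly equal to the criterion starts a new meal.
    """
    if criterion <= 0:
        raise DataError("criterion must be positive minutes")
    v = _check_visits(visits)
    prev_end = v.groupby("cow_id")["end"].shift()
    gap_min = (v["start"] - prev_end) / pd.Timedelta(minutes=1)
    new_meal = gap_min.isna() | (gap_min >= criterion)
    v["meal_id"] = new_meal.cumsum()
    meals = (
        v.groupby(["cow_id", "meal_id"], sort=False)
        .agg(
            start=("start", "first"),
            end=("end", "last"),
            intake_kg=("intake_kg", "sum"),
            n_visits=("start", "size"),
        )
        .reset_index()
        .drop(columns="meal_id")
    )
    return meals


def largest_meal_per_day(meals: pd.DataFrame) -> pd.DataFrame:
    """Flag the highest-intake meal per cow-day (ties broken by earliest start).

    Meals are assigned to calendar days by their start time; a new boolean
    column ``is_largest_of_day`` is added.
    """
    m = meals.copy()
    m["start"] = pd.to_datetime(m["start"])
    m["date"] = m["start"].dt.date
    m["is_largest_of_day"] = False
    if len(m):
        ranked = m.sort_values(
            ["cow_id", "date", "intake_kg", "start"],
            ascending=[True, True, False, True],
            kind="mergesort",
        )
        top = ranked.groupby(["cow_id", "date"], sort=False).head(1).index
        m.loc[top, "is_largest_of_day"] = True
    return m


def post_meal_delta(
    trace: TemperatureTrace, meal_start, meal_end, lag_min: float = 20.0, n_avg: int = 3
) -> PostMealDelta | None:
    """Temperature change around one meal, or None if the trace cannot support it.

    ``pre_temp``: mean of the ``n_avg`` consecutive records nearest to and
    not after the meal start. ``post_temp``: mean of the ``n_avg`` records
    centred on the record nearest to ``meal_end + lag_min`` minutes.
    """
    t = trace.times.values
    meal_start = np.datetime64(pd.Timestamp(meal_start))
    meal_end = np.datetime64(pd.Timestamp(meal_end))
    half = n_avg // 2

    i_end = int(np.searchsorted(t, meal_start, side="right"))
    if i_end < n_avg:
        return None
    pre = float(np.mean(trace.values[i_end - n_avg : i_end]))

    target = meal_end + np.timedelta64(int(round(lag_min * 60)), "s")
    j = int(np.searchsorted(t, target))
    # nearest record; tie (equidistant) resolved toward the earlier record
    if j >= len(t) or (j > 0 and (target - t[j - 1]) <= (t[j] - target)):
        j -= 1
    if j - half < 0 or j + half >= len(t):
        return None
    post = float(np.mean(trace.values[j - half : j + half + 1]))

    return PostMealDelta(
        cow_id=trace.cow_id,
        date=pd.Timestamp(meal_start).date(),
        delta=post - pre,
        pre_temp=pre,
        post_temp=post,
    )


def cow_post_meal_trait(
    trace: TemperatureTrace, meals: pd.DataFrame, lag_min: float = 20.0
) -> tuple[float, list[PostMealDelta]]:
    """Cow-level post-meal trait: mean delta over the largest meals of the trial.

    ``meals`` must carry ``is_largest_of_day``; meals with insufficient trace
    coverage are skipped with a warning. Returns ``(trait, per-meal deltas)``;
    the trait is NaN when no meal was evaluable.
    """
    if "is_largest_of_day" not in meals.columns:
        meals = largest_meal_per_day(meals)
    sel = meals[(meals["cow_id"] == trace.cow_id) & meals["is_largest_of_day"]]
    deltas: list[PostMealDelta] = []
    skipped = 0
    for _, row in sel.iterrows():
        d = post_meal_delta(trace, row["start"], row["end"], lag_min=lag_min)
        if d is None:
            skipped += 1
        else:
            deltas.append(d)
    if skipped:
        warnings.warn(
            f"cow {trace.cow_id!r}: {skipped} largest meal(s) skipped for insufficient trace coverage",
            stacklevel=2,
        )
    trait = float(np.mean([d.delta for d in deltas])) if deltas else float("nan")
    return trait, deltas
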