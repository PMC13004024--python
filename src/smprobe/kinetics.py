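"""Dwell/arrival statistics, censored exponential fits, on-rates and Kd.

Bound lifetimes and probe arrival times from single-molecule event tables
are treated as (possibly right-censored) survival data: an event truncated
by photobleaching or the movie end contributes a survival term to the
likelihood instead of a density term, and molecules that never bind
contribute right-censored arrival times.  Apparent dissociation constants
come from the equilibrium bound-time fraction of each molecule,

    Y = t_PR / (t_PR + t_R),        Kd = (1 - Y) / Y * [P]0,

with ``t_PR`` the total protein-complexed time and ``t_R`` the total free
time inside the evaluation window (default from 200 s until donor bleach),
and ``[P]0`` the total labeled protein concentration standing in for the
free concentration.  A class-level ("bulk") Kd pools all molecules of a
folding class into a single virtual molecule before applying the formula.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter
from scipy.optimize import minimize

from .io import EventTable
from .selection import MoleculeAnnotation

ARRIVAL = "arrival_time"
BOUND_LIFETIME = "bound_lifetime"
INTERARRIVAL = "interarrival"


@dataclass
class DwellSample:
    """Positive durations (s) with right-censoring flags."""

    values: np.ndarray
    censored: np.ndarray
    kind: str = BOUND_LIFETIME

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.censored = np.asarray(self.censored, dtype=bool)
        if (self.values <= 0).any():
            raise ValueError("dwell values must be > 0")

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def n_uncensored(self) -> int:
        return int((~self.censored).sum())

    @property
    def censoring_fraction(self) -> float:
        return float(self.censored.mean()) if self.n else 0.0

    def median(self, method: str = "auto") -> float:
        """Sample median; Kaplan-Meier when censoring exceeds 5%.

        ``method='naive'`` forces the plain median of uncensored values,
        ``method='km'`` forces the Kaplan-Meier estimate.
        """
        if method == "auto":
            method = "km" if self.censoring_fraction > 0.05 else "naive"
        if method == "naive":
            vals = self.values[~self.censored]
            return float(np.median(vals)) if len(vals) else math.nan
        kmf = KaplanMeierFitter()
        kmf.fit(self.values, event_observed=~self.censored)
        return float(kmf.median_survival_time_)


@dataclass
class ExponentialFit:
    """Maximum-likelihood exponential (mixture) fit of a dwell sample.

    ``model_preference`` is ``AIC(1 component) - AIC(2 components)`` when
    both were fitted; positive values prefer the richer model.
    """

    n_components: int
    rates: tuple[float, ...]
    weights: tuple[float, ...]
    log_likelihood: float
    model_preference: float = math.nan
    converged: bool = True
    message: str = ""

    @property
    def mean_dwell(self) -> float:
        return float(sum(w / r for w, r in zip(self.weights, self.rates)))


def _exp_loglik(values, censored, rates, weights) -> float:
    rates = np.asarray(rates)[None, :]
    weights = np.asarray(weights)[None, :]
    t = np.asarray(values)[:, None]
    surv = weights * np.exp(-rates * t)
    dens = (weights * rates * np.exp(-rates * t)).sum(axis=1)
    surv = surv.sum(axis=1)
    obs = ~np.asarray(censored)
    with np.errstate(divide="ignore"):
        ll = np.where(obs, np.log(np.maximum(dens, 1e-300)), np.log(np.maximum(surv, 1e-300)))
    return float(ll.sum())


def fit_exponential(sample: DwellSample, n_components: int = 1) -> ExponentialFit:
    """Censored maximum-likelihood exponential (mixture) fit.

    The single-component MLE is closed form: rate = (# uncensored) / (sum of
    all durations, censored included).  The two-component fit maximizes the
    censored mixture likelihood numerically from moment-based starts.
    """
    if n_components not in (1, 2):
        raise ValueError("n_components must be 1 or 2")
    if sample.n_uncensored < (10 if n_components == 1 else 50):
        raise ValueError(
            f"need >= {10 if n_components == 1 else 50} uncensored dwells, "
            f"got {sample.n_uncensored}"
        )
    total_time = float(sample.values.sum())
    rate1 = sample.n_uncensored / total_time
    ll1 = _exp_loglik(sample.values, sample.censored, [rate1], [1.0])
    if n_components == 1:
        return ExponentialFit(1, (rate1,), (1.0,), ll1)

    def negloglik(theta):
        r1, r2 = np.exp(theta[0]), np.exp(theta[1])
        w = 1.0 / (1.0 + np.exp(-theta[2]))
        return -_exp_loglik(sample.values, sample.censored, [r1, r2], [w, 1.0 - w])

    starts = []
    uncensored = sample.values[~sample.censored]
    q25, q75 = np.quantile(uncensored, [0.25, 0.75])
    for fast, slow, w in [
        (3.0 * rate1, rate1 / 3.0, 0.5),
        (math.log(2.0) / max(q25, 1e-9), math.log(2.0) / max(q75, 1e-9), 0.5),
        (10.0 * rate1, rate1, 0.3),
    ]:
        starts.append([math.log(fast), math.log(slow), math.log(w / (1 - w))])
    best = None
    for x0 in starts:
        res = minimize(negloglik, x0, method="Nelder-Mead", options={"maxiter": 2000, "xatol": 1e-6, "fatol": 1e-9})
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    r1, r2 = float(np.exp(best.x[0])), float(np.exp(best.x[1]))
    w = float(1.0 / (1.0 + math.exp(-best.x[2])))
    if r1 < r2:  # report fast component first
        r1, r2, w = r2, r1, 1.0 - w
    ll2 = -float(best.fun)
    aic1 = 2 * 1 - 2 * ll1
    aic2 = 2 * 3 - 2 * ll2
    return ExponentialFit(
        2,
        (r1, r2),
        (w, 1.0 - w),
        ll2,
        model_preference=aic1 - aic2,
        converged=bool(best.success or ll2 >= ll1),
        message=str(best.message),
    )


# ---------------------------------------------------------------------------
# arrival times and bound lifetimes
# ---------------------------------------------------------------------------


def arrival_times(
    events: EventTable,
    annotations: list[MoleculeAnnotation],
    reporter: str,
    t0: float | None = None,
    delivery_time: float = 25.0,
) -> DwellSample:
    """Time from reagent delivery to the first event, per selected molecule.

    ``t0`` defaults to the delivery time (end of the injection dead time).
    Molecules without any event contribute a right-censored value at the end
    of their usable window (donor bleach or trace end).
    """
    start = delivery_time if t0 is None else t0
    values, censored = [], []
    for ann in annotations:
        if not ann.selected:
            continue
        usable_end = ann.donor_bleach_time
        if math.isnan(usable_end):
            usable_end = ann.duration
        if start >= usable_end:
            raise ValueError(f"t0={start} is past the usable end of {ann.molecule_id}")
        ev = events.select(molecule_id=ann.molecule_id, reporter=reporter)
        starts = (
            ev.df["t_start_sub"]
            if "t_start_sub" in ev.df.columns
            else ev.df["t_start"]
        )
        first = None
        for t_start in starts:
            if t_start >= start:
                first = t_start
                break
        if first is None:
            values.append(usable_end - start)
            censored.append(True)
        else:
            values.append(max(first - start, 1e-9))
            censored.append(False)
    return DwellSample(np.array(values), np.array(censored), kind=ARRIVAL)


def bound_lifetimes(events: EventTable, reporter: str | None = None) -> DwellSample:
    """Event durations with censoring flags propagated from the table."""
    table = events if reporter is None else events.select(reporter=reporter)
    return DwellSample(table.durations, table.censored, kind=BOUND_LIFETIME)


# ---------------------------------------------------------------------------
# concentration dependence
# ---------------------------------------------------------------------------


@dataclass
class OnRateFit:
    """Linear fit of pseudo-first-order arrival rate vs. concentration."""

    kon: float  # slope, 1/M/s
    intercept: float  # 1/s
    r_squared: float
    concentrations: np.ndarray
    rates: np.ndarray


def on_rate_vs_concentration(
    concentrations: np.ndarray,
    rates: np.ndarray,
    weights: np.ndarray | None = None,
    through_origin: bool = False,
) -> OnRateFit:
    """Weighted linear fit of arrival rate against probe concentration."""
    c = np.asarray(concentrations, dtype=float)
    r = np.asarray(rates, dtype=float)
    if len(c) < 2:
        raise ValueError("need rates at >= 2 concentrations")
    w = np.ones_like(c) if weights is None else np.asarray(weights, dtype=float)
    if through_origin:
        slope = float(np.sum(w * c * r) / np.sum(w * c * c))
        intercept = 0.0
    else:
        wsum = w.sum()
        cbar = np.sum(w * c) / wsum
        rbar = np.sum(w * r) / wsum
        slope = float(np.sum(w * (c - cbar) * (r - rbar)) / np.sum(w * (c - cbar) ** 2))
        intercept = float(rbar - slope * cbar)
    pred = slope * c + intercept
    ss_res = float(np.sum(w * (r - pred) ** 2))
    ss_tot = float(np.sum(w * (r - np.sum(w * r) / w.sum()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return OnRateFit(kon=slope, intercept=intercept, r_squared=r2, concentrations=c, rates=r)


# ---------------------------------------------------------------------------
# Kd from bound-time fraction
# ---------------------------------------------------------------------------

SINGLE_MOLECULE = "single_molecule"
BULK_CLASS = "bulk_class"


@dataclass
class KdEstimate:
    """Apparent dissociation constant from the bound-time fraction."""

    y: float  # bound fraction in [0, 1]
    t_bound: float  # t_PR, seconds
    t_free: float  # t_R, seconds
    p0: float  # total labeled protein concentration, molar
    kd: float | None  # molar; None (undefined) when y == 0
    scope: str = SINGLE_MOLECULE

    @property
    def defined(self) -> bool:
        return self.kd is not None


def _window_durations(
    window: tuple[float, float], dead_window: tuple[float, float] | None
) -> float:
    start, end = window
    if end <= start:
        raise ValueError(f"empty evaluation window {window}")
    total = end - start
    if dead_window is not None:
        lo = max(start, dead_window[0])
        hi = min(end, dead_window[1])
        total -= max(hi - lo, 0.0)
    return total


def _kd_from_times(t_bound: float, t_free: float, p0: float, scope: str) -> KdEstimate:
    total = t_bound + t_free
    y = t_bound / total if total > 0 else 0.0
    kd = None if y <= 0 else (1.0 - y) / y * p0
    return KdEstimate(y=y, t_bound=t_bound, t_free=t_free, p0=p0, kd=kd, scope=scope)


def kd_single_molecule(
    events: EventTable,
    window: tuple[float, float],
    p0: float,
    dead_window: tuple[float, float] | None = None,
) -> KdEstimate:
    """Per-molecule Kd from total bound vs. free time inside ``window``.

    ``window`` is typically (200 s, donor bleach time).  Time inside the
    laser dead window is excluded from both numerator and denominator.
    A molecule that is never bound gets ``kd=None`` (flagged undefined)
    rather than an infinity.
    """
    if p0 <= 0:
        raise ValueError("p0 must be > 0")
    usable = _window_durations(window, dead_window)
    t_bound = events.total_time_in(*window)
    if dead_window is not None:
        lo, hi = max(window[0], dead_window[0]), min(window[1], dead_window[1])
        if hi > lo:
            t_bound -= events.total_time_in(lo, hi)
    t_free = max(usable - t_bound, 0.0)
    return _kd_from_times(t_bound, t_free, p0, SINGLE_MOLECULE)


def kd_bulk(
    per_molecule: list[tuple[EventTable, tuple[float, float]]],
    p0: float,
    dead_window: tuple[float, float] | None = None,
) -> KdEstimate:
    """Class-level Kd: all molecules pooled into a single virtual molecule."""
    if not per_molecule:
        raise ValueError("empty class")
    t_bound = 0.0
    t_free = 0.0
    for events, window in per_molecule:
        est = kd_single_molecule(events, window, p0, dead_window)
        t_bound += est.t_bound
        t_free += est.t_free
    return _kd_from_times(t_bound, t_free, p0, BULK_CLASS)


def kd_fold_change(a: KdEstimate, b: KdEstimate) -> float:
    """Ratio of two (bulk) Kd estimates, ``a / b``."""
    if not (a.defined and b.defined):
        raise ValueError("fold change undefined when either Kd is undefined")
    assert a.kd is not None and b.kd is not None
    return a.kd / b.kd


__all__ = [
    "ARRIVAL",
    "BOUND_LIFETIME",
    "BULK_CLASS",
    "DwellSample",
    "ExponentialFit",
    "KdEstimate",
    "OnRateFit",
    "SINGLE_MOLECULE",
    "arrival_times",
    "bound_lifetimes",
    "fit_exponential",
    "kd_bulk",
    "kd_fold_change",
    "kd_single_molecule",
    "on_rate_vs_concentration",
]
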