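"""Time-tracked prediction error for survival models.

The Brier score at time t is the mean squared deviation between the
predicted event probability pi(t, x) and the observed event status
delta(t) = I(T <= t).  Right censoring is handled with inverse probability
of censoring weights (IPCW): a case censored before t contributes weight 0,
a case with an observed event before t is up-weighted by 1/P(t_i-), and a
case still at risk at t by 1/P(t), where P is the (marginal) reverse
Kaplan-Meier estimate of the censoring survival function.  Curves are
aggregated into the integrated prediction error (IPEC, a trapezoidal
integral over the evaluation grid) and reported relative to the
Kaplan-Meier reference predictor:

    rIPEC = (IPEC_KM - IPEC_model) / IPEC_KM,

positive values meaning the model beats the covariate-free KM prediction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data import SurvivalDataset
from .stepfun import StepFunction

logger = logging.getLogger(__name__)

__all__ = [
    "kaplan_meier",
    "censoring_survival",
    "brier_curve",
    "ipec",
    "ripec",
    "mean_curve",
    "PredictionErrorCurve",
    "evaluation_grid",
]


@dataclass(frozen=True)
class PredictionErrorCurve:
    """Expected Brier score tracked over an evaluation time grid."""

    times: np.ndarray
    err: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        e = np.asarray(self.err, dtype=float)
        if t.shape != e.shape:
            raise ValueError("times and err must have equal shape")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "err", e)


def _product_limit(times, indicator) -> StepFunction:
    """Product-limit estimator treating ``indicator`` as the event flag."""
    times = np.asarray(times, dtype=float)
    ind = np.asarray(indicator).astype(bool)
    order = np.argsort(times, kind="stable")
    t, d = times[order], ind[order]
    uniq = np.unique(t[d]) if d.any() else np.array([])
    if uniq.size == 0:
        return StepFunction(np.array([]), np.array([]), init=1.0)
    at_risk = t.size - np.searchsorted(t, uniq, side="left")
    deaths = np.array([np.sum(d[t == u]) for u in uniq])
    surv = np.cumprod(1.0 - deaths / at_risk)
    return StepFunction(uniq, surv, init=1.0)


def kaplan_meier(times, events) -> StepFunction:
    """Kaplan-Meier estimate of the survival function S(t)."""
    return _product_limit(times, events)


def censoring_survival(times, events) -> StepFunction:
    """Reverse Kaplan-Meier: product-limit estimate of P(C > t), obtained by
    flipping the event indicator.  Marginal (covariate-free)."""
    return _product_limit(times, 1 - np.asarray(events))


def evaluation_grid(test: SurvivalDataset, cens: StepFunction,
                    min_cens_prob: float = 0.05) -> np.ndarray:
    """Unique event times of the test part, truncated at the largest test
    time with censoring survival above ``min_cens_prob`` (weight stability)."""
    grid = np.unique(test.times[test.events == 1])
    tau_candidates = test.times[cens(test.times) > min_cens_prob]
    if tau_candidates.size == 0:
        return grid[:1]
    return grid[grid <= tau_candidates.max()]


def ipcw_weights(times, events, t: float, cens: StepFunction) -> np.ndarray:
    """IPCW weights W_i(t): I(t_i <= t) delta_i / P(t_i-) + I(t_i > t) / P(t).

    Cases censored at or before t get weight 0.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    w = np.zeros(times.size)
    past_event = (times <= t) & (events == 1)
    denom_past = cens.left(times[past_event])
    w[past_event] = np.where(denom_past > 0, 1.0 / denom_past, 0.0)
    at_risk = times > t
    p_t = float(cens(t))
    if p_t > 0:
        w[at_risk] = 1.0 / p_t
    return w


def brier_curve(event_prob, test: SurvivalDataset, cens: StepFunction,
                grid=None) -> PredictionErrorCurve:
    """IPCW Brier score of an event-probability predictor over a grid.

    ``event_prob(t, X)`` must return pi(t, x) for an (m, p) matrix X (an
    (m,) vector of probabilities).  ``cens`` is the censoring survival
    estimated on the *training* part.  Grid points where P(t) = 0 are
    dropped (logged), since the weights are undefined there.
    """
    if grid is None:
        grid = evaluation_grid(test, cens)
    grid = np.asarray(grid, dtype=float)
    keep = cens(grid) > 0
    if not keep.all():
        logger.warning("truncating Brier grid at last time with positive "
                       "censoring survival (%d points dropped)", (~keep).sum())
        grid = grid[keep]
    err = np.empty(grid.size)
    for k, t in enumerate(grid):
        w = ipcw_weights(test.times, test.events, t, cens)
        status = ((test.times <= t) & (test.events == 1)).astype(float)
        pi = np.asarray(event_prob(t, test.covariates), dtype=float)
        err[k] = np.mean(w * (status - pi) ** 2)
    return PredictionErrorCurve(grid, err)


def km_event_prob(km: StepFunction):
    """Adapt a survival step function to the ``event_prob(t, X)`` signature
    used by :func:`brier_curve` (covariate-free predictor)."""
    def predict(t, X):
        return np.full(np.atleast_2d(X).shape[0], 1.0 - float(km(t)))
    return predict


def mean_curve(curves) -> PredictionErrorCurve:
    """Aggregate prediction error curves from several resamples by plain
    pointwise averaging on the union grid (each curve extended as a
    right-continuous step function)."""
    curves = list(curves)
    if not curves:
        raise ValueError("need at least one curve")
    grid = np.unique(np.concatenate([c.times for c in curves]))
    stacked = np.vstack([
        StepFunction(c.times, c.err, init=0.0)(grid) for c in curves])
    return PredictionErrorCurve(grid, stacked.mean(axis=0))


def ipec(curve: PredictionErrorCurve) -> float:
    """Integrated prediction error: trapezoidal integral of the curve."""
    if curve.times.size < 2:
        raise ValueError("need at least 2 grid points to integrate")
    return float(np.trapezoid(curve.err, curve.times))


def ripec(ipec_model: float, ipec_km: float) -> float:
    """Relative integrated prediction error versus the Kaplan-Meier:
    (IPEC_KM - IPEC_model) / IPEC_KM."""
    if ipec_km == 0:
        raise ZeroDivisionError("IPEC of the Kaplan-Meier reference is zero")
    return (ipec_km - ipec_model) / ipec_km
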