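"""Componentwise likelihood-based boosting for the Cox proportional hazards
model.

The hazard is lambda(t|x) = lambda0(t) exp(x' beta).  Starting from beta = 0,
each boosting step updates exactly one coefficient: for every candidate j the
score U_j and Fisher information I_j of the partial log-likelihood are
evaluated at theta_j = 0 (all other components held at the current estimate),
the penalized score statistic U_j^2 / (I_j + rho) picks the winner j*, and
beta_{j*} is moved by the penalized Newton step U_{j*} / (I_{j*} + rho).
The penalty rho = (number of events) * (1/nu - 1) makes nu the relative step
size; mandatory (clinical) covariates are refit without penalty at the start
of every step.  The step count is the only other tuning parameter and is
chosen by cross-validated predictive partial likelihood.

Ties are handled with the Breslow convention throughout: the risk set at an
event time t_i is every subject j with t_j >= t_i.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import NoEventsError, StandardizationParams, SurvivalDataset, standardize
from .stepfun import StepFunction

logger = logging.getLogger(__name__)

__all__ = [
    "BoostConfig",
    "CoxBoost",
    "CoxBoostResults",
    "partial_log_likelihood",
    "score_and_information",
    "fit_coxboost",
    "cv_select_steps",
    "breslow_baseline",
]


@dataclass(frozen=True)
class BoostConfig:
    """Tuning parameters of the boosting fit.

    ``penalty=None`` means the default rho = n_events * (1/nu - 1).
    ``unpenalized`` overrides the dataset's mandatory index set.
    """

    nu: float = 0.05
    penalty: float | None = None
    max_steps: int = 200
    cv_folds: int = 10
    unpenalized: tuple[int, ...] | None = None

    def __post_init__(self):
        if not 0 < self.nu <= 1:
            raise ValueError("nu must be in (0, 1]")
        if self.penalty is not None and self.penalty < 0:
            raise ValueError("penalty must be >= 0")
        if self.max_steps < 0:
            raise ValueError("max_steps must be >= 0")


class _PLLWorkspace:
    """Sorted views of one dataset plus the Breslow risk-set bookkeeping.

    Rows are sorted by observed time ascending; ``first`` maps each sorted
    row to the first row sharing its time, so reverse cumulative sums taken
    at ``first[i]`` are sums over the risk set {j : t_j >= t_i}.
    """

    def __init__(self, times, events, X):
        order = np.argsort(times, kind="stable")
        self.order = order
        self.t = np.asarray(times, float)[order]
        self.d = np.asarray(events)[order].astype(bool)
        self.X = np.asarray(X, float)[order]
        self.first = np.searchsorted(self.t, self.t, side="left")
        self.ev_rows = np.flatnonzero(self.d)
        self.ev_first = self.first[self.ev_rows]

    def eta(self, beta):
        return self.X @ beta

    def pll(self, eta_sorted):
        """Breslow partial log-likelihood from the sorted linear predictor."""
        if self.ev_rows.size == 0:
            return 0.0
        log_s0 = np.logaddexp.accumulate(eta_sorted[::-1])[::-1]
        return float(np.sum(eta_sorted[self.ev_rows] - log_s0[self.ev_first]))

    def _risk_moments(self, eta_sorted, cols=None):
        """Reverse-cumulative weighted moments of X over risk sets.

        Returns (mu, var) at each event row: the risk-set mean and variance
        of every covariate (or of ``cols``), weighted by exp(eta).
        """
        w = np.exp(eta_sorted - eta_sorted.max())
        X = self.X if cols is None else self.X[:, cols]
        w0 = np.cumsum(w[::-1])[::-1]
        wX = np.cumsum((w[:, None] * X)[::-1], axis=0)[::-1]
        wX2 = np.cumsum((w[:, None] * X * X)[::-1], axis=0)[::-1]
        r = self.ev_first
        mu = wX[r] / w0[r, None]
        var = wX2[r] / w0[r, None] - mu**2
        return mu, np.maximum(var, 0.0)

    def score_info(self, eta_sorted, cols=None):
        """Score U_j and information I_j at theta_j = 0 for all covariates."""
        if self.ev_rows.size == 0:
            p = self.X.shape[1] if cols is None else len(np.atleast_1d(cols))
            return np.zeros(p), np.zeros(p)
        mu, var = self._risk_moments(eta_sorted, cols)
        Xev = self.X[self.ev_rows] if cols is None else self.X[np.ix_(self.ev_rows, np.atleast_1d(cols))]
        U = np.sum(Xev - mu, axis=0)
        I = np.sum(var, axis=0)
        return U, I


def partial_log_likelihood(beta, data: SurvivalDataset) -> float:
    """Breslow partial log-likelihood of ``beta`` on ``data`` (covariates
    taken as given, no standardization)."""
    ws = _PLLWorkspace(data.times, data.events, data.covariates)
    return ws.pll(ws.eta(np.asarray(beta, float)))

def score_and_information(j: int, beta, data: SurvivalDataset) -> tuple[float, float]:
    """Score and Fisher information of the PLL in direction j, evaluated at
    theta_j = 0 with the other components held at ``beta``."""
    ws = _PLLWorkspace(data.times, data.events, data.covariates)
    U, I = ws.score_info(ws.eta(np.asarray(beta, float)), cols=[j])
    return float(U[0]), float(I[0])


@dataclass
class CoxBoostResults:
    """Fitted componentwise-boosting Cox model.

    ``params`` holds coefficients on the standardized-covariate scale (the
    scale on which score statistics are comparable); ``params_original``
    rescales them to the input units.  ``trace`` lists the covariate updated
    in each boosting step and ``pll_path`` the training PLL after each step.
    """

    model: "CoxBoost"
    params: np.ndarray
    steps: int
    trace: list[int]
    pll_path: np.ndarray
    penalty: float

    # -- coefficient views ------------------------------------------------
    @property
    def names(self):
        return self.model.data.names

    @property
    def selected(self) -> np.ndarray:
        """Indices with nonzero coefficients (mandatory ones included)."""
        return np.flatnonzero(self.params != 0.0)

    @property
    def params_original(self) -> np.ndarray:
        return self.params / self.model.scaler.scales

    def summary(self) -> pd.DataFrame:
        """Nonzero coefficients: standardized and original scale, update count."""
        idx = self.selected
        counts = np.bincount(self.trace, minlength=self.params.size) if self.trace else \
            np.zeros(self.params.size, int)
        return pd.DataFrame({
            "covariate": [self.names[j] for j in idx],
            "coef_std": self.params[idx],
            "coef": self.params_original[idx],
            "updates": counts[idx],
            "mandatory": [j in self.model.unpenalized for j in idx],
        }, index=idx)

    # -- prediction -------------------------------------------------------
    def linear_predictor(self, X=None) -> np.ndarray:
        """x' beta on the standardized scale (training rows by default)."""
        Z = self.model.Z if X is None else self.model.scaler.transform(X)
        return Z @ self.params

    @property
    def baseline(self) -> StepFunction:
        """Breslow cumulative baseline hazard on the training data."""
        if not hasattr(self, "_baseline"):
            self._baseline = breslow_baseline(self, self.model.data)
        return self._baseline

    def predict_survival(self, X, t) -> np.ndarray:
        """S(t|x) = exp(-H0(t) exp(x' beta)); x in original units.

        Broadcasts over an (m, p) covariate matrix and a time grid,
        returning an (m, len(t)) array (or lower-dimensional for scalars).
        """
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        if np.any(t_arr < 0):
            raise ValueError("time must be nonnegative")
        X_arr = np.asarray(X, dtype=float)
        lp = self.linear_predictor(np.atleast_2d(X_arr))
        S = np.exp(-np.outer(np.exp(lp), self.baseline(t_arr)))
        if X_arr.ndim == 1:
            S = S[0]
        if np.ndim(t) == 0:
            S = S[..., 0]
        return S

    def predict_event_probability(self, X, t) -> np.ndarray:
        """pi(t, x) = 1 - S(t|x), the probability of an event by t."""
        return 1.0 - self.predict_survival(X, t)


class CoxBoost:
    """Componentwise likelihood-based boosting for the Cox model.

    Parameters
    ----------
    data : SurvivalDataset
        Training data; covariates are standardized internally (constant
        columns get scale 1).
    config : BoostConfig, optional
        Tuning parameters; keyword arguments override individual fields.
    """

    def __init__(self, data: SurvivalDataset, config: BoostConfig | None = None, **kw):
        if config is None:
            config = BoostConfig(**kw)
        elif kw:
            config = BoostConfig(**{**config.__dict__, **kw})
        self.config = config
        self.data = data
        std, self.scaler = standardize(data)
        self.Z = std.covariates
        self.ws = _PLLWorkspace(data.times, data.events, self.Z)
        self.unpenalized = tuple(self.config.unpenalized
                                 if self.config.unpenalized is not None
                                 else data.mandatory)
        self.penalty = (self.config.penalty if self.config.penalty is not None
                        else data.n_events * (1.0 / self.config.nu - 1.0))
        mask = np.ones(data.p, dtype=bool)
        mask[list(self.unpenalized)] = False
        self._penalized_mask = mask

    # -- fitting ----------------------------------------------------------
    def fit(self, steps: int) -> CoxBoostResults:
        """Run ``steps`` boosting updates from beta = 0."""
        beta, trace, pll_path = self._boost_path(self.ws, steps)
        return CoxBoostResults(self, beta, steps, trace, np.asarray(pll_path),
                               self.penalty)

    def _boost_path(self, ws: _PLLWorkspace, steps: int, record_eta=None):
        """Core boosting loop on a workspace (training rows of one fold or
        the full data).  ``record_eta`` optionally receives the full-data
        linear predictor after every step (used by the CV criterion)."""
        if steps > 0 and not ws.d.any():
            raise NoEventsError("boosting requires at least one event")
        p = ws.X.shape[1]
        beta = np.zeros(p)
        eta = np.zeros(ws.X.shape[0])
        trace: list[int] = []
        pll_path = [ws.pll(eta)]
        K = [k for k in self.unpenalized]
        pmask = self._penalized_mask
        for step in range(steps):
            # unpenalized refit cycle over the mandatory covariates
            for k in K:
                U, I = ws.score_info(eta, cols=[k])
                if I[0] > 0:
                    theta = U[0] / I[0]
                    beta[k] += theta
                    eta = eta + theta * ws.X[:, k]
            U, I = ws.score_info(eta)
            crit = np.where(I + self.penalty > 0, U**2 / (I + self.penalty), 0.0)
            crit[~pmask] = -np.inf
            if not np.all(np.isfinite(U)):
                raise FloatingPointError(f"non-finite score statistic at step {step + 1}")
            j = int(np.argmax(crit))
            theta = U[j] / (I[j] + self.penalty) if I[j] + self.penalty > 0 else 0.0
            beta[j] += theta
            eta = eta + theta * ws.X[:, j]
            trace.append(j)
            pll_path.append(ws.pll(eta))
            if record_eta is not None:
                record_eta(step, beta)
        return beta, trace, pll_path

    # -- cross-validation -------------------------------------------------
    def select_steps_cv(self, seed: int = 0, folds: int | None = None,
                        max_steps: int | None = None, return_path: bool = False):
        """Choose the boosting step count by K-fold cross-validated
        predictive partial likelihood.

        For each fold the model path is fit on the complement; the criterion
        at step k is PLL(full data, beta_k) - PLL(training part, beta_k),
        summed over folds (Verweij-van Houwelingen decomposition).  Folds
        are stratified by event status; deterministic given ``seed``.
        """
        folds = folds or self.config.cv_folds
        max_steps = self.config.max_steps if max_steps is None else max_steps
        if folds < 2:
            raise ValueError("need at least 2 folds")
        if max_steps == 0:
            return (0, np.zeros(1)) if return_path else 0
        assign = self._stratified_folds(folds, seed)
        crit = np.zeros(max_steps + 1)
        full_ws = self.ws
        for f in range(folds):
            tr = np.flatnonzero(assign != f)
            ws_tr = _PLLWorkspace(self.data.times[tr], self.data.events[tr], self.Z[tr])
            contrib = np.zeros(max_steps + 1)
            contrib[0] = full_ws.pll(np.zeros(self.data.n)) - ws_tr.pll(np.zeros(tr.size))

            def record(step, beta, _ws=ws_tr, _c=contrib):
                nz = np.flatnonzero(beta)
                eta_full = full_ws.X[:, nz] @ beta[nz]
                _c[step + 1] = full_ws.pll(eta_full) - _ws.pll(_ws.X[:, nz] @ beta[nz])

            self._boost_path(ws_tr, max_steps, record_eta=record)
            crit += contrib
        best = int(np.argmax(crit))
        if best == max_steps:
            logger.info("CV optimum hit the max_steps cap (%d)", max_steps)
        return (best, crit / folds) if return_path else best

    def _stratified_folds(self, folds: int, seed: int, max_redraws: int = 100) -> np.ndarray:
        """Fold assignment stratified by event status, redrawn (incremented
        seed) until every training part (fold complement) keeps >= 1 event."""
        for attempt in range(max_redraws + 1):
            rng = np.random.default_rng(seed + attempt)
            assign = np.empty(self.data.n, dtype=int)
            for status in (0, 1):
                rows = rng.permutation(np.flatnonzero(self.data.events == status))
                assign[rows] = np.arange(rows.size) % folds
            ok = all(self.data.events[assign != f].sum() >= 1 for f in range(folds))
            if ok:
                return assign
        raise NoEventsError(f"could not build event-containing CV folds (seed={seed})")

    def fit_cv(self, seed: int = 0, folds: int | None = None,
               max_steps: int | None = None) -> CoxBoostResults:
        """Select the step count by CV, then fit with it on the full data."""
        return self.fit(self.select_steps_cv(seed=seed, folds=folds, max_steps=max_steps))


# -- functional wrappers (operation-level API) ------------------------------

def fit_coxboost(data: SurvivalDataset, config: BoostConfig | None = None,
                 steps: int = 0) -> CoxBoostResults:
    """Fit a componentwise-boosting Cox model with a fixed step count."""
    return CoxBoost(data, config).fit(steps)


def cv_select_steps(data: SurvivalDataset, config: BoostConfig | None = None,
                    seed: int = 0) -> int:
    """Cross-validated boosting step count for ``data`` under ``config``."""
    return CoxBoost(data, config).select_steps_cv(seed=seed)


def breslow_baseline(results: CoxBoostResults, data: SurvivalDataset) -> StepFunction:
    """Breslow estimator of the cumulative baseline hazard:
    H0(t) = sum over event times s <= t of d_s / sum_{j at risk} exp(eta_j).
    Reduces to Nelson-Aalen when beta = 0."""
    ws = results.model.ws if data is results.model.data else \
        _PLLWorkspace(data.times, data.events, results.model.scaler.transform(data.covariates))
    eta = ws.X @ results.params
    w = np.exp(eta - eta.max())
    s0 = np.cumsum(w[::-1])[::-1] * np.exp(eta.max())
    ev_times = ws.t[ws.d]
    uniq, counts = np.unique(ev_times, return_counts=True)
    # risk-set sum at each unique event time = s0 at the first row with that time
    rows = np.searchsorted(ws.t, uniq, side="left")
    jumps = counts / s0[rows]
    return StepFunction(uniq, np.cumsum(jumps))
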