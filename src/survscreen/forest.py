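"""Random survival forests with log-rank splitting and permutation
importance.

Each tree is grown unpruned on a 0.632 without-replacement resample of the
training data.  At every node, ``mtry`` candidate covariates are drawn and
the split (over all midpoints between adjacent unique values) maximizing
the standardized two-sample log-rank statistic between the daughter nodes
is taken.  Terminal nodes carry the Nelson-Aalen estimate of the cumulative
hazard function (CHF) of their cases, evaluated on the forest time grid
(the union of training event times).  The ensemble CHF of a case is the
average terminal CHF over trees, and its "mortality" -- the predicted risk
score -- is the sum of the ensemble CHF over the grid.

Permutation accuracy importance (PAM) of a covariate is the increase in
out-of-bag (OOB) prediction error, 1 - Harrell's C of OOB mortality, after
the covariate's column is randomly permuted.  Covariates never used in any
split have PAM exactly 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import SurvivalDataset, subsample
from .stepfun import StepFunction

logger = logging.getLogger(__name__)

__all__ = [
    "ForestConfig",
    "SurvivalTree",
    "SurvivalForestModel",
    "SurvivalForestResults",
    "nelson_aalen",
    "logrank_split_statistic",
    "grow_tree",
    "fit_forest",
    "harrell_c",
    "permutation_importance",
]


@dataclass(frozen=True)
class ForestConfig:
    """Forest tuning parameters; ``mtry=None`` means round(sqrt(p))."""

    ntree: int = 1000
    mtry: int | None = None
    min_node_events: int = 3
    resample_fraction: float = 0.632
    seed: int = 0

    def __post_init__(self):
        if self.ntree < 1:
            raise ValueError("ntree must be >= 1")
        if self.mtry is not None and self.mtry < 1:
            raise ValueError("mtry must be >= 1")


def nelson_aalen(times, events) -> StepFunction:
    """Nelson-Aalen cumulative hazard: H(t) = sum_{s <= t} d_s / Y_s over
    the distinct event times s, with d_s deaths and Y_s at risk."""
    times = np.asarray(times, dtype=float)
    d = np.asarray(events).astype(bool)
    if times.size == 0:
        raise ValueError("need at least one observation")
    uniq = np.unique(times[d])
    if uniq.size == 0:
        return StepFunction(np.array([]), np.array([]), init=0.0)
    t_sorted = np.sort(times)
    at_risk = times.size - np.searchsorted(t_sorted, uniq, side="left")
    deaths = np.array([np.sum(d & (times == u)) for u in uniq])
    return StepFunction(uniq, np.cumsum(deaths / at_risk))


def _logrank_stats(times, events, left_masks):
    """Standardized log-rank statistics for many left/right partitions.

    ``left_masks`` is (m, K) boolean; returns (K,) absolute standardized
    statistics (0 where the variance vanishes).
    """
    t = np.asarray(times, dtype=float)
    d = np.asarray(events).astype(bool)
    s = np.unique(t[d])
    if s.size == 0:
        return np.zeros(left_masks.shape[1])
    R = (t[:, None] >= s[None, :]).astype(float)            # at risk
    D = (d[:, None] & (t[:, None] == s[None, :])).astype(float)  # deaths
    Y = R.sum(axis=0)
    dd = D.sum(axis=0)
    L = left_masks.astype(float)
    Yl = R.T @ L                                            # (E, K)
    Ol = D.T @ L
    frac = Yl / Y[:, None]
    expected = dd[:, None] * frac
    hyper = np.where(Y > 1, (Y - dd) / np.maximum(Y - 1, 1), 0.0)
    var = (dd * hyper)[:, None] * frac * (1.0 - frac)
    num = np.abs((Ol - expected).sum(axis=0))
    den = var.sum(axis=0)
    return np.where(den > 0, num / np.sqrt(np.where(den > 0, den, 1.0)), 0.0)


def logrank_split_statistic(node_data: SurvivalDataset, j: int, c: float) -> float:
    """Absolute standardized two-sample log-rank statistic between the
    daughters x_j <= c and x_j > c."""
    left = node_data.covariates[:, j] <= c
    if not left.any() or left.all():
        raise ValueError("split leaves an empty daughter node")
    return float(_logrank_stats(node_data.times, node_data.events, left[:, None])[0])


@dataclass
class SurvivalTree:
    """Array-coded survival tree.

    ``feature[v] < 0`` marks node v as terminal; ``leaf_slot[v]`` then
    indexes its row in ``chf`` (terminal Nelson-Aalen CHFs on the forest
    grid).  ``mortality`` is the per-leaf CHF sum over the grid.
    """

    feature: np.ndarray
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    leaf_slot: np.ndarray
    chf: np.ndarray
    in_bag: np.ndarray
    used_features: frozenset

    @property
    def mortality(self) -> np.ndarray:
        return self.chf.sum(axis=1)

    def apply(self, X: np.ndarray) -> np.ndarray:
        """Leaf-slot index for every row of X (vectorized drop-down)."""
        node = np.zeros(X.shape[0], dtype=int)
        while True:
            internal = np.flatnonzero(self.feature[node] >= 0)
            if internal.size == 0:
                return self.leaf_slot[node]
            cur = node[internal]
            go_left = X[internal, self.feature[cur]] <= self.threshold[cur]
            node[internal] = np.where(go_left, self.left[cur], self.right[cur])

    def predict_chf(self, X: np.ndarray) -> np.ndarray:
        return self.chf[self.apply(X)]

    def predict_mortality(self, X: np.ndarray) -> np.ndarray:
        return self.mortality[self.apply(X)]


def grow_tree(data: SurvivalDataset, in_bag, config: ForestConfig,
              seed: int | np.random.Generator = 0,
              grid: np.ndarray | None = None) -> SurvivalTree:
    """Grow one unpruned survival tree on the in-bag cases.

    Splitting stops when a node has fewer than ``min_node_events`` distinct
    event times or no candidate split with a positive log-rank statistic.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    in_bag = np.asarray(in_bag, dtype=int)
    X = data.covariates[in_bag]
    t = data.times[in_bag]
    d = data.events[in_bag].astype(bool)
    if not d.any():
        raise ValueError("in-bag part contains no events")
    p = data.p
    mtry = config.mtry or max(1, int(round(np.sqrt(p))))
    if grid is None:
        grid = np.unique(data.times[data.events == 1])

    feature, threshold, left, right, leaf_slot = [], [], [], [], []
    chf_rows: list[np.ndarray] = []
    used: set[int] = set()

    def build(rows: np.ndarray) -> int:
        node = len(feature)
        feature.append(-1)
        threshold.append(np.nan)
        left.append(-1)
        right.append(-1)
        leaf_slot.append(-1)
        split = None
        if np.unique(t[rows][d[rows]]).size >= config.min_node_events:
            split = _search_split(rows)
        if split is None:
            leaf_slot[node] = len(chf_rows)
            chf_rows.append(nelson_aalen(t[rows], d[rows])(grid))
            return node
        j, c = split
        used.add(int(j))
        feature[node] = j
        threshold[node] = c
        go_left = X[rows, j] <= c
        left[node] = build(rows[go_left])
        right[node] = build(rows[~go_left])
        return node

    def _search_split(rows: np.ndarray):
        cand = rng.choice(p, size=min(mtry, p), replace=False)
        tt, dd_flag = t[rows], d[rows]
        s = np.unique(tt[dd_flag])
        if s.size == 0:
            return None
        # node-level risk/death bookkeeping, shared by all candidates
        R = (tt[:, None] >= s[None, :]).astype(float)
        D = (dd_flag[:, None] & (tt[:, None] == s[None, :])).astype(float)
        Y = R.sum(axis=0)
        dd = D.sum(axis=0)
        hyper = np.where(Y > 1, (Y - dd) / np.maximum(Y - 1, 1), 0.0)
        best_stat, best = 0.0, None
        for j in cand:
            v = X[rows, j]
            u = np.unique(v)
            if u.size < 2:
                continue
            cuts = (u[:-1] + u[1:]) / 2.0
            L = (v[:, None] <= cuts[None, :]).astype(float)
            frac = (R.T @ L) / Y[:, None]
            num = np.abs((D.T @ L - dd[:, None] * frac).sum(axis=0))
            den = ((dd * hyper)[:, None] * frac * (1.0 - frac)).sum(axis=0)
            stats = np.where(den > 0, num / np.sqrt(np.where(den > 0, den, 1.0)), 0.0)
            k = int(np.argmax(stats))
            if stats[k] > best_stat:
                best_stat, best = float(stats[k]), (int(j), float(cuts[k]))
        return best

    build(np.arange(in_bag.size))
    return SurvivalTree(
        np.asarray(feature), np.asarray(threshold), np.asarray(left),
        np.asarray(right), np.asarray(leaf_slot),
        np.vstack(chf_rows), in_bag, frozenset(used),
    )


class SurvivalForestModel:
    """Random survival forest model for a :class:`SurvivalDataset`.

    ``fit()`` grows ``ntree`` trees on independent 0.632 without-replacement
    resamples and returns a :class:`SurvivalForestResults`.
    """

    def __init__(self, data: SurvivalDataset, config: ForestConfig | None = None, **kw):
        if config is None:
            config = ForestConfig(**kw)
        elif kw:
            config = ForestConfig(**{**config.__dict__, **kw})
        if config.mtry is not None and config.mtry > data.p:
            raise ValueError("mtry cannot exceed the number of covariates")
        self.data = data
        self.config = config
        self.grid = np.unique(data.times[data.events == 1])

    def fit(self) -> "SurvivalForestResults":
        cfg = self.config
        root = np.random.SeedSequence(cfg.seed)
        trees = []
        for ss in root.spawn(cfg.ntree):
            rng = np.random.default_rng(ss)
            split = subsample(self.data, cfg.resample_fraction, seed=rng)
            trees.append(grow_tree(self.data, split.train_idx, cfg,
                                   seed=rng, grid=self.grid))
        return SurvivalForestResults(self, trees)


class SurvivalForestResults:
    """Fitted forest: ensemble predictions, OOB error and importance."""

    def __init__(self, model: SurvivalForestModel, trees: list[SurvivalTree]):
        self.model = model
        self.trees = trees
        data = model.data
        n = data.n
        self.oob_mask = np.ones((len(trees), n), dtype=bool)
        for b, tree in enumerate(trees):
            self.oob_mask[b, tree.in_bag] = False
        # per-tree mortality of every training case (used for OOB error/PAM)
        self._train_mort = np.vstack(
            [tree.predict_mortality(data.covariates) for tree in trees])

    # -- ensemble predictions --------------------------------------------
    def ensemble_chf(self, X) -> np.ndarray:
        """Mean terminal CHF over trees, on the forest grid; (m, G)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        acc = np.zeros((X.shape[0], self.model.grid.size))
        for tree in self.trees:
            acc += tree.predict_chf(X)
        return acc / len(self.trees)

    def ensemble_mortality(self, X) -> np.ndarray:
        """Predicted risk: ensemble CHF summed over the forest grid."""
        return self.ensemble_chf(X).sum(axis=1)

    def oob_mortality(self, train_mort: np.ndarray | None = None) -> np.ndarray:
        """OOB ensemble mortality of every training case (NaN if a case was
        in-bag for every tree)."""
        M = self._train_mort if train_mort is None else train_mort
        counts = self.oob_mask.sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(counts > 0,
                            (M * self.oob_mask).sum(axis=0) / counts, np.nan)

    def case_mortality(self, i: int, oob_only: bool = False) -> float:
        """Ensemble mortality of training case i (OOB trees only on request)."""
        if not oob_only:
            return float(self._train_mort[:, i].mean())
        sel = self.oob_mask[:, i]
        if not sel.any():
            raise ValueError(f"case {i} is in-bag for every tree; OOB mortality undefined")
        return float(self._train_mort[sel, i].mean())

    # -- error and importance --------------------------------------------
    def _oob_error(self, train_mort: np.ndarray | None = None) -> float:
        mort = self.oob_mortality(train_mort)
        ok = ~np.isnan(mort)
        data = self.model.data
        return 1.0 - harrell_c(mort[ok], data.times[ok], data.events[ok])

    def oob_concordance(self) -> float:
        return 1.0 - self._oob_error()

    def permutation_importance(self, j: int | None = None, seed: int = 0):
        """PAM of covariate j (or a per-covariate table for all j).

        Only trees that split on j need re-dropping; for unused covariates
        the importance is exactly 0 without computation.
        """
        if j is None:
            vals = np.array([self.permutation_importance(k, seed=seed)
                             for k in range(self.model.data.p)])
            return pd.Series(vals, index=list(self.model.data.names), name="pam")
        base_err = self._base_err_cached()
        affected = [b for b, tree in enumerate(self.trees) if j in tree.used_features]
        if not affected:
            return 0.0
        data = self.model.data
        rng = np.random.default_rng(np.random.SeedSequence((seed, j)))
        Xp = data.covariates.copy()
        Xp[:, j] = Xp[rng.permutation(data.n), j]
        M = self._train_mort.copy()
        for b in affected:
            M[b] = self.trees[b].predict_mortality(Xp)
        return self._oob_error(M) - base_err

    def _base_err_cached(self) -> float:
        if not hasattr(self, "_base_err"):
            self._base_err = self._oob_error()
        return self._base_err


def fit_forest(data: SurvivalDataset, config: ForestConfig | None = None,
               **kw) -> SurvivalForestResults:
    """Fit a random survival forest (functional wrapper)."""
    return SurvivalForestModel(data, config, **kw).fit()


def harrell_c(risk_scores, times, events) -> float:
    """Harrell's concordance index of a risk score.

    Usable pairs: t_i < t_j with delta_i = 1, or t_i = t_j with exactly one
    event (the event is taken as first).  A pair is concordant when the
    earlier failure has the higher risk score; score ties count 1/2.
    """
    r = np.asarray(risk_scores, dtype=float)
    t = np.asarray(times, dtype=float)
    d = np.asarray(events).astype(bool)
    earlier = (t[:, None] < t[None, :]) & d[:, None]
    tied_time = (t[:, None] == t[None, :]) & d[:, None] & ~d[None, :]
    usable = earlier | tied_time
    n_usable = usable.sum()
    if n_usable == 0:
        raise ValueError("no usable pairs for the concordance index")
    conc = (r[:, None] > r[None, :]) & usable
    tied_r = (r[:, None] == r[None, :]) & usable
    return float((conc.sum() + 0.5 * tied_r.sum()) / n_usable)


def permutation_importance(forest: SurvivalForestResults, data: SurvivalDataset,
                           j: int, seed: int = 0) -> float:
    """Functional wrapper for :meth:`SurvivalForestResults.permutation_importance`."""
    if data is not forest.model.data:
        raise ValueError("importance is defined on the forest's training data")
    return forest.permutation_importance(j, seed=seed)
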