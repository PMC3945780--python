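"""Interaction-detection strategies for high-dimensional survival data.

The pipeline screens candidate two-way interactions (products of covariate
pairs) before offering them to a sparse Cox boosting fit:

1. Split the data 0.632/0.368 into a training part Z_b and a holdout Z'_b.
2. (a) *Main-effect detection*: run Cox boosting with cross-validated step
   count on Z_b; the covariates with nonzero coefficients form the index
   set M (clinical covariates K are always unpenalized).
   (b) *Pre-selection of interaction terms*, one of four variants:
     - ``rsf-VIF-res``: regress every covariate outside M u K on the
       anchors in M u K and keep the residuals (orthogonalization unmasks
       interaction signal hidden behind main effects); then draw S inner
       0.632 subsamples, fit a random survival forest on each, and pair up
       all covariates with positive permutation importance.  Pairs are
       counted across subsamples (variable inclusion frequencies, VIFs)
       and the R most frequent kept.
     - ``rsf-VIF``: the same without orthogonalization.
     - ``cb-VIF``: Cox boosting instead of forests on the S subsamples;
       per-variable VIFs; pairs ranked by min(VIF_a, VIF_b).
     - ``cb-crossp``: no subsampling; all distinct products of the detected
       main effects (a random R-subset if there are too many).
   (c) *Final model*: Cox boosting (CV step count) on Z_b over the
   covariates in K and M plus the pre-selected product terms, built from
   the original (non-residualized) covariate values.
   (d) *Evaluation*: IPCW Brier curve of the final model on Z'_b, with the
   integrated error reported relative to the Kaplan-Meier reference.

Ties at the R-th pre-selection rank are resolved by including every pair
with the tied inclusion frequency.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .coxboost import BoostConfig, CoxBoost, CoxBoostResults
from .data import SurvivalDataset, subsample
from .evaluation import (PredictionErrorCurve, brier_curve, censoring_survival,
                         evaluation_grid, ipec, kaplan_meier, km_event_prob, ripec)
from .forest import ForestConfig, SurvivalForestModel

logger = logging.getLogger(__name__)

__all__ = [
    "STRATEGIES",
    "StrategyConfig",
    "VIFTable",
    "StrategyResult",
    "InteractionScreen",
    "detect_main_effects",
    "orthogonalize",
    "preselect_rsf",
    "preselect_cb_vif",
    "preselect_cb_crossp",
    "run_strategy",
]

STRATEGIES = ("rsf-VIF-res", "rsf-VIF", "cb-VIF", "cb-crossp")


@dataclass(frozen=True)
class StrategyConfig:
    """Configuration of one screening pipeline run.

    ``S`` inner subsamples and ``R`` retained interaction terms default to
    50 and 10000.  ``boost`` and ``forest``
    carry the tuning of the embedded Cox boosting and forest fits.
    """

    name: str = "rsf-VIF-res"
    S: int = 50
    R: int = 10000
    mandatory: tuple[int, ...] = ()
    boost: BoostConfig = field(default_factory=BoostConfig)
    forest: ForestConfig = field(default_factory=ForestConfig)

    def __post_init__(self):
        if self.name not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.name!r}; valid: {STRATEGIES}")
        if self.S < 1 or self.R < 1:
            raise ValueError("S and R must be >= 1")


@dataclass(frozen=True)
class VIFTable:
    """Inclusion counts of terms (interaction pairs or single variables)
    across S inner subsamples."""

    counts: dict
    S: int

    def relative(self, term) -> float:
        return self.counts.get(term, 0) / self.S


@dataclass
class StrategyResult:
    """Everything one strategy run produces.

    ``preselected`` are (a, b) covariate-index pairs with a < b;
    ``candidate_terms`` maps the final model's covariate columns back to
    either ("main", index) or ("pair", (a, b)).
    """

    config: StrategyConfig
    train_idx: np.ndarray
    test_idx: np.ndarray
    main_results: CoxBoostResults
    main_effects: tuple[int, ...]
    preselected: list[tuple[int, int]]
    vif: VIFTable
    final_results: CoxBoostResults | None
    candidate_terms: list[tuple]
    brier_final: PredictionErrorCurve
    brier_main: PredictionErrorCurve
    brier_km: PredictionErrorCurve
    ripec_main: float
    ripec_final: float

    @property
    def int_screen(self) -> int:
        """Number of pre-selected interaction terms (the IntScreen count)."""
        return len(self.preselected)

    def final_nonzero_terms(self) -> list[tuple]:
        """Terms with nonzero coefficient in the final model."""
        if self.final_results is None:
            return []
        return [self.candidate_terms[j] for j in self.final_results.selected]


def detect_main_effects(train: SurvivalDataset, config: StrategyConfig,
                        seed: int = 0) -> tuple[CoxBoostResults, tuple[int, ...]]:
    """First-pass Cox boosting with CV-selected step count; returns the
    fitted model and the selected main-effect indices M (excluding the
    mandatory set, which is reported separately via the config)."""
    boost = replace(config.boost, unpenalized=config.mandatory)
    results = CoxBoost(train, boost).fit_cv(seed=seed)
    M = tuple(int(j) for j in results.selected if j not in config.mandatory)
    return results, M


def orthogonalize(train: SurvivalDataset, anchor) -> SurvivalDataset:
    """Replace every non-anchor covariate by its least-squares residual from
    a regression (with intercept) on the anchor columns.

    With an empty anchor set the data is returned unchanged.  Rank-deficient
    anchor designs are handled by the minimum-norm solution; the residuals
    remain orthogonal to the anchor span.
    """
    anchor = sorted(int(a) for a in anchor)
    if not anchor:
        return train
    X = train.covariates
    n = X.shape[0]
    if len(anchor) >= n:
        raise ValueError("anchor set must be smaller than the sample size")
    design = np.column_stack([np.ones(n), X[:, anchor]])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        logger.warning("anchor design is rank deficient (%d < %d); using the "
                       "minimum-norm regression", rank, design.shape[1])
    others = [j for j in range(train.p) if j not in anchor]
    coef, *_ = np.linalg.lstsq(design, X[:, others], rcond=None)
    out = X.copy()
    out[:, others] = X[:, others] - design @ coef
    return train.with_covariates(out)


def _top_r_by_count(counts: dict, R: int) -> list:
    """Terms sorted by count (desc) then index; the R-th rank's ties are all
    included."""
    ranked = sorted(counts, key=lambda term: (-counts[term], term))
    if len(ranked) <= R:
        return ranked
    cutoff = counts[ranked[R - 1]]
    return [term for term in ranked if counts[term] >= cutoff]


def preselect_rsf(train: SurvivalDataset, config: StrategyConfig,
                  seed: int = 0, orthogonalized: bool = True,
                  anchor=()) -> tuple[list[tuple[int, int]], VIFTable]:
    """Forest-based pre-selection (strategies rsf-VIF-res / rsf-VIF).

    For each of S inner 0.632 subsamples a survival forest is fit (on the
    residualized matrix when ``orthogonalized``) and every unordered pair of
    covariates with positive permutation importance is counted; the R most
    frequent pairs are returned (rank-R ties included).
    """
    work = orthogonalize(train, anchor) if orthogonalized else train
    root = np.random.SeedSequence((seed, 101))
    counts: dict[tuple[int, int], int] = {}
    for s, ss in enumerate(root.spawn(config.S)):
        rng = np.random.default_rng(ss)
        inner = subsample(work, 0.632, seed=rng)
        sub = work.subset(inner.train_idx)
        fcfg = replace(config.forest, seed=int(ss.generate_state(1)[0] % 2**31))
        forest = SurvivalForestModel(sub, fcfg).fit()
        pam = forest.permutation_importance(seed=fcfg.seed).to_numpy()
        positive = np.flatnonzero(pam > 0)
        if positive.size < 2:
            logger.info("inner subsample %d: fewer than two covariates with "
                        "positive importance; no pairs contributed", s)
            continue
        for pair in itertools.combinations(positive.tolist(), 2):
            counts[pair] = counts.get(pair, 0) + 1
    table = VIFTable(counts, config.S)
    return _top_r_by_count(counts, config.R), table


def preselect_cb_vif(train: SurvivalDataset, config: StrategyConfig,
                     seed: int = 0) -> tuple[list[tuple[int, int]], VIFTable]:
    """Boosting-based pre-selection (strategy cb-VIF).

    Per-variable VIFs are the selection frequencies of Cox boosting across S
    inner subsamples; pairs of ever-selected variables are ranked by
    min(VIF_a, VIF_b), ties broken by VIF_a + VIF_b then index order, with
    the rank-R tie-inclusion rule on the ranking value.
    """
    root = np.random.SeedSequence((seed, 202))
    var_counts: dict[int, int] = {}
    boost = replace(config.boost, unpenalized=config.mandatory)
    for s, ss in enumerate(root.spawn(config.S)):
        rng = np.random.default_rng(ss)
        inner = subsample(train, 0.632, seed=rng)
        sub = train.subset(inner.train_idx)
        res = CoxBoost(sub, boost).fit_cv(seed=int(ss.generate_state(1)[0] % 2**31))
        chosen = [int(j) for j in res.selected if j not in config.mandatory]
        if not chosen:
            logger.info("inner subsample %d: boosting selected no variables", s)
        for j in chosen:
            var_counts[j] = var_counts.get(j, 0) + 1
    table = VIFTable(var_counts, config.S)
    variables = sorted(var_counts)
    pairs = list(itertools.combinations(variables, 2))
    if not pairs:
        return [], table

    def key(pair):
        va, vb = var_counts[pair[0]], var_counts[pair[1]]
        return (min(va, vb), va + vb)

    ranked = sorted(pairs, key=lambda pr: (-key(pr)[0], -key(pr)[1], pr))
    if len(ranked) <= config.R:
        return ranked, table
    cutoff = key(ranked[config.R - 1])
    return [pr for pr in ranked if key(pr) >= cutoff], table


def preselect_cb_crossp(train: SurvivalDataset, M, K=(), R: int = 10000,
                        seed: int = 0) -> list[tuple[int, int]]:
    """Cross products of the detected main effects (strategy cb-crossp):
    all C(|M|, 2) pairs, or a seeded uniform subset of R if there are more."""
    M = sorted(int(j) for j in M)
    pairs = list(itertools.combinations(M, 2))
    if len(pairs) <= R:
        return pairs
    rng = np.random.default_rng(np.random.SeedSequence((seed, 303)))
    keep = rng.choice(len(pairs), size=R, replace=False)
    return [pairs[i] for i in sorted(keep)]


def _build_candidates(train: SurvivalDataset, K, M,
                      pairs) -> tuple[SurvivalDataset | None, list[tuple]]:
    """Candidate matrix of the final model: original K and M columns plus
    one product column per pre-selected pair (products of the original,
    non-residualized covariate values)."""
    X = train.covariates
    cols, terms, names = [], [], []
    for k in sorted(K):
        cols.append(X[:, k])
        terms.append(("main", int(k)))
        names.append(train.names[k])
    for m in sorted(M):
        cols.append(X[:, m])
        terms.append(("main", int(m)))
        names.append(train.names[m])
    for a, b in pairs:
        cols.append(X[:, a] * X[:, b])
        terms.append(("pair", (int(a), int(b))))
        names.append(f"{train.names[a]}:{train.names[b]}")
    if not cols:
        return None, []
    cand = SurvivalDataset(train.times, train.events, np.column_stack(cols),
                           names=tuple(names),
                           mandatory=tuple(range(len(K))))
    return cand, terms


def run_strategy(data: SurvivalDataset, config: StrategyConfig,
                 outer_seed: int = 0) -> StrategyResult:
    """Run one full screening pipeline on one outer 0.632 split.

    Every stochastic step derives its seed deterministically from
    ``outer_seed``; two calls with the same seed are bit-identical.
    Replication across datasets or outer splits is the caller's job.
    """
    root = np.random.SeedSequence(outer_seed)
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in root.spawn(5)]
    s_split, s_cv_main, s_inner, s_cv_final, s_crossp = seeds
    split = subsample(data, 0.632, seed=s_split)
    train, test = data.subset(split.train_idx), data.subset(split.test_idx)
    K = config.mandatory

    main_results, M = detect_main_effects(train, config, seed=s_cv_main)

    vif = VIFTable({}, config.S)
    if config.name == "rsf-VIF-res":
        pairs, vif = preselect_rsf(train, config, seed=s_inner,
                                   orthogonalized=True, anchor=set(M) | set(K))
    elif config.name == "rsf-VIF":
        pairs, vif = preselect_rsf(train, config, seed=s_inner, orthogonalized=False)
    elif config.name == "cb-VIF":
        pairs, vif = preselect_cb_vif(train, config, seed=s_inner)
    else:  # cb-crossp
        pairs = preselect_cb_crossp(train, M, K, config.R, seed=s_crossp)

    cand, terms = _build_candidates(train, K, M, pairs)
    if cand is None:
        final_results = None
        final_prob = km_event_prob(kaplan_meier(train.times, train.events))
    else:
        boost = replace(config.boost, unpenalized=cand.mandatory)
        final_results = CoxBoost(cand, boost).fit_cv(seed=s_cv_final)

        def final_prob(t, X, _res=final_results, _terms=terms, _tr=train):
            Xc = _candidate_rows(X, _terms)
            return _res.predict_event_probability(Xc, t)

    cens = censoring_survival(train.times, train.events)
    grid = evaluation_grid(test, cens)
    km = kaplan_meier(train.times, train.events)

    def main_prob(t, X, _res=main_results):
        return _res.predict_event_probability(X, t)

    b_final = brier_curve(final_prob, test, cens, grid)
    b_main = brier_curve(main_prob, test, cens, grid)
    b_km = brier_curve(km_event_prob(km), test, cens, grid)
    ipec_km = ipec(b_km)
    return StrategyResult(
        config=config, train_idx=split.train_idx, test_idx=split.test_idx,
        main_results=main_results, main_effects=M, preselected=list(pairs),
        vif=vif, final_results=final_results,
        candidate_terms=terms, brier_final=b_final, brier_main=b_main,
        brier_km=b_km,
        ripec_main=ripec(ipec(b_main), ipec_km),
        ripec_final=ripec(ipec(b_final), ipec_km),
    )


def _candidate_rows(X, terms) -> np.ndarray:
    """Map original-covariate rows onto the final model's candidate columns."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    cols = []
    for kind, what in terms:
        if kind == "main":
            cols.append(X[:, what])
        else:
            a, b = what
            cols.append(X[:, a] * X[:, b])
    return np.column_stack(cols)


class InteractionScreen:
    """Model-style wrapper around :func:`run_strategy`.

    >>> screen = InteractionScreen(data, strategy="rsf-VIF-res", S=50, R=10000)
    >>> result = screen.fit(seed=1)
    """

    def __init__(self, data: SurvivalDataset, strategy: str = "rsf-VIF-res",
                 S: int = 50, R: int = 10000, mandatory=None,
                 boost: BoostConfig | None = None,
                 forest: ForestConfig | None = None):
        self.data = data
        self.config = StrategyConfig(
            name=strategy, S=S, R=R,
            mandatory=tuple(mandatory) if mandatory is not None else data.mandatory,
            boost=boost or BoostConfig(),
            forest=forest or ForestConfig(),
        )

    def fit(self, seed: int = 0) -> StrategyResult:
        return run_strategy(self.data, self.config, outer_seed=seed)
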