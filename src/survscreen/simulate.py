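"""Survival-data simulator and the performance metrics of the screening
study.

Scenarios mimic a microarray study: n = 150 subjects, p = 1000 covariates
drawn from a standard normal (optionally Bernoulli(1/2) for selected
variables, or block-correlated 5-variate normals with a uniform off-diagonal
correlation).  The log hazard is linear,

    eta_i = sum_m beta_m x_im + sum_{(a,b)} gamma_ab x_ia x_ib,

and event times are exponential with rate lambda * exp(eta_i) for baseline
hazard lambda = 1/20; censoring times are independent Exponential(lambda),
which yields roughly 50% censoring at eta = 0.  ``Sim42`` has four strong
main effects whose variables also form the two interactions; the ``Sim22_*``
family has two moderate main effects and two interactions built from
variables with *zero* main effect -- the hard case the screening strategies
are designed for.

``score_replicates`` turns strategy outputs into the benchmark metrics:
IntScreen (pre-selected term count), IntSensiA (true interactions available
after screening), MainSensi / IntSensi (true terms with nonzero final
coefficients), VarsTotal and the rIPEC values, each with its standard error
across replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .data import SurvivalDataset
from .screening import StrategyResult

__all__ = [
    "ScenarioSpec",
    "SimulatedDataset",
    "MetricsRow",
    "builtin_scenarios",
    "get_scenario",
    "generate_dataset",
    "score_replicates",
    "run_replicates",
]


@dataclass(frozen=True)
class ScenarioSpec:
    """One simulation scenario: effect placement, sizes and covariate law."""

    name: str
    n: int = 150
    p: int = 1000
    main_effects: tuple[tuple[int, float], ...] = ()
    interactions: tuple[tuple[tuple[int, int], float], ...] = ()
    corr: float = 0.0
    block_size: int = 5
    binary_vars: tuple[int, ...] = ()
    base_rate: float = 1.0 / 20.0

    def __post_init__(self):
        idx = [i for i, _ in self.main_effects]
        idx += [i for (a, b), _ in self.interactions for i in (a, b)]
        if any(i >= self.p or i < 0 for i in idx):
            raise ValueError("effect indices must lie within 1..p")
        if self.corr and self.p % self.block_size:
            raise ValueError("p must be a multiple of the block size")

    def scaled(self, n: int | None = None, p: int | None = None) -> "ScenarioSpec":
        """Same effects, reduced dimension (for desk-scale runs)."""
        return replace(self, n=n or self.n, p=p or self.p)

    @property
    def true_mains(self) -> tuple[int, ...]:
        return tuple(i for i, _ in self.main_effects)

    @property
    def true_pairs(self) -> tuple[tuple[int, int], ...]:
        return tuple(tuple(sorted(pr)) for pr, _ in self.interactions)


@dataclass(frozen=True)
class SimulatedDataset:
    """A generated dataset plus its ground truth."""

    data: SurvivalDataset
    spec: ScenarioSpec
    linear_predictor: np.ndarray
    seed: int

    @property
    def true_mains(self):
        return self.spec.true_mains

    @property
    def true_pairs(self):
        return self.spec.true_pairs


def builtin_scenarios() -> list[ScenarioSpec]:
    """The twelve study scenarios.

    Sim42: main effects (3, 3, -3, -3) on the first four covariates and
    interactions (5, -5) on the pairs of those same variables.  Sim22_x:
    main effects (0.9, -0.9) and interactions (x, -x) on four further
    variables that carry no main effect (Bernoulli(1/2)-coded for the
    ``bin`` variant).  Sim22_corrXX: the Sim22_1.0 effects on
    block-correlated covariates (200 blocks of 5, uniform correlation c),
    every true variable heading a distinct block.
    """
    out = [ScenarioSpec(
        "Sim42",
        main_effects=((0, 3.0), (1, 3.0), (2, -3.0), (3, -3.0)),
        interactions=(((0, 1), 5.0), ((2, 3), -5.0)),
    )]
    for x in (1.0, 0.5, 0.25, 1.5, 2.0, 2.5):
        out.append(ScenarioSpec(
            f"Sim22_{x}",
            main_effects=((0, 0.9), (1, -0.9)),
            interactions=(((2, 3), x), ((4, 5), -x)),
        ))
    out.append(ScenarioSpec(
        "Sim22_bin",
        main_effects=((0, 0.9), (1, -0.9)),
        interactions=(((2, 3), 1.0), ((4, 5), -1.0)),
        binary_vars=(2, 3, 4, 5),
    ))
    for c in (0.1, 0.3, 0.5, 0.7):
        out.append(ScenarioSpec(
            f"Sim22_corr{str(c).replace('0.', '0')}",
            main_effects=((0, 0.9), (5, -0.9)),
            interactions=(((10, 15), 1.0), ((20, 25), -1.0)),
            corr=c,
        ))
    return out


def get_scenario(name: str) -> ScenarioSpec:
    for spec in builtin_scenarios():
        if spec.name == name:
            return spec
    valid = ", ".join(s.name for s in builtin_scenarios())
    raise KeyError(f"unknown scenario {name!r}; valid: {valid}")


def generate_dataset(spec: ScenarioSpec, seed: int = 0) -> SimulatedDataset:
    """Generate one dataset: covariates, linear predictor, exponential event
    and censoring times.  Bit-identical for a given seed."""
    rng = np.random.default_rng(seed)
    n, p = spec.n, spec.p
    if spec.corr > 0:
        nblock = p // spec.block_size
        sigma = np.full((spec.block_size, spec.block_size), spec.corr)
        np.fill_diagonal(sigma, 1.0)
        L = np.linalg.cholesky(sigma)
        Z = rng.standard_normal((n, nblock, spec.block_size))
        X = (Z @ L.T).reshape(n, p)
    else:
        X = rng.standard_normal((n, p))
    for j in spec.binary_vars:
        X[:, j] = rng.binomial(1, 0.5, size=n)
    eta = np.zeros(n)
    for i, beta in spec.main_effects:
        eta += beta * X[:, i]
    for (a, b), gamma in spec.interactions:
        eta += gamma * X[:, a] * X[:, b]
    lam = spec.base_rate
    T = rng.exponential(1.0, size=n) / (lam * np.exp(eta))
    C = rng.exponential(scale=1.0 / lam, size=n)
    times = np.minimum(T, C)
    events = (T <= C).astype(int)
    data = SurvivalDataset(times, events, X)
    return SimulatedDataset(data, spec, eta, seed)


def run_replicates(scenario: str, strategy_config, n_replicates: int,
                   seed: int = 0, p: int | None = None, n: int | None = None):
    """Generate ``n_replicates`` datasets of a scenario and run one strategy
    on each (one outer 0.632 subsample per dataset).

    Returns ``(results, sims)``; feed them to :func:`score_replicates`.
    Dataset and outer-split seeds all derive from ``seed``.
    """
    spec = get_scenario(scenario).scaled(n=n, p=p)
    seeds = [int(s.generate_state(1)[0] % 2**31)
             for s in np.random.SeedSequence(seed).spawn(n_replicates)]
    sims = [generate_dataset(spec, seed=s) for s in seeds]
    from .screening import run_strategy
    results = [run_strategy(sim.data, strategy_config, outer_seed=s)
               for sim, s in zip(sims, seeds)]
    return results, sims


@dataclass(frozen=True)
class MetricsRow:
    """Mean (and standard error across replicates) of the benchmark metrics."""

    strategy: str
    scenario: str
    n_replicates: int
    int_screen: float
    int_sensi_a: tuple[float, float]
    vars_total: tuple[float, float]
    main_sensi: tuple[float, float]
    int_sensi: tuple[float, float]
    ripec_main: tuple[float, float]
    ripec_final: tuple[float, float]

    def to_frame(self) -> pd.DataFrame:
        def fmt(ms):
            return f"{ms[0]:.3g} ({ms[1]:.2g})"
        return pd.DataFrame({
            "IntScreen": [f"{self.int_screen:.4g}"],
            "IntSensiA": [fmt(self.int_sensi_a)],
            "VarsTotal": [fmt(self.vars_total)],
            "MainSensi": [fmt(self.main_sensi)],
            "IntSensi": [fmt(self.int_sensi)],
            "rIPEC CoxBoostM": [fmt(self.ripec_main)],
            "rIPEC Final": [fmt(self.ripec_final)],
        }, index=[f"{self.scenario} ({self.strategy})"])


def _mean_se(values) -> tuple[float, float]:
    v = np.asarray(values, dtype=float)
    se = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0
    return float(v.mean()), se


def score_replicates(results: list[StrategyResult],
                     truths: list[SimulatedDataset]) -> MetricsRow:
    """Aggregate strategy runs on replicate datasets into a metrics row."""
    if not results:
        raise ValueError("no results to score")
    if len(results) != len(truths):
        raise ValueError("results and ground truths must be aligned")
    main_s, int_s, int_sa, vars_t, r_main, r_final, screens = [], [], [], [], [], [], []
    for res, truth in zip(results, truths):
        mains = truth.true_mains
        pairs = [tuple(sorted(pr)) for pr in truth.true_pairs]
        nz = res.final_nonzero_terms()
        nz_mains = {what for kind, what in nz if kind == "main"}
        nz_pairs = {tuple(sorted(what)) for kind, what in nz if kind == "pair"}
        pre = {tuple(sorted(pr)) for pr in res.preselected}
        main_s.append(np.mean([m in nz_mains for m in mains]) if mains else 1.0)
        int_s.append(np.mean([pr in nz_pairs for pr in pairs]) if pairs else 1.0)
        int_sa.append(np.mean([pr in pre for pr in pairs]) if pairs else 1.0)
        vars_t.append(len(nz))
        screens.append(res.int_screen)
        r_main.append(res.ripec_main)
        r_final.append(res.ripec_final)
    return MetricsRow(
        strategy=results[0].config.name,
        scenario=truths[0].spec.name,
        n_replicates=len(results),
        int_screen=float(np.mean(screens)),
        int_sensi_a=_mean_se(int_sa),
        vars_total=_mean_se(vars_t),
        main_sensi=_mean_se(main_s),
        int_sensi=_mean_se(int_s),
        ripec_main=_mean_se(r_main),
        ripec_final=_mean_se(r_final),
    )
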