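"""Core survival-data containers, delimited-file I/O, standardization and
0.632 subsampling.

A right-censored sample is the set of triples ``(t_i, delta_i, x_i)``:
observed time, event indicator (1 = event, 0 = censored) and the baseline
covariate vector.  :class:`SurvivalDataset` is the container every other
module consumes.  Clinical covariates that must enter models unpenalized
are tracked by index in ``mandatory``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SurvivalDataset",
    "SubsampleSplit",
    "StandardizationParams",
    "SurvivalDataError",
    "MissingColumnError",
    "InvalidEventError",
    "InvalidTimeError",
    "MissingValueError",
    "NoEventsError",
    "read_dataset",
    "write_dataset",
    "subsample",
    "standardize",
]


class SurvivalDataError(ValueError):
    """Base class for survival-data validation failures."""


class MissingColumnError(SurvivalDataError):
    """A required column label is absent from the input table."""


class InvalidEventError(SurvivalDataError):
    """Event indicators contain values other than 0 and 1."""


class InvalidTimeError(SurvivalDataError):
    """Observed times are non-positive or non-finite."""


class MissingValueError(SurvivalDataError):
    """Covariate matrix contains missing values."""


class NoEventsError(SurvivalDataError):
    """An operation that needs at least one event got none."""


@dataclass(frozen=True)
class SurvivalDataset:
    """Right-censored survival data: times, event indicators, covariates.

    Parameters
    ----------
    times : (n,) array of positive observed times.
    events : (n,) array of 0/1 event indicators.
    covariates : (n, p) covariate matrix, no missing values.
    names : length-p covariate labels (generated if omitted).
    mandatory : indices of unpenalized (clinical) covariates.
    """

    times: np.ndarray
    events: np.ndarray
    covariates: np.ndarray
    names: tuple[str, ...] = ()
    mandatory: tuple[int, ...] = ()

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        events = np.asarray(self.events, dtype=float)
        X = np.asarray(self.covariates, dtype=float)
        if X.ndim != 2:
            raise SurvivalDataError("covariates must be a 2-d matrix")
        n, p = X.shape
        if times.shape != (n,) or events.shape != (n,):
            raise SurvivalDataError("times/events length must match covariate rows")
        if n < 2:
            raise SurvivalDataError("need at least 2 observations")
        if not np.all(np.isfinite(times)) or np.any(times <= 0):
            raise InvalidTimeError("observed times must be strictly positive and finite")
        if not np.isin(events, (0.0, 1.0)).all():
            raise InvalidEventError("event indicators must be 0 or 1")
        if events.sum() < 1:
            raise NoEventsError("dataset contains no events")
        if not np.all(np.isfinite(X)):
            raise MissingValueError("covariates contain missing or non-finite values")
        names = tuple(self.names) if self.names else tuple(f"x{j + 1}" for j in range(p))
        if len(names) != p:
            raise SurvivalDataError("number of names must equal number of covariates")
        mandatory = tuple(int(k) for k in self.mandatory)
        if any(k < 0 or k >= p for k in mandatory):
            raise SurvivalDataError("mandatory indices out of range")
        events = events.astype(np.int8)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "events", events)
        object.__setattr__(self, "covariates", X)
        object.__setattr__(self, "names", names)
        object.__setattr__(self, "mandatory", mandatory)

    @property
    def n(self) -> int:
        return self.covariates.shape[0]

    @property
    def p(self) -> int:
        return self.covariates.shape[1]

    @property
    def n_events(self) -> int:
        return int(self.events.sum())

    def subset(self, idx) -> "SurvivalDataset":
        """Row subset (same covariate columns and mandatory set)."""
        idx = np.asarray(idx, dtype=int)
        return SurvivalDataset(
            self.times[idx], self.events[idx], self.covariates[idx],
            names=self.names, mandatory=self.mandatory,
        )

    def with_covariates(self, X, names=None) -> "SurvivalDataset":
        """Same rows, replaced covariate matrix (used by orthogonalization)."""
        return SurvivalDataset(
            self.times, self.events, np.asarray(X, dtype=float),
            names=tuple(names) if names is not None else self.names,
            mandatory=self.mandatory,
        )

    def to_frame(self, time_col: str = "time", event_col: str = "status") -> pd.DataFrame:
        df = pd.DataFrame(self.covariates, columns=list(self.names))
        df.insert(0, event_col, self.events.astype(int))
        df.insert(0, time_col, self.times)
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, time_col: str = "time",
                       event_col: str = "status",
                       mandatory_cols: tuple[str, ...] = ()) -> "SurvivalDataset":
        for col in (time_col, event_col, *mandatory_cols):
            if col not in df.columns:
                raise MissingColumnError(f"column {col!r} not found in table")
        cov_cols = [c for c in df.columns if c not in (time_col, event_col)]
        X = df[cov_cols].to_numpy(dtype=float, na_value=np.nan)
        if np.isnan(X).any():
            raise MissingValueError("covariates contain missing values")
        mandatory = tuple(cov_cols.index(c) for c in mandatory_cols)
        return cls(df[time_col].to_numpy(float), df[event_col].to_numpy(float),
                   X, names=tuple(cov_cols), mandatory=mandatory)


@dataclass(frozen=True)
class SubsampleSplit:
    """A without-replacement train/test split of row indices."""

    train_idx: np.ndarray
    test_idx: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "train_idx", np.asarray(self.train_idx, dtype=int))
        object.__setattr__(self, "test_idx", np.asarray(self.test_idx, dtype=int))


@dataclass(frozen=True)
class StandardizationParams:
    """Column means and scales used to standardize a covariate matrix."""

    means: np.ndarray
    scales: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.means) / self.scales

    def inverse(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) * self.scales + self.means


def _delimiter_for(path: str) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_dataset(path, time_col: str = "time", event_col: str = "status",
                 mandatory_cols: tuple[str, ...] = ()) -> SurvivalDataset:
    """Read a delimited survival table (CSV or TSV by extension, header row
    mandatory) into a :class:`SurvivalDataset`.

    All columns other than ``time_col`` and ``event_col`` are covariates, in
    file order.  ``mandatory_cols`` flags clinical covariates by name.
    """
    df = pd.read_csv(path, sep=_delimiter_for(path), float_precision="round_trip")
    return SurvivalDataset.from_dataframe(df, time_col, event_col, mandatory_cols)


def write_dataset(data: SurvivalDataset, path, time_col: str = "time",
                  event_col: str = "status") -> None:
    """Write a dataset as delimited text (CSV or TSV by extension).

    The default (shortest-repr) float formatting round-trips, so
    ``read_dataset(write_dataset(d))`` reproduces the numbers bit-compatibly.
    """
    df = data.to_frame(time_col, event_col)
    df.to_csv(path, sep=_delimiter_for(path), index=False)


def subsample(data: SurvivalDataset, fraction: float = 0.632,
              seed: int | np.random.Generator = 0,
              max_redraws: int = 100) -> SubsampleSplit:
    """Draw a without-replacement split with ``round(fraction*n)`` training
    rows, redrawing (up to ``max_redraws`` times) until the training part
    contains at least one event.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    n = data.n
    size = int(round(fraction * n))
    if size < 2:
        raise ValueError("training part would have fewer than 2 rows")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    for _ in range(max_redraws + 1):
        perm = rng.permutation(n)
        train = np.sort(perm[:size])
        if data.events[train].sum() >= 1:
            return SubsampleSplit(train, np.sort(perm[size:]))
    raise NoEventsError(
        f"no events in training part after {max_redraws} redraws (seed={seed})"
    )


def standardize(data: SurvivalDataset,
                params: StandardizationParams | None = None
                ) -> tuple[SurvivalDataset, StandardizationParams]:
    """Center and scale every covariate column to mean 0, sample sd 1.

    Constant columns get scale 1 (with a warning) so no division by zero
    occurs; their standardized values are identically 0.  If ``params`` is
    given it is applied as-is (e.g. to transform a test part with training
    parameters).
    """
    X = data.covariates
    if params is None:
        means = X.mean(axis=0)
        scales = X.std(axis=0, ddof=1)
        constant = scales <= 0
        if constant.any():
            logger.warning("constant covariate columns standardized with scale 1: %s",
                           [data.names[j] for j in np.flatnonzero(constant)])
            scales = np.where(constant, 1.0, scales)
        params = StandardizationParams(means, scales)
    return data.with_covariates(params.transform(X)), params
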