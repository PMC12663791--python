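"""Frontal-endemism statistic with a station-resampling null model.

The observed statistic is the proportion of taxa found exclusively within a
focal station set (e.g. the frontal stations).  Its null distribution comes
from Monte-Carlo draws of uniformly random station sets of the same size;
an excess of exclusives at the focal set relative to that null indicates a
region-specific flora rather than a sampling artefact.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError

__all__ = ["OccurrenceTable", "EndemismResult", "exclusive_proportion", "endemism_null"]


class OccurrenceTable:
    """Taxa x stations matrix of counts >= 0; presence means count >= 1.

    Wraps a pandas DataFrame with taxa as the index and station labels as
    columns.  Taxa with no presence anywhere are dropped on construction.
    """

    def __init__(self, counts: pd.DataFrame):
        if counts.index.duplicated().any():
            raise ConfigurationError("duplicate taxon labels")
        if counts.columns.duplicated().any():
            raise ConfigurationError("duplicate station labels")
        values = counts.to_numpy()
        if np.any(~np.isfinite(values)) or np.any(values < 0):
            raise DomainError("occurrence counts must be finite and >= 0")
        present = (values >= 1).any(axis=1)
        self.counts = counts.loc[present]

    @property
    def stations(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.index)

    @property
    def n_taxa(self) -> int:
        return len(self.counts)

    def presence(self) -> np.ndarray:
        return (self.counts.to_numpy() >= 1)


@dataclass(frozen=True)
class EndemismResult:
    """Observed exclusive proportion against its resampling null."""

    observed_proportion: float
    null_mean: float
    null_sd: float
    empirical_p: float
    n_draws: int
    seed: int
    station_set: tuple[str, ...]

    def __post_init__(self) -> None:
        for name in ("observed_proportion", "null_mean", "empirical_p"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise DomainError(f"{name} = {v} outside [0, 1]")
        if self.n_draws < 1:
            raise DomainError("n_draws must be >= 1")


def _station_indices(table: OccurrenceTable, station_set: Iterable[str]) -> np.ndarray:
    cols = list(station_set)
    if not cols:
        raise DomainError("station set must be non-empty")
    unknown = set(cols) - set(table.stations)
    if unknown:
        raise ConfigurationError(f"unknown station label(s): {sorted(unknown)}")
    lookup = {s: i for i, s in enumerate(table.stations)}
    return np.array([lookup[c] for c in cols], dtype=int)


def _exclusive_count(presence: np.ndarray, idx: np.ndarray) -> int:
    inside = presence[:, idx].any(axis=1)
    mask = np.ones(presence.shape[1], dtype=bool)
    mask[idx] = False
    outside = presence[:, mask].any(axis=1)
    return int(np.count_nonzero(inside & ~outside))


def exclusive_proportion(table: OccurrenceTable, station_set: Iterable[str]) -> float:
    """Fraction of all retained taxa found only within ``station_set``."""
    idx = _station_indices(table, station_set)
    if table.n_taxa == 0:
        raise DomainError("occurrence table has no taxa with presences")
    return _exclusive_count(table.presence(), idx) / table.n_taxa


def endemism_null(
    table: OccurrenceTable,
    station_set: Iterable[str],
    n_draws: int = 1000,
    seed: int = 0,
    *,
    exclude_focal: bool = False,
) -> EndemismResult:
    """Monte-Carlo null for the exclusive proportion of a focal station set.

    Draws ``n_draws`` uniform subsets of k = len(station_set) stations (from
    all stations; ``exclude_focal`` restricts the pool to non-focal stations
    as a sensitivity option), computes the exclusive proportion for each and
    reports the null mean/sd and the empirical p-value, the fraction of
    draws >= the observed value.  Fully reproducible from ``seed``.
    """
    focal = _station_indices(table, station_set)
    k = len(focal)
    n_stations = len(table.stations)
    pool = np.arange(n_stations)
    if exclude_focal:
        pool = np.setdiff1d(pool, focal)
    if k >= n_stations:
        raise DomainError(f"set size {k} must be smaller than the station count {n_stations}")
    if k > len(pool):
        raise DomainError("station pool too small for the requested set size")
    if n_draws < 1:
        raise DomainError("n_draws must be >= 1")

    presence = table.presence()
    observed = _exclusive_count(presence, focal) / table.n_taxa
    rng = np.random.default_rng(seed)
    draws = np.empty(n_draws)
    for i in range(n_draws):
        idx = rng.choice(pool, size=k, replace=False)
        draws[i] = _exclusive_count(presence, idx) / table.n_taxa
    return EndemismResult(
        observed_proportion=observed,
        null_mean=float(draws.mean()),
        null_sd=float(draws.std(ddof=1)) if n_draws > 1 else 0.0,
        empirical_p=float(np.mean(draws >= observed)),
        n_draws=n_draws,
        seed=seed,
        station_set=tuple(station_set),
    )
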