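"""Per-cell application of the diffusion model to imaged-cell feature tables.

Morphology from imaging flow cytometry arrives as major/minor axis lengths;
cells are treated as prolate spheroids (BV = pi/6 * major * minor^2), the
diffusion model is evaluated with nutrients interpolated to the cell's
position and the seawater state of the nearest-in-time underway record, and
results are summarized into the growth-rate-bin / trophic-strategy tables
used to ask which cells could not sustain a target growth rate by
osmotrophy alone and what alternative N-acquisition strategies they carry.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from datetime import datetime
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .diffusion import CellGeometry, ModelConfig, n_based_max_growth, p_based_max_growth
from .errors import ConfigurationError, DomainError, MissingDataError
from .track import Region, Station, UnderwayObservation, classify_region, interpolate_nutrients, nearest_observation

log = logging.getLogger(__name__)

__all__ = [
    "ImagedCellFeatures",
    "AnnotatedCell",
    "CellModelResult",
    "DEFAULT_STRATEGY_MAP",
    "DDA_RECLASSIFICATION",
    "STRATEGIES",
    "ALTERNATIVE_STRATEGIES",
    "geometry_from_features",
    "assign_strategy",
    "annotate_cells",
    "apply_model",
    "growth_bin_labels",
    "assign_growth_bin",
    "bin_and_summarize",
    "limited_cell_strategy_summary",
]

STRATEGIES = ("osmotroph", "mixotroph", "diazotroph", "dda", "unknown")

#: strategies that bypass dissolved-inorganic-N diffusion limitation
ALTERNATIVE_STRATEGIES = frozenset({"mixotroph", "diazotroph", "dda"})

#: case-insensitive substring -> trophic strategy, first match wins
DEFAULT_STRATEGY_MAP: dict[str, str] = {
    "trichodesmium": "diazotroph",
    "richelia": "diazotroph",
    "dinophyceae": "mixotroph",
}

#: taxa hosting (or suspected to host) N2-fixing symbionts, reclassified to DDA
DDA_RECLASSIFICATION: dict[str, str] = {
    "hemiaulus": "dda",
    "chaetocero": "dda",
    "haslea": "dda",
    "mastogloia": "dda",
}


@dataclass(frozen=True)
class ImagedCellFeatures:
    """Morphological features of one imaged object (axes in um after calibration)."""

    object_id: str
    timestamp: datetime
    latitude: float
    longitude: float
    major_axis: float
    minor_axis: float
    taxon: str
    area: float | None = None
    functional_group: str | None = None

    def __post_init__(self) -> None:
        if not (self.minor_axis > 0 and np.isfinite(self.major_axis)):
            raise DomainError(f"axes must be positive, got {self.major_axis}, {self.minor_axis}")
        if self.minor_axis > self.major_axis:
            raise DomainError(
                f"{self.object_id}: minor axis {self.minor_axis} exceeds major {self.major_axis}"
            )


@dataclass(frozen=True)
class AnnotatedCell:
    """A cell with derived geometry, functional group and trophic strategy."""

    features: ImagedCellFeatures
    geometry: CellGeometry
    functional_group: str
    trophic_strategy: str

    def __post_init__(self) -> None:
        if self.trophic_strategy not in STRATEGIES:
            raise DomainError(f"unknown trophic strategy {self.trophic_strategy!r}")


@dataclass(frozen=True)
class CellModelResult:
    """Model output for one cell: growth rates, region, growth bin."""

    object_id: str
    taxon: str
    functional_group: str
    trophic_strategy: str
    esd: float
    aspect_ratio: float
    din: float
    gr_n: float
    gr_p: float
    region: Region
    growth_bin: str


def geometry_from_features(features: ImagedCellFeatures) -> CellGeometry:
    """Prolate-spheroid geometry from 2-D axes: BV = pi/6 * major * minor^2."""
    major, minor = features.major_axis, features.minor_axis
    biovolume = math.pi / 6.0 * major * minor**2
    esd = (6.0 * biovolume / math.pi) ** (1.0 / 3.0)
    aspect = major / minor
    shape = "sphere" if aspect == 1.0 else "prolate"
    return CellGeometry(esd=esd, aspect_ratio=aspect, shape=shape)


def assign_strategy(taxon: str, strategy_map: Mapping[str, str] | None = None) -> str:
    """Trophic strategy from a (hierarchical) taxon label by substring lookup."""
    label = taxon.lower()
    for key, strategy in (strategy_map or DEFAULT_STRATEGY_MAP).items():
        if key.lower() in label:
            return strategy
    return "osmotroph"


def _functional_group(taxon: str) -> str:
    """Last component of a '>'-separated annotation hierarchy."""
    return taxon.split(">")[-1].strip()


def annotate_cells(
    features: Sequence[ImagedCellFeatures],
    strategy_map: Mapping[str, str] | None = None,
) -> list[AnnotatedCell]:
    return [
        AnnotatedCell(
            features=f,
            geometry=geometry_from_features(f),
            functional_group=f.functional_group or _functional_group(f.taxon),
            trophic_strategy=assign_strategy(f.taxon, strategy_map),
        )
        for f in features
    ]


def growth_bin_labels(thresholds: Sequence[float]) -> list[str]:
    """Human-readable labels for [0, t1), [t1, t2), ..., [tn, inf) d^-1 bins."""
    edges = [0.0, *thresholds]
    labels = [f"[{a:g}, {b:g})" for a, b in zip(edges, edges[1:])]
    labels.append(f">={edges[-1]:g}")
    return labels


def assign_growth_bin(gr: float, thresholds: Sequence[float]) -> str:
    idx = int(np.searchsorted(np.asarray(thresholds, dtype=float), gr, side="right"))
    return growth_bin_labels(thresholds)[idx]


def apply_model(
    cells: Sequence[AnnotatedCell],
    stations: Sequence[Station],
    underway: Sequence[UnderwayObservation],
    config: ModelConfig = ModelConfig(),
) -> tuple[list[CellModelResult], int]:
    """Run the diffusion model on every cell; returns (results, n_dropped).

    Each cell uses nutrients interpolated along the track at its position and
    the seawater state of the nearest-in-time underway record.  Cells whose
    nutrients or state cannot be resolved are dropped and counted, never
    silently zero-filled.
    """
    if not stations or not underway:
        raise ConfigurationError("apply_model needs a station track and underway records")
    results: list[CellModelResult] = []
    dropped = 0
    for cell in cells:
        f = cell.features
        try:
            obs = nearest_observation(f.timestamp, underway)
            nutrients = interpolate_nutrients((f.latitude, f.longitude), stations)
            state = obs.seawater_state
            gr_n = n_based_max_growth(cell.geometry, nutrients, state, config)
            gr_p = p_based_max_growth(cell.geometry, nutrients, state, config)
        except (MissingDataError, DomainError) as err:
            log.debug("dropping cell %s: %s", f.object_id, err)
            dropped += 1
            continue
        results.append(
            CellModelResult(
                object_id=f.object_id,
                taxon=f.taxon,
                functional_group=cell.functional_group,
                trophic_strategy=cell.trophic_strategy,
                esd=cell.geometry.esd,
                aspect_ratio=cell.geometry.aspect_ratio,
                din=nutrients.din,
                gr_n=gr_n,
                gr_p=gr_p,
                region=classify_region(obs.sst),
                growth_bin=assign_growth_bin(gr_n, config.growth_thresholds),
            )
        )
    if dropped:
        log.info("apply_model: dropped %d of %d cells", dropped, len(cells))
    return results, dropped


def results_to_frame(results: Sequence[CellModelResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "object_id": r.object_id,
                "taxon": r.taxon,
                "functional_group": r.functional_group,
                "trophic_strategy": r.trophic_strategy,
                "esd_um": r.esd,
                "aspect_ratio": r.aspect_ratio,
                "din_nmol_l": r.din,
                "gr_n_per_day": r.gr_n,
                "gr_p_per_day": r.gr_p,
                "region": r.region.value,
                "growth_bin": r.growth_bin,
            }
            for r in results
        ]
    )


def bin_and_summarize(
    results: Sequence[CellModelResult],
    thresholds: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Proportion of each functional group within region x growth-rate bin.

    Returns a tidy frame (region, growth_bin, functional_group, n, proportion);
    proportions sum to 1 within each region x bin stratum.
    """
    if not results:
        log.warning("bin_and_summarize: empty result list")
        return pd.DataFrame(
            columns=["region", "growth_bin", "functional_group", "n", "proportion"]
        )
    df = results_to_frame(results)
    if thresholds is not None:
        df["growth_bin"] = [assign_growth_bin(g, thresholds) for g in df["gr_n_per_day"]]
    counts = (
        df.groupby(["region", "growth_bin", "functional_group"], observed=True)
        .size()
        .rename("n")
        .reset_index()
    )
    counts["proportion"] = counts["n"] / counts.groupby(["region", "growth_bin"], observed=True)[
        "n"
    ].transform("sum")
    return counts


def limited_cell_strategy_summary(
    results: Sequence[CellModelResult],
    threshold: float = 0.2,
    reclassification: Mapping[str, str] | None = None,
    region: Region | None = Region.SUBTROPICAL,
) -> dict:
    """Strategy composition of diffusion-limited cells (gr_n < threshold).

    ``reclassification`` maps taxon substrings to strategies (e.g. the DDA
    map moving *Hemiaulus*/Chaetocerotaceae/*Haslea*-like/*Mastogloia* cells
    from osmotroph to dda); applying such a map can only increase the
    alternative-strategy share.  Returns counts per strategy and the
    percentage of limited cells with an alternative (non-osmotrophic) N
    acquisition strategy; percentages are absent for an empty limited set.
    """
    if not threshold > 0:
        raise DomainError("threshold must be > 0")
    pool = [r for r in results if region is None or r.region == region]
    limited = [r for r in pool if r.gr_n < threshold]

    def strategy_of(r: CellModelResult) -> str:
        if reclassification:
            label = r.taxon.lower()
            for key, strat in reclassification.items():
                if key.lower() in label:
                    return strat
        return r.trophic_strategy

    counts: dict[str, int] = {s: 0 for s in STRATEGIES}
    for r in limited:
        counts[strategy_of(r)] += 1
    n_limited = len(limited)
    n_alternative = sum(counts[s] for s in ALTERNATIVE_STRATEGIES)
    summary = {
        "n_total": len(pool),
        "n_limited": n_limited,
        "limited_fraction_percent": 100.0 * n_limited / len(pool) if pool else None,
        "strategy_counts": counts,
        "n_alternative": n_alternative,
        "alternative_strategy_percent": (
            100.0 * n_alternative / n_limited if n_limited else None
        ),
    }
    return summary
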