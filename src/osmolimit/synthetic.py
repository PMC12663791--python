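"""Synthetic cruise, cell and occurrence generators.

These emulate the statistical structure of a meridional austral-summer
transect from warm oligotrophic subtropical water into cold macronutrient-
replete subantarctic water, so that every pipeline stage can be exercised
and calibrated without the original cruise data:

* SST falls quasi-linearly (~25 -> 2 degC) along the track.
* DIN sits on a flat oligotrophic gyre plateau (~0.02 umol/L), rises
  steeply approaching the subtropical front, and plateaus above 14 umol/L
  in the subantarctic; the default knots put the subtropical regional mean
  near 0.25 umol/L.  DIN is split into ammonium/nitrite/nitrate by fixed
  fractions, and DIP follows regional DIN:DIP targets (3.7 north, 14.5
  south of the front).
* Cell morphology is lognormal in ESD with gamma-distributed aspect-ratio
  excess per taxon profile; regional relative abundances shift the
  community across the front.
* Occurrence tables give taxa Gaussian thermal niches with a tunable
  environmental-filtering strength and an optional fraction of taxa found
  only at the frontal stations.

All generators are pure functions of (parameters, seed); one master seed
spawns independent per-stream seeds.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import datetime, timedelta, timezone
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cells import AnnotatedCell, ImagedCellFeatures, apply_model, geometry_from_features
from .diffusion import ModelConfig, NutrientField
from .endemism import OccurrenceTable
from .errors import ConfigurationError, DomainError
from .track import Region, Station, UnderwayObservation, build_track, classify_region

__all__ = [
    "CruiseScenario",
    "TaxonProfile",
    "ExclusionRule",
    "default_taxon_profiles",
    "simulate_cruise",
    "simulate_cells",
    "simulate_occurrences",
]


@dataclass(frozen=True)
class CruiseScenario:
    """Parameters of the synthetic transect; defaults emulate the study region."""

    n_stations: int = 43
    lat_north: float = -27.0
    lat_south: float = -56.0
    lon_north: float = 57.0
    lon_south: float = 52.0
    start_time: datetime = datetime(2021, 1, 15, tzinfo=timezone.utc)
    duration_days: float = 48.0
    sst_north: float = 25.3  # degC at the northern end
    sst_south: float = 2.0
    salinity_north: float = 35.5
    salinity_south: float = 33.8
    # DIN profile knots (umol/L): flat gyre plateau, steep frontal rise,
    # subantarctic plateau; calibrated so the subtropical station mean ~0.25
    din_gyre: float = 0.02
    din_front: float = 4.0
    din_subantarctic: float = 20.0
    din_south: float = 30.0
    gyre_plateau_fraction: float = 0.6  # fraction of the subtropical segment on the plateau
    nh4_fraction: float = 0.15
    no2_fraction: float = 0.05
    din_dip_north: float = 3.7
    din_dip_south: float = 14.5
    nutrient_noise_gsd: float = 1.10  # lognormal geometric sd on concentrations
    dip_ratio_noise_gsd: float = 1.05
    sst_noise_station: float = 0.1
    sst_noise_underway: float = 0.2
    salinity_noise: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_stations < 2:
            raise ConfigurationError("need at least 2 stations")
        if not self.sst_north > self.sst_south:
            raise ConfigurationError("SST must decrease southward")
        if not (self.din_gyre <= self.din_front <= self.din_subantarctic <= self.din_south):
            raise ConfigurationError("DIN must rise southward (gyre <= front <= subantarctic <= south)")
        if not (0.0 < self.gyre_plateau_fraction < 1.0):
            raise ConfigurationError("gyre_plateau_fraction must lie in (0, 1)")
        if self.nh4_fraction + self.no2_fraction > 1.0:
            raise ConfigurationError("NH4 + NO2 fractions exceed 1")

    @property
    def x_front(self) -> float:
        """Track fraction where nominal SST crosses 20 degC."""
        return (self.sst_north - 20.0) / (self.sst_north - self.sst_south)

    @property
    def x_subantarctic(self) -> float:
        """Track fraction where nominal SST crosses 10 degC."""
        return (self.sst_north - 10.0) / (self.sst_north - self.sst_south)

    def din_profile_umol(self, x) -> np.ndarray:
        """Noise-free DIN (umol/L) at track fraction(s) x, log-linear between knots."""
        knots_x = [
            0.0,
            self.gyre_plateau_fraction * self.x_front,
            self.x_front,
            self.x_subantarctic,
            1.0,
        ]
        knots_y = np.log10(
            [self.din_gyre, self.din_gyre, self.din_front, self.din_subantarctic, self.din_south]
        )
        return 10.0 ** np.interp(np.asarray(x, dtype=float), knots_x, knots_y)

    def din_dip_ratio(self, x) -> np.ndarray:
        """Regional target DIN:DIP, transitioning linearly across the front."""
        x = np.asarray(x, dtype=float)
        t = np.clip((x - self.x_front) / (self.x_subantarctic - self.x_front), 0.0, 1.0)
        return self.din_dip_north + t * (self.din_dip_south - self.din_dip_north)


def _lognormal_noise(rng: np.random.Generator, gsd: float, size) -> np.ndarray:
    return np.exp(rng.normal(0.0, math.log(gsd), size=size))


def simulate_cruise(
    scenario: CruiseScenario = CruiseScenario(),
) -> tuple[list[Station], list[UnderwayObservation]]:
    """Generate the station track and 2-hourly underway observations."""
    ss = np.random.SeedSequence(scenario.seed)
    rng_st, rng_uw = (np.random.default_rng(s) for s in ss.spawn(2))

    n = scenario.n_stations
    x = np.linspace(0.0, 1.0, n)
    lat = scenario.lat_north + x * (scenario.lat_south - scenario.lat_north)
    lon = scenario.lon_north + x * (scenario.lon_south - scenario.lon_north)
    sst = (
        scenario.sst_north
        + x * (scenario.sst_south - scenario.sst_north)
        + rng_st.normal(0.0, scenario.sst_noise_station, n)
    )
    sal = (
        scenario.salinity_north
        + x * (scenario.salinity_south - scenario.salinity_north)
        + rng_st.normal(0.0, scenario.salinity_noise, n)
    )
    din = scenario.din_profile_umol(x) * _lognormal_noise(rng_st, scenario.nutrient_noise_gsd, n)
    dip = din / (
        scenario.din_dip_ratio(x) * _lognormal_noise(rng_st, scenario.dip_ratio_noise_gsd, n)
    )
    nh4 = scenario.nh4_fraction * din
    no2 = scenario.no2_fraction * din
    no3 = din - nh4 - no2

    stations = [
        Station(
            id=f"s{i + 1:02d}",
            latitude=float(lat[i]),
            longitude=float(lon[i]),
            temperature=float(sst[i]),
            salinity=float(sal[i]),
            nutrients=NutrientField(
                ammonium=float(nh4[i] * 1000.0),  # umol/L -> nmol/L
                nitrite=float(no2[i] * 1000.0),
                nitrate=float(no3[i] * 1000.0),
                phosphate=float(dip[i] * 1000.0),
            ),
        )
        for i in range(n)
    ]

    n_obs = int(scenario.duration_days * 12) + 1  # every 2 h
    xo = np.linspace(0.0, 1.0, n_obs)
    sst_o = (
        scenario.sst_north
        + xo * (scenario.sst_south - scenario.sst_north)
        + rng_uw.normal(0.0, scenario.sst_noise_underway, n_obs)
    )
    sal_o = (
        scenario.salinity_north
        + xo * (scenario.salinity_south - scenario.salinity_north)
        + rng_uw.normal(0.0, scenario.salinity_noise, n_obs)
    )
    underway = [
        UnderwayObservation(
            timestamp=scenario.start_time + timedelta(hours=2.0 * i),
            latitude=float(scenario.lat_north + xo[i] * (scenario.lat_south - scenario.lat_north)),
            longitude=float(scenario.lon_north + xo[i] * (scenario.lon_south - scenario.lon_north)),
            sst=float(sst_o[i]),
            salinity=float(sal_o[i]),
        )
        for i in range(n_obs)
    ]
    return build_track(stations), underway


@dataclass(frozen=True)
class TaxonProfile:
    """Morphology distribution and regional weighting for one synthetic taxon."""

    label: str
    functional_group: str
    trophic_strategy: str
    esd_median_um: float
    esd_gsd: float
    aspect_excess_mean: float  # mean of (E - 1); 0 = always spherical
    weights: Mapping[str, float]  # region name -> relative abundance

    def __post_init__(self) -> None:
        if self.esd_median_um <= 0 or self.esd_gsd < 1.0:
            raise ConfigurationError("esd distribution needs median > 0 and gsd >= 1")
        if self.aspect_excess_mean < 0:
            raise ConfigurationError("aspect_excess_mean must be >= 0")
        if any(w < 0 for w in self.weights.values()) or sum(self.weights.values()) <= 0:
            raise ConfigurationError("regional weights must be >= 0 and normalizable")


@dataclass(frozen=True)
class ExclusionRule:
    """Remove cells of a strategy whose modeled gr_n falls below a threshold."""

    threshold: float = 0.2
    strategy: str = "osmotroph"
    prob: float = 1.0

    def __post_init__(self) -> None:
        if self.threshold <= 0 or not (0.0 <= self.prob <= 1.0):
            raise ConfigurationError("need threshold > 0 and prob in [0, 1]")


def default_taxon_profiles() -> list[TaxonProfile]:
    """Eight profiles spanning the cruise's dominant functional groups."""
    w = lambda st, fr, sa: {"subtropical": st, "front": fr, "subantarctic": sa}
    return [
        TaxonProfile("living>Bacillariophyta>Bacillariophyceae>Fragilariopsis",
                     "diatom", "osmotroph", 12.0, 1.6, 0.8, w(0.04, 0.30, 0.45)),
        TaxonProfile("living>Bacillariophyta>Mediophyceae>Chaetoceros",
                     "diatom", "osmotroph", 10.0, 1.6, 1.5, w(0.04, 0.15, 0.30)),
        TaxonProfile("living>Dinoflagellata>Dinophyceae",
                     "Dinophyceae", "mixotroph", 15.0, 1.7, 0.4, w(0.45, 0.25, 0.08)),
        TaxonProfile("living>Cyanobacteria>Trichodesmium",
                     "Trichodesmium", "diazotroph", 22.0, 1.5, 8.0, w(0.12, 0.04, 0.0)),
        TaxonProfile("living>Bacillariophyta>Mediophyceae>Hemiaulus",
                     "diatom", "osmotroph", 14.0, 1.5, 1.2, w(0.05, 0.04, 0.01)),
        TaxonProfile("living>Haptophyta>Prymnesiophyceae>Umbellosphaera",
                     "Prymnesiophyceae", "osmotroph", 6.0, 1.4, 0.2, w(0.22, 0.12, 0.04)),
        TaxonProfile("living>Bacillariophyta>Bacillariophyceae>Haslea",
                     "diatom", "osmotroph", 9.0, 1.5, 2.0, w(0.05, 0.05, 0.02)),
        TaxonProfile("living>Bacillariophyta>Bacillariophyceae>Mastogloia",
                     "diatom", "osmotroph", 8.0, 1.4, 1.0, w(0.03, 0.05, 0.10)),
    ]


def simulate_cells(
    profiles: Sequence[TaxonProfile],
    n_cells: int,
    stations: Sequence[Station],
    underway: Sequence[UnderwayObservation],
    seed: int = 0,
    exclusion: ExclusionRule | None = None,
    config: ModelConfig = ModelConfig(),
) -> list[AnnotatedCell]:
    """Draw cells along the track with per-taxon morphology and regional weights.

    With an :class:`ExclusionRule`, cells of the targeted strategy whose
    modeled N-based growth rate falls below the threshold are removed with
    the given probability (emulating resource-based competitive exclusion).
    """
    if not profiles:
        raise ConfigurationError("no taxon profiles given")
    if not underway:
        raise ConfigurationError("no underway observations given")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])

    obs_regions = [classify_region(o.sst).value for o in underway]
    weight_matrix = np.array(
        [[p.weights.get(r, 0.0) for p in profiles] for r in obs_regions]
    )

    cells: list[AnnotatedCell] = []
    obs_idx = rng.integers(0, len(underway), size=n_cells)
    for i in obs_idx:
        obs = underway[i]
        wrow = weight_matrix[i]
        if wrow.sum() <= 0:
            continue
        p = profiles[rng.choice(len(profiles), p=wrow / wrow.sum())]
        esd = p.esd_median_um * math.exp(rng.normal(0.0, math.log(p.esd_gsd)))
        if p.aspect_excess_mean > 0:
            aspect = 1.0 + min(rng.gamma(2.0, p.aspect_excess_mean / 2.0), 49.0)
        else:
            aspect = 1.0
        minor = esd * aspect ** (-1.0 / 3.0)
        major = aspect * minor
        features = ImagedCellFeatures(
            object_id=f"cell{len(cells) + 1:06d}",
            timestamp=obs.timestamp,
            latitude=obs.latitude,
            longitude=obs.longitude,
            major_axis=major,
            minor_axis=minor,
            taxon=p.label,
            functional_group=p.functional_group,
        )
        cells.append(
            AnnotatedCell(
                features=features,
                geometry=geometry_from_features(features),
                functional_group=p.functional_group,
                trophic_strategy=p.trophic_strategy,
            )
        )

    if exclusion is not None:
        results, _ = apply_model(cells, stations, underway, config)
        gr_by_id = {r.object_id: r.gr_n for r in results}
        keep_draws = rng.random(len(cells))
        kept = []
        for cell, u in zip(cells, keep_draws):
            gr = gr_by_id.get(cell.features.object_id)
            limited = (
                cell.trophic_strategy == exclusion.strategy
                and gr is not None
                and gr < exclusion.threshold
            )
            if limited and u < exclusion.prob:
                continue
            kept.append(cell)
        cells = kept
    return cells


def simulate_occurrences(
    n_taxa: int,
    stations: Sequence[Station],
    niche_width_c: float = 3.0,
    filtering_strength: float = 0.5,
    frontal_endemic_fraction: float = 0.0,
    seed: int = 0,
    *,
    frontal_stations: Sequence[str] | None = None,
    baseline_occupancy: float = 0.35,
    mean_count: float = 5.0,
) -> OccurrenceTable:
    """Taxa x stations count table with thermal niches and optional frontal endemics.

    Presence probability is ``p0 * ((1 - strength) + strength * suitability)``
    with a Gaussian thermal suitability; at ``filtering_strength = 0`` station
    composition is exchangeable.  The first ``round(fraction * n_taxa)`` taxa
    are endemic to the frontal stations.
    """
    if not (0.0 <= filtering_strength <= 1.0):
        raise DomainError("filtering_strength must lie in [0, 1]")
    if not (0.0 <= frontal_endemic_fraction <= 1.0):
        raise DomainError("frontal_endemic_fraction must lie in [0, 1]")
    if niche_width_c <= 0 or not (0.0 < baseline_occupancy <= 1.0):
        raise DomainError("need niche_width_c > 0 and baseline_occupancy in (0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])

    temps = np.array([s.temperature for s in stations])
    ids = [s.id for s in stations]
    if frontal_stations is None:
        frontal_stations = [
            s.id for s in stations if classify_region(s.temperature) is Region.FRONT
        ]
    frontal_idx = [ids.index(sid) for sid in frontal_stations]
    n_endemic = round(frontal_endemic_fraction * n_taxa)
    if n_endemic and not frontal_idx:
        raise ConfigurationError("frontal endemics requested but no frontal stations")

    t_opt = rng.uniform(temps.min() - 1.0, temps.max() + 1.0, size=n_taxa)
    suitability = np.exp(-((temps[None, :] - t_opt[:, None]) ** 2) / (2.0 * niche_width_c**2))
    prob = baseline_occupancy * ((1.0 - filtering_strength) + filtering_strength * suitability)
    presence = rng.random((n_taxa, len(stations))) < prob

    if n_endemic:
        presence[:n_endemic, :] = False
        frontal_presence = rng.random((n_endemic, len(frontal_idx))) < 0.8
        for row in range(n_endemic):
            if not frontal_presence[row].any():
                frontal_presence[row, rng.integers(len(frontal_idx))] = True
        presence[:n_endemic, frontal_idx] = frontal_presence

    counts = np.where(presence, 1 + rng.poisson(max(mean_count - 1.0, 0.0), presence.shape), 0)
    frame = pd.DataFrame(
        counts, index=[f"taxon_{i + 1:04d}" for i in range(n_taxa)], columns=ids
    )
    return OccurrenceTable(frame)
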