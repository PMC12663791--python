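"""Readers and writers for the tabular formats, plus pipeline configuration.

Environmental tables are CSV, cell and occurrence tables TSV (matching
their reference dialects).  Files carry nutrient concentrations in umol/L
(urea in nmol/L); everything is converted to nmol/L at ingest.  Writers
emit a stable column order with a schema-version comment line; readers
skip '#' comment lines.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .cells import ImagedCellFeatures
from .diffusion import ModelConfig, NutrientField
from .endemism import OccurrenceTable
from .errors import ConfigurationError, SchemaError
from .track import Station, UnderwayObservation, build_track

log = logging.getLogger(__name__)

SCHEMA_COMMENT = "# osmolimit schema v1"

STATION_COLUMNS = [
    "station_id", "lat", "lon", "temp_c", "sal",
    "nh4_umol_l", "no2_umol_l", "no3_umol_l", "dip_umol_l",
]
UNDERWAY_COLUMNS = ["iso_time", "lat", "lon", "sst_c", "sal"]
PLAIN_CELL_COLUMNS = [
    "object_id", "iso_time", "lat", "lon", "major_axis_um", "minor_axis_um", "taxon",
]


def _read_table(path, sep: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"input file not found: {path}")
    return pd.read_csv(path, sep=sep, comment="#")


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")


def _parse_float(df: pd.DataFrame, column: str, path) -> np.ndarray:
    try:
        return df[column].astype(float).to_numpy()
    except (TypeError, ValueError) as err:
        bad = df[pd.to_numeric(df[column], errors="coerce").isna()].index
        line = int(bad[0]) + 2 if len(bad) else "?"
        raise SchemaError(f"{path}: unparseable value in column {column!r} near line {line}: {err}")


def read_station_table(path) -> list[Station]:
    """Read a station CSV (concentrations umol/L -> internal nmol/L)."""
    df = _read_table(path, ",")
    _require_columns(df, STATION_COLUMNS, path)
    for col in STATION_COLUMNS[1:]:
        _parse_float(df, col, path)
    has_urea = "urea_nmol_l" in df.columns
    stations = []
    for _, row in df.iterrows():
        stations.append(
            Station(
                id=str(row["station_id"]),
                latitude=float(row["lat"]),
                longitude=float(row["lon"]),
                temperature=float(row["temp_c"]),
                salinity=float(row["sal"]),
                nutrients=NutrientField(
                    ammonium=float(row["nh4_umol_l"]) * 1000.0,
                    nitrite=float(row["no2_umol_l"]) * 1000.0,
                    nitrate=float(row["no3_umol_l"]) * 1000.0,
                    phosphate=float(row["dip_umol_l"]) * 1000.0,
                    urea=float(row["urea_nmol_l"]) if has_urea and pd.notna(row["urea_nmol_l"]) else None,
                ),
            )
        )
    log.info("read %d stations from %s (umol/L converted to nmol/L)", len(stations), path)
    return build_track(stations) if len(stations) >= 2 else stations


def write_station_table(stations: Sequence[Station], path) -> None:
    rows = []
    any_urea = any(s.nutrients.urea is not None for s in stations)
    for s in stations:
        row = {
            "station_id": s.id, "lat": s.latitude, "lon": s.longitude,
            "temp_c": s.temperature, "sal": s.salinity,
            "nh4_umol_l": s.nutrients.ammonium / 1000.0,
            "no2_umol_l": s.nutrients.nitrite / 1000.0,
            "no3_umol_l": s.nutrients.nitrate / 1000.0,
            "dip_umol_l": s.nutrients.phosphate / 1000.0,
        }
        if any_urea:
            row["urea_nmol_l"] = s.nutrients.urea
        rows.append(row)
    _write_csv(pd.DataFrame(rows), path, sep=",")


def read_underway_table(path) -> list[UnderwayObservation]:
    df = _read_table(path, ",")
    _require_columns(df, UNDERWAY_COLUMNS, path)
    obs = [
        UnderwayObservation(
            timestamp=_parse_time(row["iso_time"], path),
            latitude=float(row["lat"]),
            longitude=float(row["lon"]),
            sst=float(row["sst_c"]),
            salinity=float(row["sal"]),
        )
        for _, row in df.iterrows()
    ]
    log.info("read %d underway records from %s", len(obs), path)
    return obs


def write_underway_table(observations: Sequence[UnderwayObservation], path) -> None:
    df = pd.DataFrame(
        {
            "iso_time": [o.timestamp.isoformat() for o in observations],
            "lat": [o.latitude for o in observations],
            "lon": [o.longitude for o in observations],
            "sst_c": [o.sst for o in observations],
            "sal": [o.salinity for o in observations],
        }
    )
    _write_csv(df, path, sep=",")


def _parse_time(value, path) -> datetime:
    try:
        ts = datetime.fromisoformat(str(value))
    except ValueError as err:
        raise SchemaError(f"{path}: unparseable timestamp {value!r}: {err}")
    return ts if ts.tzinfo else ts.replace(tzinfo=timezone.utc)


def read_cell_table(
    path, dialect: str = "ecotaxa_tsv", pixel_calibration: float | None = None
) -> list[ImagedCellFeatures]:
    """Read an imaged-cell feature table.

    ``ecotaxa_tsv``: tab-separated export with object_-prefixed columns and a
    secondary "[t]"/"[f]" type row (skipped); extra columns are tolerated.
    ``plain_csv``: flat CSV with explicit um axes.  ``pixel_calibration``
    (um/px) scales the axes when they are in pixels.
    """
    if dialect == "plain_csv":
        df = _read_table(path, ",")
        _require_columns(df, PLAIN_CELL_COLUMNS, path)
        return [
            ImagedCellFeatures(
                object_id=str(r["object_id"]),
                timestamp=_parse_time(r["iso_time"], path),
                latitude=float(r["lat"]),
                longitude=float(r["lon"]),
                major_axis=float(r["major_axis_um"]),
                minor_axis=float(r["minor_axis_um"]),
                area=float(r["area_um2"]) if "area_um2" in df.columns and pd.notna(r.get("area_um2")) else None,
                taxon=str(r["taxon"]),
            )
            for _, r in df.iterrows()
        ]
    if dialect != "ecotaxa_tsv":
        raise ConfigurationError(f"unknown cell-table dialect {dialect!r}")

    df = _read_table(path, "\t")
    required = ["object_id", "object_date", "object_time", "object_lat", "object_lon",
                "object_major", "object_minor"]
    _require_columns(df, required, path)
    if len(df) and str(df.iloc[0]["object_id"]).startswith("["):
        df = df.iloc[1:].reset_index(drop=True)  # drop the "[t]"/"[f]" type row
    taxon_col = next(
        (c for c in ("object_annotation_hierarchy", "object_annotation_category") if c in df.columns),
        None,
    )
    if taxon_col is None:
        raise SchemaError(f"{path}: no object_annotation_hierarchy/category column")
    scale = pixel_calibration if pixel_calibration is not None else 1.0
    cells = []
    for i, r in df.iterrows():
        date, time_ = str(r["object_date"]), str(r["object_time"]).zfill(6)
        try:
            ts = datetime.strptime(date + time_, "%Y%m%d%H%M%S").replace(tzinfo=timezone.utc)
        except ValueError as err:
            raise SchemaError(f"{path}: bad object_date/object_time at row {i + 3}: {err}")
        cells.append(
            ImagedCellFeatures(
                object_id=str(r["object_id"]),
                timestamp=ts,
                latitude=float(r["object_lat"]),
                longitude=float(r["object_lon"]),
                major_axis=float(r["object_major"]) * scale,
                minor_axis=float(r["object_minor"]) * scale,
                area=float(r["object_area"]) * scale**2 if "object_area" in df.columns else None,
                taxon=str(r[taxon_col]),
            )
        )
    log.info("read %d cells from %s (%s dialect)", len(cells), path, dialect)
    return cells


def write_cell_table(cells: Sequence[ImagedCellFeatures], path) -> None:
    """Write cells in the plain CSV dialect."""
    df = pd.DataFrame(
        {
            "object_id": [c.object_id for c in cells],
            "iso_time": [c.timestamp.isoformat() for c in cells],
            "lat": [c.latitude for c in cells],
            "lon": [c.longitude for c in cells],
            "major_axis_um": [c.major_axis for c in cells],
            "minor_axis_um": [c.minor_axis for c in cells],
            "taxon": [c.taxon for c in cells],
        }
    )
    _write_csv(df, path, sep=",")


def read_occurrence_table(path) -> OccurrenceTable:
    """Read a taxa x stations TSV (first column = taxon labels)."""
    df = _read_table(path, "\t")
    if df.shape[1] < 2:
        raise SchemaError(f"{path}: occurrence table needs a taxon column plus stations")
    df = df.set_index(df.columns[0])
    return OccurrenceTable(df)


def write_occurrence_table(table: OccurrenceTable, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(SCHEMA_COMMENT + "\n")
        table.counts.rename_axis("taxon").reset_index().to_csv(fh, sep="\t", index=False)


def _write_csv(df: pd.DataFrame, path, sep: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(SCHEMA_COMMENT + "\n")
        df.to_csv(fh, sep=sep, index=False)


# ----------------------------- configuration ---------------------------------

_KNOWN_TOP_KEYS = {
    "seed", "output_dir", "inputs", "synthetic", "model",
    "limited_threshold", "size_limit_growth_rates", "endemism",
}


@dataclass
class PipelineConfig:
    """Everything needed for one end-to-end run; loadable from YAML."""

    seed: int = 0
    output_dir: str = "osmolimit_out"
    inputs: dict = field(default_factory=dict)  # stations/underway/cells/occurrences paths
    synthetic: dict = field(default_factory=dict)  # generator overrides when inputs absent
    model: dict = field(default_factory=dict)  # ModelConfig overrides
    limited_threshold: float = 0.2
    size_limit_growth_rates: tuple = (0.2, 0.6)
    endemism: dict = field(default_factory=lambda: {"n_draws": 1000})

    def model_config(self) -> ModelConfig:
        kwargs = dict(self.model)
        if "growth_thresholds" in kwargs:
            kwargs["growth_thresholds"] = tuple(kwargs["growth_thresholds"])
        return ModelConfig(**kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["size_limit_growth_rates"] = list(self.size_limit_growth_rates)
        return d


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: config must be a mapping")
    unknown = set(raw) - _KNOWN_TOP_KEYS
    if unknown:
        raise ConfigurationError(
            f"{path}: unknown config key(s): {', '.join(sorted(unknown))}; "
            f"known: {', '.join(sorted(_KNOWN_TOP_KEYS))}"
        )
    if "size_limit_growth_rates" in raw:
        raw["size_limit_growth_rates"] = tuple(raw["size_limit_growth_rates"])
    return PipelineConfig(**raw)


def save_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
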