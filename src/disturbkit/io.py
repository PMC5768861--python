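"""CSV/YAML/JSON readers and writers for the framework's table formats.

All tables are comma-separated UTF-8 with a mandatory header row and ``.``
decimal separator; floating-point output is fixed to 12 significant digits
so identical runs produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .intensity import ForceSeries, RareEventRecord
from .meta import RECORD_COLUMNS, validate_records
from .severity import AbundanceSeries
from .synthdata import StudyData, SyntheticEvent

__all__ = [
    "FLOAT_FORMAT",
    "read_force_table",
    "read_abundance_table",
    "read_records_table",
    "read_tables",
    "write_table",
    "write_json",
    "write_study",
    "read_study",
]

FLOAT_FORMAT = "%.12g"


def _read_csv(path: str | Path, required: list[str], numeric: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = set(required) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    for col in numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # 1-based, plus header row
            raise ValueError(f"{path}, row {row}: non-numeric value in column {col!r}")
        df[col] = coerced
    return df


def read_force_table(path: str | Path, metadata: dict) -> tuple[ForceSeries, dict]:
    """Read a ``year,value`` force CSV plus its sidecar metadata mapping.

    ``metadata`` must provide ``measure_kind`` and ``harmful_tail`` (and
    usually ``event_value``); for rare events it instead carries
    ``record_length_years`` and ``n_events`` and this function is bypassed.
    """
    df = _read_csv(path, ["year", "value"], ["year", "value"])
    dup = df["year"].duplicated()
    if dup.any():
        raise ValueError(f"{path}, row {int(dup.idxmax()) + 2}: duplicate year")
    force = ForceSeries(
        years=df["year"].to_numpy(dtype=int),
        values=df["value"].to_numpy(dtype=float),
        measure_kind=metadata["measure_kind"],
        harmful_tail=metadata["harmful_tail"],
        label=metadata.get("label", ""),
    )
    return force, metadata


def read_abundance_table(path: str | Path, metadata: dict) -> AbundanceSeries:
    """Read a ``year[,season],abundance`` census CSV plus species metadata."""
    df = _read_csv(path, ["year", "abundance"], ["year", "abundance"])
    neg = df["abundance"] < 0
    if neg.any():
        raise ValueError(f"{path}, row {int(neg.idxmax()) + 2}: negative abundance")
    if "season" not in df.columns:
        dup = df["year"].duplicated()
        if dup.any():
            raise ValueError(
                f"{path}, row {int(dup.idxmax()) + 2}: duplicate year without season column"
            )
    excluded = [tuple(p) for p in metadata.get("excluded_periods", [])]
    return AbundanceSeries(
        data=df,
        species_id=str(metadata.get("species_id", Path(path).stem)),
        event_year=int(metadata["event_year"]),
        excluded_periods=excluded,
        generation_time=metadata.get("generation_time"),
        mobility=metadata.get("mobility"),
        habitat=metadata.get("habitat"),
        spatial_extent_km2=metadata.get("spatial_extent_km2"),
        post_event_season=metadata.get("post_event_season"),
    )


def read_records_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a severity-intensity records CSV."""
    df = _read_csv(
        path,
        RECORD_COLUMNS,
        [
            "x_log10_intensity_rp",
            "y_log10_severity_rp",
            "generation_time_years",
            "spatial_extent_km2",
        ],
    )
    return validate_records(df)


def read_tables(paths: dict[str, str | Path], metadata: dict | None = None) -> dict:
    """Read any combination of the framework's tables into domain objects.

    ``paths`` maps a kind (``force``, ``abundance``, ``records``) to a
    file; ``metadata`` supplies the sidecar configuration those kinds need.
    """
    metadata = metadata or {}
    out: dict = {}
    for kind, path in paths.items():
        if kind == "force":
            out[kind] = read_force_table(path, metadata)[0]
        elif kind == "abundance":
            out[kind] = read_abundance_table(path, metadata)
        elif kind == "records":
            out[kind] = read_records_table(path)
        else:
            raise ValueError(f"unknown table kind {kind!r}")
    return out


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def write_json(data: dict, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(data, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def write_study(study: StudyData, outdir: str | Path) -> Path:
    """Write a synthetic study to disk in the formats the pipeline reads.

    Layout: ``manifest.json``, ``records_true.csv``, and per event
    ``events/<id>/force.csv`` + ``event.yaml`` and
    ``events/<id>/<species>/abundance.csv`` + ``species.yaml``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_json(study.manifest, outdir / "manifest.json")
    write_table(study.records_true, outdir / "records_true.csv")
    for ev in study.events:
        evdir = outdir / "events" / ev.event_id
        evdir.mkdir(parents=True, exist_ok=True)
        meta: dict = {
            "event_id": ev.event_id,
            "event_type": ev.event_type,
            "event_year": int(ev.event_year),
        }
        if ev.rare_record is not None:
            meta["record_length_years"] = float(ev.rare_record.record_length)
            meta["n_events"] = int(ev.rare_record.n_events)
        else:
            write_table(
                pd.DataFrame({"year": ev.force.years, "value": ev.force.values}),
                evdir / "force.csv",
            )
            meta.update(
                {
                    "event_value": float(ev.event_value),
                    "measure_kind": ev.force.measure_kind.value,
                    "harmful_tail": ev.force.harmful_tail.value,
                    "label": ev.force.label,
                }
            )
        with open(evdir / "event.yaml", "w") as fh:
            yaml.safe_dump(meta, fh, sort_keys=True)
        for ab in ev.species:
            spdir = evdir / ab.species_id
            write_table(ab.data[["year", "abundance"]], spdir / "abundance.csv")
            with open(spdir / "species.yaml", "w") as fh:
                yaml.safe_dump(
                    {
                        "species_id": ab.species_id,
                        "event_year": int(ab.event_year),
                        "excluded_periods": [list(p) for p in ab.excluded_periods],
                        "generation_time": ab.generation_time,
                        "mobility": ab.mobility,
                        "habitat": ab.habitat,
                        "spatial_extent_km2": ab.spatial_extent_km2,
                    },
                    fh,
                    sort_keys=True,
                )
    return outdir


def read_study(indir: str | Path) -> StudyData:
    """Read a study directory written by :func:`write_study`."""
    indir = Path(indir)
    with open(indir / "manifest.json") as fh:
        manifest = json.load(fh)
    records_true = pd.read_csv(indir / "records_true.csv")
    events: list[SyntheticEvent] = []
    for evdir in sorted((indir / "events").iterdir()):
        with open(evdir / "event.yaml") as fh:
            meta = yaml.safe_load(fh)
        if "record_length_years" in meta:
            force, rare = None, RareEventRecord(meta["record_length_years"], meta["n_events"])
        else:
            force, _ = read_force_table(evdir / "force.csv", meta)
            rare = None
        species = []
        for spdir in sorted(p for p in evdir.iterdir() if p.is_dir()):
            with open(spdir / "species.yaml") as fh:
                sp_meta = yaml.safe_load(fh)
            species.append(read_abundance_table(spdir / "abundance.csv", sp_meta))
        events.append(
            SyntheticEvent(
                event_id=meta["event_id"],
                event_type=meta["event_type"],
                event_year=meta["event_year"],
                force=force,
                event_value=meta.get("event_value"),
                rare_record=rare,
                true_intensity_rp=float("nan"),
                true_severity_rp=float("nan"),
                true_es=float("nan"),
                species=species,
            )
        )
    return StudyData(scenario=None, events=events, records_true=records_true, manifest=manifest)
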