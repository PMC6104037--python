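"""File formats: record CSV + JSON sidecar, region GeoJSON, configs.

On disk the field-conventional units are used (um for lengths, nN for
loads, s for time) with unit-suffixed column headers; conversion to the
strict-SI in-memory representation happens here and nowhere else.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import Polygon, mapping, shape

from .records import IndentationRecord, ProbeSpec, ProtocolSpec
from .regions import RegionGeometry
from .rheology import RheologyModel
from .simulate import TissuePhantom

__all__ = [
    "write_record",
    "read_record",
    "geometry_to_geojson",
    "geometry_from_geojson",
    "phantom_from_dict",
    "load_config",
]

RECORD_COLUMNS = ("time_s", "depth_um", "load_nN")


def write_record(record: IndentationRecord, directory: str | Path) -> Path:
    """Write one record as <record_id>.csv plus a <record_id>.json sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    csv_path = directory / f"{record.record_id}.csv"
    pd.DataFrame(
        {
            "time_s": record.time,
            "depth_um": record.depth * 1e6,
            "load_nN": record.load * 1e9,
        }
    ).to_csv(csv_path, index=False, float_format="%.9g")
    meta = {
        "record_id": record.record_id,
        "slice_id": record.slice_id,
        "animal_id": record.animal_id,
        "location_um": list(record.location),
        "noise_seed": record.noise_seed,
        "probe": dataclasses.asdict(record.probe),
        "protocol": dataclasses.asdict(record.protocol),
    }
    (directory / f"{record.record_id}.json").write_text(json.dumps(meta, indent=2))
    return csv_path


def read_record(csv_path: str | Path) -> IndentationRecord:
    """Read a record CSV and its JSON sidecar back into SI units."""
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    missing = set(RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"record file {csv_path} lacks columns {sorted(missing)}")
    sidecar = csv_path.with_suffix(".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"missing metadata sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    protocol = dict(meta["protocol"])
    protocol["fs_frequencies"] = tuple(protocol.get("fs_frequencies", ()))
    return IndentationRecord(
        time=df["time_s"].to_numpy(),
        depth=df["depth_um"].to_numpy() * 1e-6,
        load=df["load_nN"].to_numpy() * 1e-9,
        probe=ProbeSpec(**meta["probe"]),
        protocol=ProtocolSpec(**protocol),
        location=tuple(meta.get("location_um", (0.0, 0.0))),
        slice_id=meta.get("slice_id", "slice0"),
        animal_id=meta.get("animal_id", "animal0"),
        record_id=meta.get("record_id", csv_path.stem),
        noise_seed=meta.get("noise_seed"),
    )


def geometry_to_geojson(geometry: RegionGeometry, path: str | Path) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {"label": label},
            "geometry": mapping(poly),
        }
        for label, poly in geometry.regions
    ]
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, indent=2)
    )


def geometry_from_geojson(path: str | Path) -> RegionGeometry:
    doc = json.loads(Path(path).read_text())
    regions = []
    for feat in doc["features"]:
        label = feat["properties"]["label"]
        geom = shape(feat["geometry"])
        if not isinstance(geom, Polygon):
            raise ValueError(f"region {label!r}: only Polygon geometries are supported")
        regions.append((label, geom))
    return RegionGeometry(regions)


def phantom_from_dict(cfg: dict) -> TissuePhantom:
    """Build a phantom from a config mapping.

    Expected shape::

        background: {kind: elastic, E0: 1500}
        surface_offset_um: 20
        regions:
          - label: GCL
            polygon: [[0, 0], [200, 0], [200, 200], [0, 200]]   # um
            rheology: {kind: kelvin_voigt, E0: 800, eta: 15}
    """
    regions = []
    for reg in cfg.get("regions", []):
        regions.append(
            (
                reg["label"],
                Polygon(reg["polygon"]),
                RheologyModel(**reg["rheology"]),
            )
        )
    background = RheologyModel(**cfg.get("background", {"kind": "elastic", "E0": 1500.0}))
    return TissuePhantom(
        regions=regions,
        background=background,
        surface_offset=float(cfg.get("surface_offset_um", 20.0)) * 1e-6,
    )


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON run configuration document."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)
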