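"""Reading and writing measurement tables, TPS landmark files and reports.

Measurement tables are plain CSV (comma separator, ``.`` decimal, header row)
with lengths in millimetres. Landmark files follow the community TPS dialect
(``LM=<n>`` count line, ``n`` coordinate lines, optional ``ID=``/``IMAGE=``/
``SCALE=`` lines per specimen block). Reports are JSON.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    FormatError,
    IntegrityError,
    MalformedValueError,
    SchemaError,
)

log = logging.getLogger("scalemorph")

#: canonical length-variable names, in measurement order
ALL_VARIABLES = ("L1", "L2", "L3", "L4", "L5", "L6", "L7", "L8")

#: the subset that must be resolvable for the pipeline to run
REQUIRED_VARIABLES = ("L1", "L3", "L4", "L5", "L6")

#: the 16 squamation areas a record may carry as position metadata
VALID_AREAS = (
    "D1", "D2", "D3",
    "M1", "M2", "M3", "M4", "M5",
    "V1", "V2", "V3", "V4", "V5", "V6",
    "I", "II",
)


@dataclass
class ScaleRecord:
    """One measured scale: identifiers, lengths (mm) and optional metadata."""

    scale_id: str
    lengths: dict[str, float]
    specimen_id: str = ""
    area_label: str | None = None
    lateral_line: bool | None = None

    def __post_init__(self) -> None:
        for name, value in self.lengths.items():
            if name not in ALL_VARIABLES:
                raise SchemaError(f"unknown length variable {name!r}")
            if not math.isfinite(value) or value < 0:
                raise MalformedValueError(
                    f"length {name} of scale {self.scale_id!r} is {value!r}; "
                    "lengths must be finite and >= 0"
                )
        if self.area_label is not None and self.area_label not in VALID_AREAS:
            raise SchemaError(
                f"area_label {self.area_label!r} is not one of the 16 areas"
            )


@dataclass
class MeasurementTable:
    """An ordered collection of scale records sharing one variable set."""

    records: list[ScaleRecord]
    variable_names: tuple[str, ...]
    units: str = "mm"
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.scale_id in seen:
                raise IntegrityError(f"duplicate scale_id {rec.scale_id!r}")
            seen.add(rec.scale_id)
            missing = set(self.variable_names) - set(rec.lengths)
            if missing:
                raise IntegrityError(
                    f"scale {rec.scale_id!r} lacks variables {sorted(missing)}"
                )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def scale_ids(self) -> list[str]:
        return [rec.scale_id for rec in self.records]

    def matrix(self, variables: Sequence[str] | None = None) -> np.ndarray:
        """Return an (n, p) float array of the requested variables, row order preserved."""
        variables = tuple(variables if variables is not None else self.variable_names)
        missing = set(variables) - set(self.variable_names)
        if missing:
            raise SchemaError(f"variables not in table: {sorted(missing)}")
        return np.array(
            [[rec.lengths[v] for v in variables] for rec in self.records],
            dtype=float,
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.records:
            row: dict[str, object] = {"scale_id": rec.scale_id}
            if rec.specimen_id:
                row["specimen_id"] = rec.specimen_id
            row.update({v: rec.lengths[v] for v in self.variable_names})
            if rec.area_label is not None:
                row["area"] = rec.area_label
            if rec.lateral_line is not None:
                row["lateral_line"] = rec.lateral_line
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class LandmarkConfiguration:
    """Eleven labeled 2-D landmarks of one scale in crown view (indices 1-11)."""

    points: np.ndarray  # shape (n, 2), mm
    scale_id: str = ""
    view: str = "crown"
    conforming: bool = True  # False when the block did not have 11 landmarks

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise FormatError("landmark points must be an (n, 2) array")
        if not np.all(np.isfinite(self.points)):
            raise FormatError(f"non-finite landmark coordinate in {self.scale_id!r}")
        self.conforming = self.points.shape[0] == 11

    def landmark(self, index: int) -> np.ndarray:
        """1-based landmark accessor matching the anatomical numbering."""
        return self.points[index - 1]


# ---------------------------------------------------------------------------
# CSV measurement tables


def read_measurement_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
) -> MeasurementTable:
    """Read a CSV measurement table.

    ``schema`` maps canonical names (``scale_id``, ``L1`` ... ``L8``,
    ``specimen_id``, ``area``, ``lateral_line``) to the file's column names;
    canonical columns present under their own names need no entry. At least
    scale_id and the five required lengths (L1, L3, L4, L5, L6) must resolve.
    Malformed numeric cells are reported with their row numbers (1-based,
    excluding the header).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    schema = dict(schema or {})
    colmap: dict[str, str] = {}
    for canonical in ("scale_id", "specimen_id", "area", "lateral_line", *ALL_VARIABLES):
        source = schema.get(canonical, canonical)
        if source in df.columns:
            colmap[canonical] = source

    for required in ("scale_id", *REQUIRED_VARIABLES):
        if required not in colmap:
            raise SchemaError(
                f"required column {required!r} not resolvable in {path.name} "
                f"(have {list(df.columns)})"
            )

    variables = tuple(v for v in ALL_VARIABLES if v in colmap)
    bad: list[tuple[int, str]] = []
    records: list[ScaleRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        rowdict = dict(zip(df.columns, row))
        lengths: dict[str, float] = {}
        ok = True
        for v in variables:
            cell = rowdict[colmap[v]]
            if cell is None or (isinstance(cell, float) and math.isnan(cell)) or str(cell).strip() == "":
                if v in REQUIRED_VARIABLES:
                    bad.append((i, v))
                    ok = False
                continue
            try:
                value = float(cell)
            except (TypeError, ValueError):
                bad.append((i, v))
                ok = False
                continue
            if not math.isfinite(value):
                bad.append((i, v))
                ok = False
                continue
            lengths[v] = value
        if not ok:
            continue
        area = rowdict.get(colmap.get("area", ""), None)
        if isinstance(area, str):
            area = area.strip() or None
        lat = rowdict.get(colmap.get("lateral_line", ""), None)
        if isinstance(lat, str):
            lat = lat.strip().lower() in ("1", "true", "yes") if lat.strip() else None
        records.append(
            ScaleRecord(
                scale_id=str(rowdict[colmap["scale_id"]]),
                specimen_id=str(rowdict.get(colmap.get("specimen_id", ""), "") or ""),
                lengths=lengths,
                area_label=area,
                lateral_line=lat,
            )
        )

    if bad:
        locs = ", ".join(f"row {r} column {c}" for r, c in bad)
        raise MalformedValueError(
            f"{path.name}: malformed numeric cells at {locs}", locations=bad
        )
    return MeasurementTable(
        records=records, variable_names=variables, provenance=str(path)
    )


def write_measurement_table(table: MeasurementTable, path: str | Path) -> None:
    """Write a table back to CSV; full float precision so round-trips are exact."""
    df = table.to_frame()
    df.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# TPS landmark files


def read_tps(path: str | Path) -> list[LandmarkConfiguration]:
    """Parse a TPS landmark file into one configuration per specimen block.

    Coordinates are multiplied by the block's ``SCALE=`` factor when present.
    Blocks whose landmark count differs from 11 are parsed and returned but
    flagged non-conforming (``conforming=False``) with a logged warning; the
    morphometry stage skips them.
    """
    path = Path(path)
    lines = [ln.strip() for ln in path.read_text().splitlines()]
    configs: list[LandmarkConfiguration] = []
    i = 0
    block = 0
    while i < len(lines):
        if not lines[i]:
            i += 1
            continue
        block += 1
        if not lines[i].upper().startswith("LM="):
            raise FormatError(
                f"{path.name}: block {block} does not start with an LM= count line "
                f"(got {lines[i]!r})"
            )
        try:
            n = int(lines[i].split("=", 1)[1])
        except ValueError as exc:
            raise FormatError(f"{path.name}: unreadable LM count in block {block}") from exc
        i += 1
        coords: list[list[float]] = []
        while i < len(lines) and len(coords) < n:
            if not lines[i]:
                i += 1
                continue
            parts = lines[i].split()
            if len(parts) != 2:
                break
            try:
                coords.append([float(parts[0]), float(parts[1])])
            except ValueError:
                break
            i += 1
        if len(coords) != n:
            raise FormatError(
                f"{path.name}: block {block} declares LM={n} but has "
                f"{len(coords)} coordinate lines"
            )
        scale_id = ""
        factor = 1.0
        while i < len(lines) and lines[i] and "=" in lines[i] and not lines[i].upper().startswith("LM="):
            key, _, value = lines[i].partition("=")
            key = key.strip().upper()
            if key == "ID":
                scale_id = value.strip()
            elif key == "IMAGE" and not scale_id:
                scale_id = value.strip()
            elif key == "SCALE":
                factor = float(value)
            i += 1
        cfg = LandmarkConfiguration(
            points=np.asarray(coords) * factor, scale_id=scale_id or f"block{block}"
        )
        if not cfg.conforming:
            log.warning(
                "%s: block %d (%s) has %d landmarks, expected 11; "
                "excluded from morphometry",
                path.name, block, cfg.scale_id, n,
            )
        configs.append(cfg)
    return configs


# ---------------------------------------------------------------------------
# JSON reports


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return float(obj)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if obj is None or isinstance(obj, (str, bool)):
        return obj
    if hasattr(obj, "as_dict"):
        return _jsonable(obj.as_dict())
    raise TypeError(f"unserializable field of type {type(obj).__name__}: {obj!r}")


def write_report(result, path: str | Path) -> None:
    """Serialize a pipeline result (or any nested dict of results) to JSON.

    Keys are emitted in insertion order and floats at full precision, so a
    report read back and re-written is byte-identical.
    """
    payload = _jsonable(result if isinstance(result, dict) else result.as_dict())
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def read_config(path: str | Path) -> dict:
    """Read a YAML key-value run configuration."""
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: configuration must be a key-value mapping")
    return cfg
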