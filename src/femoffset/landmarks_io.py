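"""Landmark annotation data model and lossless CSV/JSON round-tripping.

A radiograph annotation is a set of clicked points, each with a role:

* ``medial_cortex`` / ``lateral_cortex`` — points along the two borders of the
  proximal femoral shaft (canonically 5 each), fitted with straight lines whose
  bisector defines the shaft axis;
* ``head`` — points around the projected femoral head (canonically 6), fitted
  with a circle whose centre is the head's centre of rotation;
* ``calibration`` — points on the rim of the in-plane metal calibration sphere
  (1-inch diameter), used to convert pixels to millimetres.

Pixel coordinates use the image convention (origin top-left, x rightward,
y downward); every downstream computation uses distances only, so the
convention is documentation rather than arithmetic.  ``rotation_deg`` is the
nominal actuator angle relative to the radiographically aligned neutral
(0 = trochanteric lines superimposed), negative for external rotation and
positive for internal rotation.

Numeric fields round-trip at full ``repr`` precision in both formats.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

from .errors import SchemaError, ValidationError

ROLES = ("medial_cortex", "lateral_cortex", "head", "calibration")

#: minimum point count per role for the fits to be uniquely defined
ROLE_MINIMA: Mapping[str, int] = {
    "medial_cortex": 2,
    "lateral_cortex": 2,
    "head": 3,
    "calibration": 3,
}

#: canonical counts used by the rater protocol and the simulator default
CANONICAL_COUNTS: Mapping[str, int] = {
    "medial_cortex": 5,
    "lateral_cortex": 5,
    "head": 6,
    "calibration": 5,
}

CSV_HEADER = ["specimen_id", "image_id", "rotation_deg", "role", "x_px", "y_px"]


@dataclass(frozen=True)
class LandmarkPoint:
    """One annotated point on one radiograph."""

    specimen_id: str
    image_id: str
    rotation_deg: float
    role: str
    x_px: float
    y_px: float

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValidationError(
                f"unknown landmark role {self.role!r}; expected one of {ROLES}"
            )
        for name in ("rotation_deg", "x_px", "y_px"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValidationError(f"{name} must be finite, got {v!r}")


@dataclass(frozen=True)
class LandmarkSet:
    """All annotated points for one radiograph, grouped by role."""

    specimen_id: str
    image_id: str
    rotation_deg: float
    points: tuple[LandmarkPoint, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        # canonical storage order: grouped by role (ROLES order), stable within
        # role, so CSV and JSON round-trips compare equal however rows were
        # interleaved on disk
        ordered = tuple(
            p for role in ROLES for p in self.points if p.role == role
        )
        object.__setattr__(self, "points", ordered)
        for p in self.points:
            if (p.specimen_id, p.image_id) != (self.specimen_id, self.image_id):
                raise ValidationError(
                    f"point {(p.specimen_id, p.image_id)} does not belong to "
                    f"image {(self.specimen_id, self.image_id)}"
                )
            if p.rotation_deg != self.rotation_deg:
                raise ValidationError(
                    f"point rotation {p.rotation_deg!r} disagrees with image "
                    f"rotation {self.rotation_deg!r} in {self.image_id!r}"
                )
        for role, minimum in ROLE_MINIMA.items():
            n = len(self.role_points(role))
            if 0 < n < minimum:
                raise ValidationError(
                    f"specimen {self.specimen_id!r} image {self.image_id!r}: "
                    f"role {role!r} has {n} points, needs >= {minimum}"
                )

    def role_points(self, role: str) -> list[LandmarkPoint]:
        if role not in ROLES:
            raise ValidationError(f"unknown landmark role {role!r}")
        return [p for p in self.points if p.role == role]

    def role_xy(self, role: str):
        """``(n, 2)`` float array of the points with the given role."""
        import numpy as np

        pts = self.role_points(role)
        return np.array([[p.x_px, p.y_px] for p in pts], dtype=float)

    def counts(self) -> dict[str, int]:
        return {role: len(self.role_points(role)) for role in ROLES}

    def require_roles(self, roles: Iterable[str]) -> None:
        """Raise unless every listed role meets its fit minimum."""
        for role in roles:
            n = len(self.role_points(role))
            if n < ROLE_MINIMA[role]:
                raise ValidationError(
                    f"specimen {self.specimen_id!r} image {self.image_id!r}: "
                    f"role {role!r} has {n} points, needs >= {ROLE_MINIMA[role]}"
                )


def _sets_from_points(points: Sequence[LandmarkPoint]) -> list[LandmarkSet]:
    """Group points into one LandmarkSet per (specimen_id, image_id), in file order."""
    order: list[tuple[str, str]] = []
    grouped: dict[tuple[str, str], list[LandmarkPoint]] = {}
    for p in points:
        key = (p.specimen_id, p.image_id)
        if key not in grouped:
            grouped[key] = []
            order.append(key)
        grouped[key].append(p)
    sets = []
    for key in order:
        pts = grouped[key]
        rotations = {p.rotation_deg for p in pts}
        if len(rotations) != 1:
            raise ValidationError(
                f"image {key} carries conflicting rotation_deg values {sorted(rotations)}"
            )
        sets.append(
            LandmarkSet(
                specimen_id=key[0],
                image_id=key[1],
                rotation_deg=pts[0].rotation_deg,
                points=tuple(pts),
            )
        )
    return sets


def _parse_float(text: str, column: str) -> float:
    try:
        return float(text)
    except ValueError as exc:
        raise SchemaError(f"column {column!r}: cannot parse {text!r} as a number") from exc


def read_landmarks(path: str | Path, format: Literal["csv", "json"] = "csv") -> list[LandmarkSet]:
    """Read landmark annotations, one :class:`LandmarkSet` per radiograph.

    Raises :class:`SchemaError` for structural problems (missing columns,
    unparsable numbers) and :class:`ValidationError` for domain violations
    (unknown role, fewer points than the role minimum).
    """
    path = Path(path)
    if format == "csv":
        with path.open(newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                return []
            missing = [c for c in CSV_HEADER if c not in reader.fieldnames]
            if missing:
                raise SchemaError(f"missing column(s) {missing} in {path}")
            points = [
                LandmarkPoint(
                    specimen_id=row["specimen_id"],
                    image_id=row["image_id"],
                    rotation_deg=_parse_float(row["rotation_deg"], "rotation_deg"),
                    role=row["role"],
                    x_px=_parse_float(row["x_px"], "x_px"),
                    y_px=_parse_float(row["y_px"], "y_px"),
                )
                for row in reader
            ]
        return _sets_from_points(points)
    if format == "json":
        with path.open(encoding="utf-8") as fh:
            data = json.load(fh)
        if not isinstance(data, list):
            raise SchemaError(f"{path}: top-level JSON value must be a list of images")
        points: list[LandmarkPoint] = []
        for entry in data:
            for key in ("specimen_id", "image_id", "rotation_deg", "points"):
                if key not in entry:
                    raise SchemaError(f"{path}: image object missing key {key!r}")
            for role, xy in entry["points"].items():
                for x, y in xy:
                    points.append(
                        LandmarkPoint(
                            specimen_id=entry["specimen_id"],
                            image_id=entry["image_id"],
                            rotation_deg=float(entry["rotation_deg"]),
                            role=role,
                            x_px=float(x),
                            y_px=float(y),
                        )
                    )
        return _sets_from_points(points)
    raise ValueError(f"unknown format {format!r}; expected 'csv' or 'json'")


def write_landmarks(
    sets: Iterable[LandmarkSet], path: str | Path, format: Literal["csv", "json"] = "csv"
) -> None:
    """Write landmark sets so that :func:`read_landmarks` round-trips bit-exactly."""
    path = Path(path)
    sets = list(sets)
    if format == "csv":
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(CSV_HEADER)
            for s in sets:
                for p in s.points:
                    writer.writerow(
                        [p.specimen_id, p.image_id, repr(p.rotation_deg), p.role,
                         repr(p.x_px), repr(p.y_px)]
                    )
        return
    if format == "json":
        payload = []
        for s in sets:
            grouped: dict[str, list[list[float]]] = {}
            for p in s.points:
                grouped.setdefault(p.role, []).append([p.x_px, p.y_px])
            payload.append(
                {
                    "specimen_id": s.specimen_id,
                    "image_id": s.image_id,
                    "rotation_deg": s.rotation_deg,
                    "points": grouped,
                }
            )
        with path.open("w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)
            fh.write("\n")
        return
    raise ValueError(f"unknown format {format!r}; expected 'csv' or 'json'")
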