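"""Reading and writing annotation and measurement files.

Annotation JSON: a list of objects, one per hip::

    {"dog_id": ..., "side": "left"|"right",
     "head_boundary": [[x, y], ...],
     "proximal_margin": [[x, y], ...],
     "distal_margin": [[x, y], ...],
     "rim_point": [x, y],
     "contra_head_centre": [x, y] | null}

A long-format CSV dialect is also read, with columns
``dog_id, side, landmark_role, point_index, x, y`` where ``landmark_role``
is one of head_boundary, proximal_margin, distal_margin, rim_point,
contra_head_centre.

Measurement CSV columns: dog_id, side, examiner, session, fnt, fhd, fnti,
na (na may be empty), optionally plus a grade column.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .geometry import GeometryError, HipAnnotation, HipMeasurement, Margin, Point2D

LANDMARK_ROLES = (
    "head_boundary",
    "proximal_margin",
    "distal_margin",
    "rim_point",
    "contra_head_centre",
)

MEASUREMENT_COLUMNS = ["dog_id", "side", "examiner", "session", "fnt", "fhd", "fnti", "na"]


class AnnotationFormatError(ValueError):
    """Malformed annotation record; the message names the offending record."""


def _annotation_from_dict(obj: dict, where: str) -> HipAnnotation:
    try:
        contra = obj.get("contra_head_centre")
        return HipAnnotation(
            dog_id=str(obj["dog_id"]),
            side=str(obj["side"]),
            head_boundary=np.asarray(obj["head_boundary"], dtype=float),
            proximal_margin=Margin(np.asarray(obj["proximal_margin"], dtype=float)),
            distal_margin=Margin(np.asarray(obj["distal_margin"], dtype=float)),
            rim_point=Point2D(*map(float, obj["rim_point"])),
            contra_head_centre=None if contra is None else Point2D(*map(float, contra)),
        )
    except (KeyError, TypeError, ValueError, GeometryError) as err:
        raise AnnotationFormatError(f"{where}: {err}") from err


def read_annotations_json(path: str | Path) -> list[HipAnnotation]:
    data = json.loads(Path(path).read_text())
    if isinstance(data, dict):
        data = [data]
    return [
        _annotation_from_dict(obj, f"{path} record {i}") for i, obj in enumerate(data)
    ]


def write_annotations_json(annotations: Iterable[HipAnnotation], path: str | Path) -> None:
    out = []
    for ann in annotations:
        contra = ann.contra_head_centre
        out.append(
            {
                "dog_id": ann.dog_id,
                "side": ann.side,
                "head_boundary": ann.head_boundary.tolist(),
                "proximal_margin": ann.proximal_margin.points.tolist(),
                "distal_margin": ann.distal_margin.points.tolist(),
                "rim_point": [ann.rim_point.x, ann.rim_point.y],
                "contra_head_centre": None if contra is None else [contra.x, contra.y],
            }
        )
    Path(path).write_text(json.dumps(out, indent=1))


def read_annotations_csv(path: str | Path) -> list[HipAnnotation]:
    """Read the long-format landmark CSV dialect."""
    df = pd.read_csv(path)
    required = {"dog_id", "side", "landmark_role", "point_index", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise AnnotationFormatError(f"{path}: missing columns {sorted(missing)}")
    bad = set(df["landmark_role"]) - set(LANDMARK_ROLES)
    if bad:
        raise AnnotationFormatError(f"{path}: unknown landmark roles {sorted(bad)}")
    annotations = []
    for (dog_id, side), hip in df.groupby(["dog_id", "side"], sort=True):
        obj: dict = {"dog_id": dog_id, "side": side}
        for role, part in hip.groupby("landmark_role"):
            pts = part.sort_values("point_index")[["x", "y"]].to_numpy(dtype=float)
            if role in ("rim_point", "contra_head_centre"):
                obj[role] = pts[0].tolist()
            else:
                obj[role] = pts
        annotations.append(_annotation_from_dict(obj, f"{path} hip {dog_id}/{side}"))
    return annotations


def measurements_to_frame(measurements: Sequence[HipMeasurement]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "dog_id": m.dog_id,
                "side": m.side,
                "examiner": m.examiner,
                "session": m.session,
                "fnt": m.fnt,
                "fhd": m.fhd,
                "fnti": m.fnti,
                "na": m.na,
            }
            for m in measurements
        ],
        columns=MEASUREMENT_COLUMNS,
    )


def write_measurements_csv(measurements: Sequence[HipMeasurement] | pd.DataFrame, path: str | Path) -> None:
    df = (
        measurements
        if isinstance(measurements, pd.DataFrame)
        else measurements_to_frame(measurements)
    )
    df.to_csv(path, index=False)


def read_measurements_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("examiner", "session", "fnti") if c not in df.columns]
    if missing:
        raise AnnotationFormatError(f"{path}: measurement CSV missing columns {missing}")
    return df
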