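"""File formats: single-channel images, annotation JSON, feature/patient CSV.

Annotation documents are JSON, one per image::

    {
      "image_id": "...",
      "onh": {"cx": ..., "cy": ..., "diameter": ...},
      "bifurcations": [
        {"apex": [x, y], "parent_end": [x, y],
         "child_a_end": [x, y], "child_b_end": [x, y],
         "seeds": [{"center": [x, y], "axis_angle": ..,
                    "length": .., "initial_width": ..}, ...x3],
         "vessel_type": "arteriole" | "venule"},
        ...
      ]
    }
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .types import (
    BifurcationAnnotation,
    BifurcationGeometry,
    OnhReference,
    Point2D,
    RectangleSeed,
)


def load_image(path: str | Path) -> np.ndarray:
    """Load a PNG/TIFF image as a 2-D float array.

    RGB(A) images are reduced to their green channel, the channel fundus
    vessel work conventionally measures on.
    """
    with Image.open(path) as im:
        arr = np.asarray(im)
    if arr.ndim == 3:
        arr = arr[..., 1]
    return arr.astype(float)


def save_image(path: str | Path, image: np.ndarray) -> None:
    """Save a 2-D array as an 8- or 16-bit single-channel PNG/TIFF."""
    arr = np.asarray(image)
    if arr.dtype not in (np.uint8, np.uint16):
        arr = np.clip(np.rint(arr), 0, 255).astype(np.uint8)
    Image.fromarray(arr).save(path)


def _point(obj) -> Point2D:
    return Point2D(float(obj[0]), float(obj[1]))


def load_annotations(path: str | Path) -> tuple[str, OnhReference, list[BifurcationAnnotation]]:
    doc = json.loads(Path(path).read_text())
    onh = OnhReference(
        center=Point2D(float(doc["onh"]["cx"]), float(doc["onh"]["cy"])),
        diameter=float(doc["onh"]["diameter"]),
    )
    image_id = str(doc["image_id"])
    annotations = []
    for b in doc["bifurcations"]:
        seeds = tuple(
            RectangleSeed(
                center=_point(s["center"]),
                axis_angle=float(s["axis_angle"]),
                length=float(s["length"]),
                initial_width=float(s["initial_width"]),
                label=s.get("label", ""),
            )
            for s in b["seeds"]
        )
        annotations.append(BifurcationAnnotation(
            apex=_point(b["apex"]),
            parent_end=_point(b["parent_end"]),
            child_a_end=_point(b["child_a_end"]),
            child_b_end=_point(b["child_b_end"]),
            seeds=seeds,  # type: ignore[arg-type]
            vessel_type=str(b["vessel_type"]),
            image_id=image_id,
        ))
    return image_id, onh, annotations


def save_annotations(
    path: str | Path,
    image_id: str,
    onh: OnhReference,
    annotations: list[BifurcationAnnotation],
) -> None:
    doc = {
        "image_id": image_id,
        "onh": {"cx": onh.center.x, "cy": onh.center.y, "diameter": onh.diameter},
        "bifurcations": [
            {
                "apex": [a.apex.x, a.apex.y],
                "parent_end": [a.parent_end.x, a.parent_end.y],
                "child_a_end": [a.child_a_end.x, a.child_a_end.y],
                "child_b_end": [a.child_b_end.x, a.child_b_end.y],
                "seeds": [
                    {"center": [s.center.x, s.center.y],
                     "axis_angle": s.axis_angle, "length": s.length,
                     "initial_width": s.initial_width, "label": s.label}
                    for s in a.seeds
                ],
                "vessel_type": a.vessel_type,
            }
            for a in annotations
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def geometry_to_frame(
    records: list[BifurcationGeometry],
    image_id: str,
    patient_id: str | None = None,
) -> pd.DataFrame:
    """One row per measured bifurcation, including usability flags."""
    rows = []
    for i, g in enumerate(records):
        row = {"patient_id": patient_id if patient_id is not None else image_id,
               "image_id": image_id, "bifurcation_id": i}
        row.update(g.as_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def load_patients(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["patient_id"] = df["patient_id"].astype(str)
    for col in ("hypertension", "high_cholesterol", "progressor"):
        if col in df.columns:
            df[col] = df[col].map(
                {True: True, False: False, "True": True, "False": False,
                 1: True, 0: False, "1": True, "0": False}
            )
    return df


def load_features(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["patient_id"] = df["patient_id"].astype(str)
    df["image_id"] = df["image_id"].astype(str)
    return df
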