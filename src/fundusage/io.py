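"""Reading and writing the pipeline's file formats.

* Landmark JSON, one file per image:
  ``{"image": str, "laterality": "right"|"left", "fovea": [x, y],
  "disc_boundary": [[x, y], ...], "crossings": {"st_artery": [x, y],
  "it_artery": [x, y], "st_vein": [x, y], "it_vein": [x, y]}}``
  with 0-based floating-point pixel coordinates.
* Feature table CSV: columns ``id``, optionally ``age``, then the 42 feature
  names in their frozen order; UTF-8 with a header row.
* Images: 8-bit RGB PNG or TIFF, via imageio.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .colorimetry import FEATURE_NAMES, FeatureVector, as_image
from .errors import SchemaError
from .geometry import LandmarkSet, Point2D
from .lasso import CohortTable

__all__ = [
    "read_image",
    "read_landmarks",
    "write_landmarks",
    "features_to_frame",
    "write_feature_csv",
    "read_feature_csv",
]


def read_image(path) -> np.ndarray:
    """Load an 8-bit RGB raster (PNG/TIFF), dropping any alpha channel."""
    arr = iio.imread(path)
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    try:
        return as_image(arr)
    except ValueError as exc:
        raise SchemaError(f"{path}: {exc}") from exc


def read_landmarks(path) -> LandmarkSet:
    """Parse one landmark JSON file into a validated :class:`LandmarkSet`."""
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    try:
        crossings = data["crossings"]
        return LandmarkSet(
            fovea=Point2D(*data["fovea"]),
            disc_boundary=tuple(Point2D(*p) for p in data["disc_boundary"]),
            crossing_st_artery=Point2D(*crossings["st_artery"]),
            crossing_it_artery=Point2D(*crossings["it_artery"]),
            crossing_st_vein=Point2D(*crossings["st_vein"]),
            crossing_it_vein=Point2D(*crossings["it_vein"]),
            laterality=data["laterality"],
        )
    except (KeyError, TypeError) as exc:
        raise SchemaError(f"{path}: malformed landmark file ({exc})") from exc


def write_landmarks(path, landmarks: LandmarkSet, image: str = "") -> None:
    data = {
        "image": image,
        "laterality": landmarks.laterality,
        "fovea": list(landmarks.fovea),
        "disc_boundary": [list(p) for p in landmarks.disc_boundary],
        "crossings": {k: list(v) for k, v in landmarks.crossings.items()},
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(data, fh, indent=1, sort_keys=True)
        fh.write("\n")


def features_to_frame(rows: dict[str, FeatureVector], ages: dict[str, float] | None = None) -> pd.DataFrame:
    """Stack per-eye feature vectors (keyed by id) into the CSV layout."""
    ids = sorted(rows)
    frame = pd.DataFrame([rows[i].as_dict() for i in ids], columns=list(FEATURE_NAMES))
    if ages is not None:
        frame.insert(0, "age", [ages[i] for i in ids])
    frame.insert(0, "id", ids)
    return frame


def write_feature_csv(path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, index=False, float_format="%.10g")


def read_feature_csv(path, require_age: bool = False) -> CohortTable:
    """Load a feature-table CSV into a :class:`CohortTable`."""
    frame = pd.read_csv(path)
    if "id" not in frame.columns:
        raise SchemaError(f"{path}: missing required 'id' column")
    missing = [name for name in FEATURE_NAMES if name not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing feature columns {missing[:5]}{'...' if len(missing) > 5 else ''}")
    has_age = "age" in frame.columns
    if require_age and not has_age:
        raise SchemaError(f"{path}: an 'age' column is required for this operation")
    X = frame[list(FEATURE_NAMES)].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise SchemaError(f"{path}: feature table contains missing or non-finite values")
    return CohortTable(
        ids=tuple(frame["id"].astype(str)),
        X=X,
        feature_names=FEATURE_NAMES,
        y=frame["age"].to_numpy(dtype=float) if has_age else None,
    )
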