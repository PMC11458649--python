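"""Region colorimetry of a fundus photograph.

Samples mean red, green, and blue intensities inside circular regions of
interest (ROIs) and computes the tessellation fundus index (TFI),

    TFI = R / (R + G + B),

from the three region means. Higher TFI means a redder region — the raster
signature of a tessellated (choroid-visible) fundus. Together with the
landmark geometry this assembles the 42-parameter feature vector of one eye:
four vessel angles, the papillomacular position, the disc ovality ratio, and
R, G, B, TFI at nine locations (eight peripapillary compass points plus the
fovea).

Images are 8-bit RGB rasters used exactly as stored — no gamma linearization
or illumination correction. A pixel (integer column i, row j) belongs to an
ROI when its center-to-center distance to the ROI center is at most the ROI
radius; there is no partial-pixel weighting, so every mean is exactly
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .errors import OutOfBoundsError, UndefinedTFIError
from .geometry import (
    LOCATIONS,
    LandmarkSet,
    Point2D,
    RoiConfig,
    disc_geometry,
    pmp_angle,
    roi_layout,
    temporal_direction,
    vessel_angle,
)

__all__ = [
    "FEATURE_NAMES",
    "RegionColor",
    "FeatureVector",
    "as_image",
    "mean_rgb",
    "tfi",
    "extract_features",
]

#: The 42 feature names in their frozen order: geometry first, then the nine
#: locations channel by channel (R block, G block, B block, TFI block), each
#: block ordered temporal, supratemporal, superior, supranasal, nasal,
#: infranasal, inferior, infratemporal, fovea.
FEATURE_NAMES: tuple[str, ...] = (
    "st_ra",
    "it_ra",
    "st_rv",
    "it_rv",
    "pmp",
    "ovality",
    *(f"r_{loc}" for loc in LOCATIONS),
    *(f"g_{loc}" for loc in LOCATIONS),
    *(f"b_{loc}" for loc in LOCATIONS),
    *(f"tfi_{loc}" for loc in LOCATIONS),
)
assert len(FEATURE_NAMES) == 42


@dataclass(frozen=True)
class RegionColor:
    """Mean channel intensities and TFI of one sampled region."""

    location: str
    mean_r: float
    mean_g: float
    mean_b: float
    tfi: float


@dataclass(frozen=True)
class FeatureVector:
    """The 42 fundus parameters of one eye, in the frozen order."""

    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.values) != 42:
            raise ValueError(f"FeatureVector needs 42 values, got {len(self.values)}")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(FEATURE_NAMES, self.values))

    def __getitem__(self, name: str) -> float:
        return self.values[FEATURE_NAMES.index(name)]

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


def as_image(image: np.ndarray) -> np.ndarray:
    """Validate an 8-bit RGB raster and return it as an (H, W, 3) uint8 array."""
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB image, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        if np.issubdtype(arr.dtype, np.integer) and arr.min() >= 0 and arr.max() <= 255:
            arr = arr.astype(np.uint8)
        else:
            raise ValueError(f"expected 8-bit intensities in [0, 255], got dtype {arr.dtype}")
    return arr


def mean_rgb(
    image: np.ndarray, center: Point2D, radius: float
) -> tuple[float, float, float]:
    """Mean R, G, B over all pixels within ``radius`` of ``center``.

    The circle must lie entirely inside the image; a partially out-of-bounds
    ROI raises :class:`OutOfBoundsError` rather than silently clipping (a
    clipped mean would be biased toward the interior).
    """
    img = as_image(image)
    h, w = img.shape[:2]
    cx, cy = float(center[0]), float(center[1])
    if radius <= 0:
        raise ValueError("ROI radius must be positive")
    if cx - radius < 0 or cx + radius > w - 1 or cy - radius < 0 or cy + radius > h - 1:
        raise OutOfBoundsError(
            f"ROI circle at ({cx:.1f}, {cy:.1f}) r={radius:.1f} extends outside the "
            f"{w}x{h} image"
        )
    x0, x1 = int(np.floor(cx - radius)), int(np.ceil(cx + radius))
    y0, y1 = int(np.floor(cy - radius)), int(np.ceil(cy + radius))
    xs = np.arange(x0, x1 + 1)
    ys = np.arange(y0, y1 + 1)
    dist2 = (xs[None, :] - cx) ** 2 + (ys[:, None] - cy) ** 2
    mask = dist2 <= radius**2
    if not mask.any():
        raise OutOfBoundsError("ROI contains no pixel centers")
    patch = img[y0 : y1 + 1, x0 : x1 + 1, :].astype(float)
    means = patch[mask].mean(axis=0)
    return float(means[0]), float(means[1]), float(means[2])


def tfi(mean_r: float, mean_g: float, mean_b: float) -> float:
    """Tessellation fundus index R/(R+G+B) of the region means."""
    if mean_r < 0 or mean_g < 0 or mean_b < 0:
        raise ValueError("channel means must be non-negative")
    total = mean_r + mean_g + mean_b
    if total == 0:
        raise UndefinedTFIError("TFI undefined: R + G + B == 0")
    return mean_r / total


def region_colors(
    image: np.ndarray, landmarks: LandmarkSet, config: RoiConfig | None = None
) -> dict[str, RegionColor]:
    """Sample all nine regions; keys follow :data:`~fundusage.geometry.LOCATIONS`."""
    disc = disc_geometry(landmarks)
    temporal = temporal_direction(disc.center, landmarks.fovea)
    layout = roi_layout(disc, temporal, landmarks.fovea, config)
    out: dict[str, RegionColor] = {}
    for loc, center in layout.centers.items():
        try:
            r, g, b = mean_rgb(image, center, layout.roi_radius)
        except OutOfBoundsError as exc:
            raise OutOfBoundsError(f"{loc} ROI: {exc}") from exc
        out[loc] = RegionColor(loc, r, g, b, tfi(r, g, b))
    return out


def extract_features(
    image: np.ndarray, landmarks: LandmarkSet, config: RoiConfig | None = None
) -> FeatureVector:
    """Assemble the full 42-parameter feature vector for one eye."""
    disc = disc_geometry(landmarks)
    temporal = temporal_direction(disc.center, landmarks.fovea)
    colors = region_colors(image, landmarks, config)
    geometry_values = [
        vessel_angle(disc.center, landmarks.crossing_st_artery, temporal),
        vessel_angle(disc.center, landmarks.crossing_it_artery, temporal),
        vessel_angle(disc.center, landmarks.crossing_st_vein, temporal),
        vessel_angle(disc.center, landmarks.crossing_it_vein, temporal),
        pmp_angle(disc.center, landmarks.fovea, temporal),
        disc.ovality,
    ]
    values = (
        *geometry_values,
        *(colors[loc].mean_r for loc in LOCATIONS),
        *(colors[loc].mean_g for loc in LOCATIONS),
        *(colors[loc].mean_b for loc in LOCATIONS),
        *(colors[loc].tfi for loc in LOCATIONS),
    )
    return FeatureVector(values=values)
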