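"""Synthetic fundus data with known ground truth.

Two generators make the whole pipeline testable without any clinical data:

1. :func:`generate_cohort` draws feature-table cohorts whose feature–age
   correlation *signs* follow the published age correlations of the 42 fundus
   parameters (e.g. peripapillary blue intensity falls with age on the
   temporal side, red intensity rises everywhere). Magnitudes are calibrated
   so the expected per-feature Pearson r matches the reported values, which
   span roughly 0–0.49. TFI columns are always recomputed from the generated
   R, G, B columns, never sampled independently, so their correlations are
   emergent. When ``age_noise_sd`` is set, the recorded age is an exact
   linear function of the stored features plus Gaussian noise of that SD —
   which gives leave-one-out MAE the closed-form target σ·√(2/π).

2. :func:`render_fundus` paints a fundus-like raster — blended background,
   nine constant-color sampling regions, an elliptical optic disc, a darker
   fovea, four vessel rays — together with the landmark set an annotator
   would produce. Region fills are constant and vessels stay inside the ROI
   ring, so extraction recovers the render truth to sub-degree / sub-unit
   accuracy by construction.

All randomness flows from one integer seed through one generator instance per
call; there is no global random state.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .colorimetry import FEATURE_NAMES
from .errors import RenderError
from .geometry import LOCATIONS, LandmarkSet, Point2D, RoiConfig
from .lasso import CohortTable

logger = logging.getLogger(__name__)

__all__ = [
    "AGE_CORRELATION_TARGETS",
    "CohortSpec",
    "RenderTruth",
    "generate_cohort",
    "sample_render_truth",
    "render_fundus",
    "make_fixture_suite",
]

#: Target marginal Pearson correlation with age for every *directly generated*
#: feature (geometry and the 27 channel means). Signs are the published
#: age-correlation pattern; e.g. blue temporal strongly negative, red inferior
#: positive. TFI columns are derived from R, G, B and have no entry here.
AGE_CORRELATION_TARGETS: dict[str, float] = {
    "pmp": 0.076,
    "ovality": 0.012,
    "st_ra": 0.086,
    "it_ra": 0.044,
    "st_rv": 0.058,
    "it_rv": 0.059,
    "r_temporal": 0.155,
    "r_supratemporal": 0.195,
    "r_superior": 0.266,
    "r_supranasal": 0.206,
    "r_nasal": 0.136,
    "r_infranasal": 0.298,
    "r_inferior": 0.267,
    "r_infratemporal": 0.158,
    "r_fovea": 0.253,
    "g_temporal": -0.051,
    "g_supratemporal": 0.064,
    "g_superior": 0.260,
    "g_supranasal": 0.255,
    "g_nasal": 0.203,
    "g_infranasal": 0.333,
    "g_inferior": 0.154,
    "g_infratemporal": -0.064,
    "g_fovea": 0.464,
    "b_temporal": -0.438,
    "b_supratemporal": -0.295,
    "b_superior": -0.052,
    "b_supranasal": 0.003,
    "b_nasal": 0.032,
    "b_infranasal": 0.046,
    "b_inferior": -0.223,
    "b_infratemporal": -0.442,
    "b_fovea": 0.458,
}

#: Typical values at the age-range midpoint (60 years): vessel angles in
#: degrees from the temporal horizontal, PMP in degrees, ovality ratio, and
#: 8-bit channel means of an orange-red fundus with a darker fovea.
DEFAULT_BASELINES: dict[str, float] = {
    "st_ra": 66.0,
    "it_ra": 71.0,
    "st_rv": 58.0,
    "it_rv": 63.0,
    "pmp": 5.0,
    "ovality": 1.18,
    "r_temporal": 198.0,
    "r_supratemporal": 195.0,
    "r_superior": 192.0,
    "r_supranasal": 190.0,
    "r_nasal": 188.0,
    "r_infranasal": 190.0,
    "r_inferior": 193.0,
    "r_infratemporal": 196.0,
    "r_fovea": 150.0,
    "g_temporal": 112.0,
    "g_supratemporal": 108.0,
    "g_superior": 105.0,
    "g_supranasal": 102.0,
    "g_nasal": 100.0,
    "g_infranasal": 103.0,
    "g_inferior": 106.0,
    "g_infratemporal": 110.0,
    "g_fovea": 72.0,
    "b_temporal": 62.0,
    "b_supratemporal": 58.0,
    "b_superior": 55.0,
    "b_supranasal": 52.0,
    "b_nasal": 50.0,
    "b_infranasal": 53.0,
    "b_inferior": 56.0,
    "b_infratemporal": 60.0,
    "b_fovea": 55.0,
}

#: Residual SDs around the age trend, in feature units.
DEFAULT_NOISE_SDS: dict[str, float] = {
    **{k: 7.0 for k in ("st_ra", "it_ra", "st_rv", "it_rv")},
    "pmp": 3.5,
    "ovality": 0.06,
    **{f"{ch}_{loc}": 8.0 for ch in "rgb" for loc in LOCATIONS},
}


def _slopes_from_targets(
    targets: dict[str, float], noise_sds: dict[str, float], age_sd: float
) -> dict[str, float]:
    """Slopes (feature units / year) giving expected Pearson r = target.

    With x = b + s·(age−60) + N(0, σ) and r = t/√(1+t²) for t = s·sd(age)/σ,
    the slope hitting a target r is s = σ/sd(age) · r/√(1−r²).
    """
    slopes = {}
    for name, r in targets.items():
        t = r / np.sqrt(1.0 - r * r)
        slopes[name] = t * noise_sds[name] / age_sd
    return slopes


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for one synthetic cohort.

    ``age_noise_sd`` is the SD (years) of the irreducible error when the
    recorded age is constructed as a linear function of the features; set it
    to ``None`` to record the latent sampling age itself.
    """

    n: int = 500
    age_range: tuple[float, float] = (40.0, 80.0)
    effect_slopes: dict[str, float] | None = None  # default: calibrated from targets
    noise_sds: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_NOISE_SDS))
    baselines: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BASELINES))
    age_noise_sd: float | None = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 10:
            raise ValueError("cohort size must be at least 10")
        if not self.age_range[1] > self.age_range[0]:
            raise ValueError("age_range must be increasing")
        if any(v < 0 for v in self.noise_sds.values()):
            raise ValueError("noise SDs must be non-negative")

    def resolved_slopes(self) -> dict[str, float]:
        if self.effect_slopes is not None:
            return dict(self.effect_slopes)
        age_sd = (self.age_range[1] - self.age_range[0]) / np.sqrt(12.0)
        return _slopes_from_targets(AGE_CORRELATION_TARGETS, self.noise_sds, age_sd)


_GENERATED = [n for n in FEATURE_NAMES if not n.startswith("tfi_")]  # 33 direct features


def generate_cohort(spec: CohortSpec) -> tuple[CohortTable, dict]:
    """Draw one cohort; returns the table and the generating truth.

    The truth dict records the slopes, noise SDs, per-feature expected
    correlation signs, and — when ``age_noise_sd`` is set — the exact linear
    weights ``w``/intercept ``c0`` such that age = c0 + X·w + N(0, σ).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    latent_age = rng.uniform(*spec.age_range, size=n)
    slopes = spec.resolved_slopes()
    noise = spec.noise_sds
    base = spec.baselines

    cols: dict[str, np.ndarray] = {}
    clipped = 0
    for name in _GENERATED:
        s = slopes.get(name, 0.0)
        x = base[name] + s * (latent_age - 60.0) + rng.normal(0.0, noise[name], size=n)
        if name.split("_")[0] in ("r", "g", "b"):
            inside = (x >= 0.0) & (x <= 255.0)
            clipped += int((~inside).sum())
            x = np.clip(x, 0.0, 255.0)
        cols[name] = x
    if clipped:
        logger.warning("clipped %d generated channel intensities into [0, 255]", clipped)

    for loc in LOCATIONS:  # TFI always recomputed from the stored channels
        r, g, b = cols[f"r_{loc}"], cols[f"g_{loc}"], cols[f"b_{loc}"]
        cols[f"tfi_{loc}"] = r / (r + g + b)

    X = np.column_stack([cols[name] for name in FEATURE_NAMES])

    weights = np.zeros(len(FEATURE_NAMES))
    sigma = spec.age_noise_sd
    denom = sum(slopes.get(nm, 0.0) ** 2 / noise[nm] ** 2 for nm in _GENERATED if noise[nm] > 0)
    if sigma is None or denom == 0.0:
        y = latent_age if sigma is None else latent_age + rng.normal(0.0, sigma, size=n)
        c0 = float("nan")
    else:
        # inverse-variance reconstruction of the latent age from the features:
        # w_j ∝ s_j/σ_j², normalized so Σ w_j s_j = 1, hence X·w tracks age 1:1
        for j, name in enumerate(FEATURE_NAMES):
            if name in _GENERATED and noise[name] > 0:
                weights[j] = (slopes.get(name, 0.0) / noise[name] ** 2) / denom
        c0 = 60.0 - float(weights @ np.array([base.get(nm, 0.0) for nm in FEATURE_NAMES]))
        y = c0 + X @ weights + rng.normal(0.0, sigma, size=n)

    table = CohortTable(
        ids=tuple(f"eye{i:05d}" for i in range(n)),
        X=X,
        feature_names=FEATURE_NAMES,
        y=y,
    )
    truth = {
        "slopes": slopes,
        "noise_sds": dict(noise),
        "baselines": dict(base),
        "expected_sign": {nm: float(np.sign(slopes.get(nm, 0.0))) for nm in _GENERATED},
        "expected_r": {
            nm: float(t / np.sqrt(1 + t**2))
            for nm, t in (
                (nm, slopes.get(nm, 0.0) * (spec.age_range[1] - spec.age_range[0]) / np.sqrt(12.0) / noise[nm])
                for nm in _GENERATED
                if noise[nm] > 0
            )
        },
        "weights": weights,
        "intercept": c0,
        "age_noise_sd": sigma,
        "latent_age": latent_age,
        "n_clipped": clipped,
    }
    return table, truth


# ---------------------------------------------------------------------------
# Image rendering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RenderTruth:
    """Exact ground truth behind one rendered image.

    The disc is an axis-aligned ellipse (``disc_semi_axes`` = (horizontal,
    vertical) semi-axes; real discs are vertically oval, so the vertical axis
    is the major one and ovality = vertical/horizontal). Vessel angles are in
    degrees from the temporal horizontal; ``pmp`` is signed (positive =
    fovea inferior). ``fovea`` must be consistent with ``pmp`` — use
    :func:`sample_render_truth` to construct consistent truths.
    """

    disc_center: Point2D
    fovea: Point2D
    disc_semi_axes: tuple[float, float]
    st_ra: float
    it_ra: float
    st_rv: float
    it_rv: float
    pmp: float
    region_rgb: dict[str, tuple[float, float, float]]
    laterality: str = "right"

    @property
    def ovality(self) -> float:
        ax, ay = self.disc_semi_axes
        return max(ax, ay) / min(ax, ay)

    def mean_disc_radius(self, n: int = 3600) -> float:
        """Mean center-to-boundary distance of the ellipse, sampled densely."""
        t = 2.0 * np.pi * np.arange(n) / n
        ax, ay = self.disc_semi_axes
        return float(np.hypot(ax * np.cos(t), ay * np.sin(t)).mean())


def sample_render_truth(
    rng: np.random.Generator,
    width: int = 560,
    height: int = 400,
    laterality: str | None = None,
) -> RenderTruth:
    """Draw a random, internally consistent render truth that fits the frame."""
    lat = laterality or ("right" if rng.random() < 0.5 else "left")
    tx = 1.0 if lat == "right" else -1.0
    radius = rng.uniform(38.0, 46.0)
    ovality = rng.uniform(1.05, 1.35)
    # vertical major axis; scale so the mean boundary distance equals `radius`
    t = 2.0 * np.pi * np.arange(3600) / 3600
    mean_unit = np.hypot(np.cos(t), ovality * np.sin(t)).mean()
    ax = radius / mean_unit
    ay = ovality * ax
    margin = 2.2 * radius + 6.0  # outer edge of the peripapillary ROI ring
    cy = rng.uniform(margin, height - margin)
    fovea_dist = 4.5 * radius
    pmp = rng.uniform(-12.0, 12.0)
    if tx > 0:
        cx = rng.uniform(margin, width - margin - fovea_dist - 0.6 * radius)
    else:
        cx = rng.uniform(margin + fovea_dist + 0.6 * radius, width - margin)
    fovea = Point2D(
        cx + tx * fovea_dist * np.cos(np.deg2rad(pmp)),
        cy + fovea_dist * np.sin(np.deg2rad(abs(pmp))) * np.sign(pmp),
    )
    region_rgb = {}
    for loc in LOCATIONS:
        base = (
            DEFAULT_BASELINES[f"r_{loc}"],
            DEFAULT_BASELINES[f"g_{loc}"],
            DEFAULT_BASELINES[f"b_{loc}"],
        )
        # integer-valued colors survive the 8-bit raster round trip exactly
        region_rgb[loc] = tuple(float(np.rint(np.clip(b + rng.normal(0, 6.0), 5, 250))) for b in base)
    return RenderTruth(
        disc_center=Point2D(cx, cy),
        fovea=fovea,
        disc_semi_axes=(ax, ay),
        st_ra=rng.uniform(55.0, 80.0),
        it_ra=rng.uniform(55.0, 80.0),
        st_rv=rng.uniform(45.0, 70.0),
        it_rv=rng.uniform(45.0, 70.0),
        pmp=pmp,
        region_rgb=region_rgb,
        laterality=lat,
    )


def _ray_direction(tx: float, angle_deg: float, inferior: bool) -> np.ndarray:
    """Unit direction at ``angle_deg`` from the temporal horizontal, on the
    superior (-y) or inferior (+y) side."""
    a = np.deg2rad(angle_deg)
    return np.array([tx * np.cos(a), np.sin(a) if inferior else -np.sin(a)])


def render_fundus(
    truth: RenderTruth,
    width: int = 560,
    height: int = 400,
    seed: int | None = None,
    noise_sd: float = 0.0,
    config: RoiConfig | None = None,
    n_boundary: int = 36,
) -> tuple[np.ndarray, LandmarkSet]:
    """Render the image and the landmark set an annotator would supply.

    The nine sampling disks are painted with constant colors slightly larger
    than the extraction radius, vessels are confined inside the ROI ring, and
    landmark coordinates are exact, so the extraction round trip recovers
    ``truth`` up to boundary-sampling error (and pixel noise if requested).
    """
    config = config or RoiConfig()
    cx, cy = truth.disc_center
    ax, ay = truth.disc_semi_axes
    radius = truth.mean_disc_radius()
    tx = 1.0 if truth.fovea.x > cx else -1.0
    roi_dist = config.center_dist_mult * radius
    roi_radius = config.roi_radius_mult * radius

    centers: dict[str, np.ndarray] = {}
    for k, loc in enumerate(LOCATIONS[:8]):
        ang = np.deg2rad(45.0 * k)
        centers[loc] = np.array([cx, cy]) + roi_dist * np.array([tx * np.cos(ang), -np.sin(ang)])
    centers["fovea"] = np.array(truth.fovea, dtype=float)

    paint_radius = roi_radius + 2.0
    for loc, c in centers.items():
        if (
            c[0] - paint_radius < 1
            or c[0] + paint_radius > width - 2
            or c[1] - paint_radius < 1
            or c[1] + paint_radius > height - 2
        ):
            raise RenderError(f"{loc} ROI does not fit inside the {width}x{height} frame")
    if cx - ax < 1 or cx + ax > width - 2 or cy - ay < 1 or cy + ay > height - 2:
        raise RenderError("optic disc does not fit inside the frame")

    ys, xs = np.mgrid[0:height, 0:width]
    img = np.zeros((height, width, 3), dtype=float)

    # background: inverse-square-distance blend of the nine region colors
    wsum = np.zeros((height, width))
    for loc, c in centers.items():
        d2 = (xs - c[0]) ** 2 + (ys - c[1]) ** 2 + (0.5 * roi_radius) ** 2
        w = 1.0 / d2
        img += w[..., None] * np.asarray(truth.region_rgb[loc])
        wsum += w
    img /= wsum[..., None]

    # constant-color sampling disks (painted larger than the sampling radius)
    for loc, c in centers.items():
        mask = (xs - c[0]) ** 2 + (ys - c[1]) ** 2 <= paint_radius**2
        img[mask] = np.asarray(truth.region_rgb[loc])

    # vessels: four rays from the disc center, confined inside the ROI ring
    vessel_len = 1.08 * radius
    vessel_specs = [
        (truth.st_ra, False, (150.0, 45.0, 45.0)),
        (truth.it_ra, True, (150.0, 45.0, 45.0)),
        (truth.st_rv, False, (110.0, 30.0, 35.0)),
        (truth.it_rv, True, (110.0, 30.0, 35.0)),
    ]
    box = int(np.ceil(vessel_len)) + 3
    x0, x1 = max(0, int(cx) - box), min(width, int(cx) + box + 1)
    y0, y1 = max(0, int(cy) - box), min(height, int(cy) + box + 1)
    bx, by = xs[y0:y1, x0:x1], ys[y0:y1, x0:x1]
    for angle, inferior, color in vessel_specs:
        d = _ray_direction(tx, angle, inferior)
        rel = np.stack([bx - cx, by - cy], axis=-1)
        t_along = np.clip(rel @ d, 0.0, vessel_len)
        perp = rel - t_along[..., None] * d
        mask = (perp**2).sum(-1) <= 1.5**2
        img[y0:y1, x0:x1][mask] = np.asarray(color)

    # optic disc ellipse on top of the vessels' origin
    disc_mask = ((xs - cx) / ax) ** 2 + ((ys - cy) / ay) ** 2 <= 1.0
    img[disc_mask] = np.asarray((235.0, 208.0, 160.0))

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    image = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    # landmarks: exact boundary sample, crossings on the rays, exact fovea
    t = 2.0 * np.pi * np.arange(n_boundary) / n_boundary
    boundary = tuple(
        Point2D(cx + ax * np.cos(tk), cy + ay * np.sin(tk)) for tk in t
    )
    cross_at = 1.05 * radius
    crossings = {}
    for name, (angle, inferior) in {
        "st_artery": (truth.st_ra, False),
        "it_artery": (truth.it_ra, True),
        "st_vein": (truth.st_rv, False),
        "it_vein": (truth.it_rv, True),
    }.items():
        d = _ray_direction(tx, angle, inferior)
        crossings[name] = Point2D(cx + cross_at * d[0], cy + cross_at * d[1])
    landmarks = LandmarkSet(
        fovea=truth.fovea,
        disc_boundary=boundary,
        crossing_st_artery=crossings["st_artery"],
        crossing_it_artery=crossings["it_artery"],
        crossing_st_vein=crossings["st_vein"],
        crossing_it_vein=crossings["it_vein"],
        laterality=truth.laterality,  # type: ignore[arg-type]
    )
    return image, landmarks


def make_fixture_suite(
    out_dir, seed: int = 0, n_images: int = 12, cohort_n: int = 200
) -> dict:
    """Write a small standard fixture set: rendered PNGs + landmark JSONs + a
    cohort CSV. Fully determined by ``seed``; returns a manifest of paths."""
    from .io import write_landmarks  # local import to avoid a cycle

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    image_paths, landmark_paths = [], []
    for i in range(n_images):
        truth = sample_render_truth(rng)
        image, landmarks = render_fundus(truth, seed=int(rng.integers(2**31)), noise_sd=2.0)
        img_path = out / f"img{i:03d}.png"
        lmk_path = out / f"img{i:03d}.json"
        iio.imwrite(img_path, image)
        write_landmarks(lmk_path, landmarks, image=img_path.name)
        image_paths.append(str(img_path))
        landmark_paths.append(str(lmk_path))

    table, _ = generate_cohort(CohortSpec(n=cohort_n, seed=int(rng.integers(2**31))))
    frame = pd.DataFrame(table.X, columns=list(table.feature_names))
    frame.insert(0, "age", table.y)
    frame.insert(0, "id", list(table.ids))
    csv_path = out / "cohort.csv"
    frame.to_csv(csv_path, index=False, float_format="%.10g")
    return {"images": image_paths, "landmarks": landmark_paths, "cohort_csv": str(csv_path)}
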