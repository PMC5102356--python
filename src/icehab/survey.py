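"""Survey-level statistics: per-scene summaries, aggregation, extrapolation.

A survey is a set of non-overlapping frames sampled over a fjord. Each
frame yields a :class:`SceneStats` row (class percentages, iceberg count,
sizes, angularity, distance to the glacier terminus); the survey is
summarized per variable (mean, SD, max, n) and the mean iceberg percentage
is extrapolated to the full fjord area with a two-source uncertainty
(classification + frame-edge scale distortion, combined in quadrature).
A seeded resampling check (repeated subsample means) verifies that the
sampled frames are representative of the fjord.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RBFInterpolator
from shapely.geometry import LineString, Point

from icehab.classify import BRASH, EXCLUDED, ICEBERG, WATER, ClassLabelMap

__all__ = [
    "GridSpec",
    "SceneStats",
    "SurveyStats",
    "UncertaintySpec",
    "aggregate_survey",
    "combine_uncertainty",
    "distance_to_terminus",
    "extrapolate_fjord",
    "interpolate_map",
    "representativeness_resample",
    "scene_stats",
]

EARTH_RADIUS_M = 6_371_000.0


@dataclass(frozen=True)
class SceneStats:
    """Per-frame classification summary.

    Percentages are over the non-excluded area and sum to 100; iceberg
    means are absent (None) when the scene holds no icebergs.
    """

    scene_id: str
    iceberg_pct: float
    brash_pct: float
    water_pct: float
    n_icebergs: int
    iceberg_area_m2: float
    mean_iceberg_size_m2: float | None
    mean_angularity: float | None
    scene_area_m2: float
    dist_to_terminus_km: float | None = None


@dataclass(frozen=True)
class SurveyStats:
    """Survey-level summary: per-variable mean/SD/max/n plus area totals.

    ``summary`` maps variable name -> (mean, sd, max, n). ``se_mean_frac``
    is the analytic standard error of the survey-mean iceberg *fraction*
    (SD of per-scene fractions over sqrt(n)).
    """

    summary: dict[str, tuple[float, float, float, int]]
    n_images: int
    total_iceberg_area_m2: float
    total_ice_area_m2: float
    se_mean_frac: float
    fjord_iceberg_area_m2: float | None = None
    uncertainty_m2: float | None = None


@dataclass(frozen=True)
class UncertaintySpec:
    """Two-source uncertainty on iceberg area.

    ``classification_frac``: fractional underestimate from icebergs
    misclassified as brash (0.26 at the operating point).
    ``distortion_frac``: bound on frame-edge scale distortion from the
    pinhole geometry of low-altitude frames (0.07). Combined in quadrature
    by default; an arithmetic-sum alternative is available.
    """

    classification_frac: float = 0.26
    distortion_frac: float = 0.07
    combination: str = "quadrature"

    def __post_init__(self) -> None:
        if self.classification_frac < 0 or self.distortion_frac < 0:
            raise ValueError("uncertainty fractions must be >= 0")
        if self.combination not in ("quadrature", "sum"):
            raise ValueError("combination must be 'quadrature' or 'sum'")


def scene_stats(
    class_map: ClassLabelMap,
    objects,
    pixel_size_m: float,
    scene_id: str = "",
    dist_to_terminus_km: float | None = None,
) -> SceneStats:
    """Summarize one classified scene.

    Percentages are computed over the non-excluded area; iceberg size and
    angularity are means over the scene's iceberg objects.
    """
    labels = class_map.labels
    n_domain = int((labels != EXCLUDED).sum())
    if n_domain == 0:
        raise ValueError("fully excluded scene")
    px_area = pixel_size_m**2
    frac = class_map.class_fractions()
    areas = [o.geometry.area_m2 for o in objects]
    angs = [o.geometry.angularity for o in objects]
    return SceneStats(
        scene_id=scene_id,
        iceberg_pct=100.0 * frac[ICEBERG],
        brash_pct=100.0 * frac[BRASH],
        water_pct=100.0 * frac[WATER],
        n_icebergs=len(objects),
        iceberg_area_m2=float(sum(areas)),
        mean_iceberg_size_m2=float(np.mean(areas)) if areas else None,
        mean_angularity=float(np.mean(angs)) if angs else None,
        scene_area_m2=n_domain * px_area,
        dist_to_terminus_km=dist_to_terminus_km,
    )


def distance_to_terminus(scene_center, terminus) -> float:
    """Great-circle-approximated distance (km) from a frame center to the
    glacier terminus polyline.

    ``scene_center`` is (lat, lon); ``terminus`` is a sequence of >= 2
    (lat, lon) vertices. Points are projected to a local equirectangular
    plane about the terminus' mean latitude (adequate at fjord scale),
    then the minimum point-to-segment distance is taken.
    """
    terminus = [(float(a), float(b)) for a, b in terminus]
    if len(terminus) < 2:
        raise ValueError("terminus polyline needs >= 2 vertices")
    lat0 = math.radians(np.mean([p[0] for p in terminus]))
    scale = EARTH_RADIUS_M * math.pi / 180.0

    def _xy(lat, lon):
        return (lon * scale * math.cos(lat0), lat * scale)

    line = LineString([_xy(lat, lon) for lat, lon in terminus])
    pt = Point(_xy(float(scene_center[0]), float(scene_center[1])))
    return pt.distance(line) / 1000.0


def aggregate_survey(stats: list[SceneStats]) -> SurveyStats:
    """Summarize a survey: per-variable mean, SD (n-1), max, n; area totals.

    Variables with no defined value in a scene (e.g. iceberg size when the
    scene has no icebergs) are summarized over the scenes where they are
    defined. A single-scene survey reports SD = 0 by convention.
    """
    if not stats:
        raise ValueError("need >= 1 scene")

    def _col(getter):
        vals = [getter(s) for s in stats]
        return np.array([v for v in vals if v is not None], dtype=float)

    variables = {
        "iceberg_pct": _col(lambda s: s.iceberg_pct),
        "brash_pct": _col(lambda s: s.brash_pct),
        "water_pct": _col(lambda s: s.water_pct),
        "mean_iceberg_size_m2": _col(lambda s: s.mean_iceberg_size_m2),
        "mean_angularity": _col(lambda s: s.mean_angularity),
        "dist_to_terminus_km": _col(lambda s: s.dist_to_terminus_km),
    }
    summary = {}
    for name, vals in variables.items():
        if vals.size == 0:
            continue
        sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        summary[name] = (float(vals.mean()), sd, float(vals.max()), int(vals.size))

    iceberg_areas = np.array([s.iceberg_area_m2 for s in stats])
    brash_areas = np.array([s.brash_pct / 100.0 * s.scene_area_m2 for s in stats])
    fracs = np.array([s.iceberg_pct / 100.0 for s in stats])
    n = len(stats)
    se = float(fracs.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    return SurveyStats(
        summary=summary,
        n_images=n,
        total_iceberg_area_m2=float(iceberg_areas.sum()),
        total_ice_area_m2=float(iceberg_areas.sum() + brash_areas.sum()),
        se_mean_frac=se,
    )


def extrapolate_fjord(mean_iceberg_pct: float, fjord_area_km2: float) -> float:
    """Fjord-wide iceberg area (m^2): mean scene percentage times fjord area."""
    if mean_iceberg_pct < 0 or fjord_area_km2 <= 0:
        raise ValueError("inputs must be positive")
    return mean_iceberg_pct / 100.0 * fjord_area_km2 * 1e6


def combine_uncertainty(spec: UncertaintySpec, round_digits: int | None = 2) -> float:
    """Combine the two uncertainty sources into one fraction.

    Quadrature by default: sqrt(a^2 + b^2); with the operating values
    (0.26, 0.07) this gives 0.2693, reported as 0.27 at the default
    2-decimal rounding (rounding configurable/disable-able).
    """
    if spec.combination == "quadrature":
        frac = math.hypot(spec.classification_frac, spec.distortion_frac)
    else:
        frac = spec.classification_frac + spec.distortion_frac
    if round_digits is not None:
        frac = round(frac, round_digits)
    return frac


def representativeness_resample(
    stats: list[SceneStats],
    n_trials: int = 100,
    sample_size: int = 40,
    seed: int = 0,
) -> tuple[np.ndarray, float, float]:
    """Check that sampled frames represent the fjord: repeated subsampling.

    Draws ``n_trials`` samples of ``sample_size`` scenes (without
    replacement within each trial, seeded) and records the mean iceberg
    percentage of each sample. Returns ``(trial_means, mean_of_means,
    se_of_mean)`` where ``se_of_mean`` is the analytic standard error of
    the full-survey mean iceberg *fraction* (SD of scene fractions over
    sqrt(n)).
    """
    n = len(stats)
    if sample_size > n:
        raise ValueError("sample_size exceeds the number of scenes")
    pcts = np.array([s.iceberg_pct for s in stats])
    rng = np.random.default_rng(seed)
    trial_means = np.array(
        [pcts[rng.choice(n, size=sample_size, replace=False)].mean() for _ in range(n_trials)]
    )
    fracs = pcts / 100.0
    se = float(fracs.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    return trial_means, float(trial_means.mean()), se


@dataclass(frozen=True)
class GridSpec:
    """Regular evaluation grid for interpolated cover maps (meter coords)."""

    x_min: float
    x_max: float
    y_min: float
    y_max: float
    nx: int = 100
    ny: int = 100

    def points(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        xs = np.linspace(self.x_min, self.x_max, self.nx)
        ys = np.linspace(self.y_min, self.y_max, self.ny)
        xx, yy = np.meshgrid(xs, ys)
        return xx, yy, np.column_stack([xx.ravel(), yy.ravel()])


def interpolate_map(
    points: np.ndarray,
    values: np.ndarray,
    grid_spec: GridSpec,
    kernel: str = "thin_plate_spline",
) -> np.ndarray:
    """Grid scattered per-frame values into a continuous cover surface.

    Exact radial-basis-function interpolation: the surface passes through
    every measured point (and may over/undershoot between them). Default
    kernel is the thin-plate spline.

    Raises on duplicate points with conflicting values (the system is
    then singular) and requires >= 3 non-collinear points.
    """
    points = np.asarray(points, dtype=float)
    values = np.asarray(values, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2:
        raise ValueError("points must be (n, 2)")
    if points.shape[0] < 3:
        raise ValueError("need >= 3 points")
    uniq, idx, counts = np.unique(points, axis=0, return_index=True, return_counts=True)
    if (counts > 1).any():
        for p in uniq[counts > 1]:
            dup = values[(points == p).all(axis=1)]
            if np.ptp(dup) > 0:
                raise ValueError("duplicate points with conflicting values")
        # consistent duplicates: deduplicate
        points, values = uniq, values[idx]
        if points.shape[0] < 3:
            raise ValueError("need >= 3 distinct points")
    spans = points.max(axis=0) - points.min(axis=0)
    d = points - points.mean(axis=0)
    if np.linalg.matrix_rank(d, tol=1e-9 * max(spans.max(), 1.0)) < 2:
        raise ValueError("points must not be collinear")
    rbf = RBFInterpolator(points, values, kernel=kernel)
    _, _, grid_pts = grid_spec.points()
    return rbf(grid_pts).reshape(grid_spec.ny, grid_spec.nx)
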