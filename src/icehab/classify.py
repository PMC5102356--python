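"""The ice classification rule set: one scene in, class map + icebergs out.

Pipeline for a scene (all parameters default to the operating rule set):

1. Derive the intensity channel from the enhanced RGB frame.
2. Contrast-split the domain into bright and dark objects; bright objects
   become candidate icebergs, dark objects stay unclassified.
3. Merge candidate icebergs into connected components and drop components
   below the minimum iceberg size (1000 px / 1.6 m^2 at 0.04 m — the area
   needed to support a hauled-out harbor seal); dropped pixels return to
   the unclassified pool.
4. Multi-resolution segmentation of the unclassified domain.
5. Per segment, GLCM homogeneity < 0.45 -> water, else brash ice; segments
   too small to carry texture -> brash (the mixed/ambiguous class).
6. Second contrast split within each candidate-iceberg component (water is
   excluded by construction): dark sub-objects -> brash, and remaining
   bright components are re-filtered by the size floor so "false icebergs"
   — clusters of small fragments bright enough to pass step 2 — break into
   constituent pieces. Survivors become icebergs with full geometry.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from icehab.features import (
    GLCMSpec,
    ObjectGeometry,
    object_geometry,
    quantize_intensity,
    segment_homogeneities,
)
from icehab.scene_io import SceneImage, rgb_to_intensity
from icehab.segmentation import (
    DegenerateDomainError,
    MRSParams,
    ThresholdSearchSpec,
    contrast_split,
    merge_connected,
    multiresolution_segmentation,
)

__all__ = [
    "BRASH",
    "EXCLUDED",
    "ICEBERG",
    "WATER",
    "ClassLabelMap",
    "IcebergObject",
    "RuleSetParams",
    "classify_scene",
    "classify_survey",
]

logger = logging.getLogger(__name__)

EXCLUDED = 0
WATER = 1
BRASH = 2
ICEBERG = 3

CLASS_NAMES = {EXCLUDED: "excluded", WATER: "water", BRASH: "brash", ICEBERG: "iceberg"}


@dataclass(frozen=True)
class RuleSetParams:
    """Tunable parameters of the classification rule set.

    Defaults reproduce the operating point: 1000-pixel / 1.6 m^2 iceberg
    floor, water homogeneity threshold 0.45, multi-resolution segmentation
    at scale 50 / shape 0.2 / compactness 0.5, and a second contrast split
    of candidate icebergs. At pixel sizes other than 0.04 m the m^2 floor
    governs (the pixel count is a resolution-specific proxy for the
    biological 1.6 m^2 constant).
    """

    min_iceberg_px: int = 1000
    min_iceberg_m2: float = 1.6
    water_homogeneity_max: float = 0.45
    mrs: MRSParams = field(default_factory=MRSParams)
    contrast_search: ThresholdSearchSpec = field(default_factory=ThresholdSearchSpec)
    glcm: GLCMSpec = field(default_factory=GLCMSpec)
    second_split: bool = True
    connectivity: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_iceberg_px <= 0:
            raise ValueError("min_iceberg_px must be positive")
        if not 0.0 < self.water_homogeneity_max < 1.0:
            raise ValueError("water_homogeneity_max must be in (0, 1)")

    def pixel_floor(self, pixel_size_m: float) -> int:
        """Minimum iceberg size in pixels at a given resolution."""
        floor = math.ceil(self.min_iceberg_m2 / pixel_size_m**2 - 1e-9)
        if abs(pixel_size_m - 0.04) < 1e-12:
            floor = max(floor, self.min_iceberg_px)
        return max(floor, 1)


@dataclass(frozen=True)
class ClassLabelMap:
    """Per-pixel class labels over {excluded, water, brash, iceberg}."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 2:
            raise ValueError("labels must be 2-D")
        if not np.isin(labels, [EXCLUDED, WATER, BRASH, ICEBERG]).all():
            raise ValueError("labels must be in {0, 1, 2, 3}")
        object.__setattr__(self, "labels", labels)

    def class_fractions(self) -> dict[int, float]:
        """Fraction of the non-excluded area per class."""
        labels = self.labels
        n = int((labels != EXCLUDED).sum())
        if n == 0:
            raise ValueError("fully excluded scene")
        return {
            cls: int((labels == cls).sum()) / n for cls in (WATER, BRASH, ICEBERG)
        }


@dataclass(frozen=True)
class IcebergObject:
    """One classified iceberg: pixel set plus geometry."""

    object_id: int
    rows: np.ndarray
    cols: np.ndarray
    geometry: ObjectGeometry

    @property
    def n_pixels(self) -> int:
        return self.rows.size

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[self.rows, self.cols] = True
        return m


def classify_scene(
    scene: SceneImage, params: RuleSetParams | None = None
) -> tuple[ClassLabelMap, list[IcebergObject]]:
    """Run the full rule set on one scene.

    Returns the class map (every non-excluded pixel classified) and the
    list of iceberg objects with geometry. A constant fully-dark scene
    yields zero icebergs and water/brash per the texture rule; a fully
    excluded scene is an error.
    """
    if params is None:
        params = RuleSetParams()
    domain = scene.domain_mask()
    if not domain.any():
        raise ValueError("non-excluded domain is empty")

    intensity = rgb_to_intensity(scene)
    values = intensity.values
    px_floor = params.pixel_floor(scene.pixel_size_m)

    # 2. first contrast split: bright -> candidate icebergs
    try:
        split = contrast_split(values, domain, params.contrast_search)
        candidate = split.bright_mask
    except DegenerateDomainError:
        # constant domain: treat as all-dark (no bright candidates)
        candidate = np.zeros(scene.shape, dtype=bool)

    # 3. merge candidates, enforce the size floor
    comp = merge_connected(candidate, params.connectivity)
    if comp.n_segments:
        sizes = np.bincount(comp.labels.ravel(), minlength=comp.n_segments + 1)
        keep = sizes >= px_floor
        keep[0] = False
        candidate = keep[comp.labels]

    # 4./5. segment the unclassified (dark) domain, label water vs brash
    labels = np.full(scene.shape, EXCLUDED, dtype=np.int32)
    unclassified = domain & ~candidate
    if unclassified.any():
        seg = multiresolution_segmentation(
            values, params.mrs, seed=params.seed, domain=unclassified
        )
        levels = quantize_intensity(values, params.glcm.n_levels)
        homog = segment_homogeneities(levels, seg.labels, seg.n_segments, params.glcm)
        # NaN homogeneity (no valid pair) -> brash, the conservative class
        is_water = np.zeros(seg.n_segments + 1, dtype=bool)
        with np.errstate(invalid="ignore"):
            is_water[1:] = homog < params.water_homogeneity_max
        inside = seg.labels > 0
        labels[inside] = np.where(is_water[seg.labels[inside]], WATER, BRASH)

    # 6. second contrast split within each candidate component
    icebergs: list[IcebergObject] = []
    if candidate.any():
        comp = merge_connected(candidate, params.connectivity)
        comp_labels = comp.labels
        final_iceberg = np.zeros(scene.shape, dtype=bool)
        for cid in range(1, comp.n_segments + 1):
            comp_mask = comp_labels == cid
            if params.second_split:
                try:
                    sub = contrast_split(values, comp_mask, params.contrast_search)
                    bright = sub.bright_mask
                except DegenerateDomainError:
                    bright = comp_mask  # constant bright component stays whole
                labels[comp_mask & ~bright] = BRASH
                sub_comp = merge_connected(bright, params.connectivity)
                if sub_comp.n_segments:
                    sizes = np.bincount(
                        sub_comp.labels.ravel(), minlength=sub_comp.n_segments + 1
                    )
                    keep = sizes >= px_floor
                    keep[0] = False
                    surv = keep[sub_comp.labels]
                    labels[bright & ~surv] = BRASH
                    final_iceberg |= surv
            else:
                final_iceberg |= comp_mask
        labels[final_iceberg] = ICEBERG

        final_comp = merge_connected(final_iceberg, params.connectivity)
        for cid in range(1, final_comp.n_segments + 1):
            mask = final_comp.labels == cid
            rows, cols = np.nonzero(mask)
            geom = object_geometry(mask, scene.pixel_size_m)
            icebergs.append(
                IcebergObject(
                    object_id=cid, rows=rows, cols=cols, geometry=geom
                )
            )

    labels[~domain] = EXCLUDED
    return ClassLabelMap(labels=labels), icebergs


def object_feature_table(
    scene: SceneImage,
    class_map: ClassLabelMap,
    objects: list[IcebergObject],
    glcm: GLCMSpec | None = None,
):
    """Per-iceberg feature table: id, class, size, geometry, texture.

    Returns a pandas DataFrame with columns object_id, class, n_pixels,
    area_m2, perimeter_m, angularity, homogeneity (NaN when the object is
    too small to carry texture).
    """
    import pandas as pd

    from icehab.features import UndefinedTextureError, glcm_homogeneity

    if glcm is None:
        glcm = GLCMSpec()
    intensity = rgb_to_intensity(scene)
    rows = []
    for obj in objects:
        mask = obj.mask(scene.shape)
        try:
            homog = glcm_homogeneity(intensity, mask, glcm)
        except UndefinedTextureError:
            homog = float("nan")
        rows.append(
            {
                "object_id": obj.object_id,
                "class": CLASS_NAMES[ICEBERG],
                "n_pixels": obj.n_pixels,
                "area_m2": obj.geometry.area_m2,
                "perimeter_m": obj.geometry.perimeter_m,
                "angularity": obj.geometry.angularity,
                "homogeneity": homog,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "object_id", "class", "n_pixels", "area_m2",
            "perimeter_m", "angularity", "homogeneity",
        ],
    )


def classify_survey(
    scenes, params: RuleSetParams | None = None, compute_stats: bool = True
):
    """Classify each scene of a survey independently.

    Per-scene failures are logged and skipped rather than aborting the
    batch; if every scene fails, an aggregate error is raised. Returns a
    list of ``(scene, class_map, icebergs, stats)`` tuples (stats ``None``
    when ``compute_stats`` is false).
    """
    from icehab.survey import scene_stats

    results = []
    errors = []
    for scene in scenes:
        try:
            class_map, objects = classify_scene(scene, params)
            stats = (
                scene_stats(
                    class_map, objects, scene.pixel_size_m, scene_id=scene.scene_id
                )
                if compute_stats
                else None
            )
            results.append((scene, class_map, objects, stats))
        except Exception as exc:  # noqa: BLE001 - per-scene isolation
            logger.warning("scene %s failed: %s", scene.scene_id, exc)
            errors.append((scene.scene_id, exc))
    if not results:
        raise RuntimeError(f"all {len(errors)} scenes failed classification")
    return results
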