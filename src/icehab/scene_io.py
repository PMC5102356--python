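"""Scene input/output: reading frames, enhancement, intensity, writers.

A *scene* is one non-overlapping aerial sampling frame: an RGB image with a
known pixel size in meters and optional geolocation (frame center
latitude/longitude, flying altitude). Scenes are standardized to a common
pixel size (0.04 m by default) with bilinear interpolation before
classification.

The photographic enhancement applied in the original workflow (contrast
stretch, vibrance, sharpening from an interactive photo editor) is mapped
here to three auditable operators applied in order: a linear contrast
expansion about mid-gray, a saturation boost weighted toward
low-saturation pixels, and an unsharp mask.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage
from skimage import color, measure, transform

__all__ = [
    "EnhanceParams",
    "IntensityImage",
    "SceneImage",
    "enhance",
    "iceberg_polygons",
    "load_metadata",
    "load_scene",
    "read_label_raster",
    "rgb_to_intensity",
    "standardize_resolution",
    "write_label_raster",
    "write_outputs",
]

#: PNG palette for label rasters; index = class code.
LABEL_PALETTE = {
    0: (0, 0, 0),  # excluded
    1: (30, 60, 140),  # water
    2: (160, 190, 210),  # brash ice
    3: (255, 255, 255),  # iceberg
}


@dataclass(frozen=True)
class SceneImage:
    """One aerial RGB frame with square pixels of known size in meters."""

    scene_id: str
    pixels: np.ndarray
    pixel_size_m: float
    center_lat: float | None = None
    center_lon: float | None = None
    altitude_m: float | None = None
    exclusion_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError("pixels must be an (H, W, 3) RGB grid")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("image must be non-empty")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValueError("channel values must lie in [0, 1]")
        if self.pixel_size_m <= 0:
            raise ValueError("pixel_size_m must be positive")
        if self.exclusion_mask is not None:
            m = np.asarray(self.exclusion_mask, dtype=bool)
            if m.shape != px.shape[:2]:
                raise ValueError("exclusion_mask shape must match pixels")
            object.__setattr__(self, "exclusion_mask", m)
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    def domain_mask(self) -> np.ndarray:
        """Boolean mask of pixels eligible for classification."""
        if self.exclusion_mask is None:
            return np.ones(self.shape, dtype=bool)
        return ~self.exclusion_mask


@dataclass(frozen=True)
class IntensityImage:
    """Single-channel brightness in [0, 1] derived from an RGB scene."""

    values: np.ndarray
    pixel_size_m: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("values must be 2-D")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class EnhanceParams:
    """Enhancement strengths; all zero means identity.

    ``contrast`` maps to a linear gain ``1 + contrast`` about 0.5 (0.2
    emulates a "+20" contrast slider); ``vibrance`` boosts saturation with
    weight ``1 - saturation`` so already-vivid pixels change little;
    ``sharpen_amount``/``sharpen_radius`` drive an unsharp mask with a
    Gaussian blur of the given sigma in pixels.
    """

    contrast: float = 0.2
    vibrance: float = 0.2
    sharpen_amount: float = 0.4
    sharpen_radius: float = 1.0

    def __post_init__(self) -> None:
        if self.contrast < 0 or self.vibrance < 0 or self.sharpen_amount < 0:
            raise ValueError("enhancement strengths must be non-negative")
        if self.sharpen_radius <= 0:
            raise ValueError("sharpen_radius must be positive")


def _to_unit(arr: np.ndarray) -> np.ndarray:
    """Rescale an integer image to [0, 1] by its dtype's full scale."""
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(float) / np.iinfo(arr.dtype).max
    return np.clip(arr.astype(float), 0.0, 1.0)


def load_metadata(path: str | Path) -> pd.DataFrame:
    """Read the per-scene metadata table (CSV), indexed by ``scene_id``.

    Expected columns: ``scene_id`` plus any of ``lat``, ``lon``,
    ``altitude_m``, ``pixel_size_m``, ``footprint_width_m``,
    ``footprint_height_m``.
    """
    df = pd.read_csv(path)
    if "scene_id" not in df.columns:
        raise ValueError("metadata must have a scene_id column")
    return df.set_index("scene_id", drop=False)


def load_scene(image_path: str | Path, metadata_row=None) -> SceneImage:
    """Load one scene image and attach its metadata.

    ``pixel_size_m`` must be present in the metadata or derivable as
    ``footprint_width_m / image width``. Missing geolocation is tolerated:
    the scene is still classifiable, only distance-to-terminus and mapping
    become unavailable.
    """
    image_path = Path(image_path)
    with Image.open(image_path) as im:
        arr = np.asarray(im.convert("RGB"))
    pixels = _to_unit(arr)

    meta = dict(metadata_row) if metadata_row is not None else {}

    def _get(key):
        v = meta.get(key)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return None
        return float(v)

    pixel_size = _get("pixel_size_m")
    if pixel_size is None:
        fw = _get("footprint_width_m")
        if fw is not None:
            pixel_size = fw / pixels.shape[1]
    if pixel_size is None:
        raise ValueError(
            f"{image_path.name}: pixel_size_m missing and not derivable from footprint"
        )
    if pixel_size <= 0:
        raise ValueError(f"{image_path.name}: non-positive pixel size")

    return SceneImage(
        scene_id=str(meta.get("scene_id", image_path.stem)),
        pixels=pixels,
        pixel_size_m=pixel_size,
        center_lat=_get("lat"),
        center_lon=_get("lon"),
        altitude_m=_get("altitude_m"),
    )


def standardize_resolution(
    scene: SceneImage, target_pixel_size_m: float = 0.04
) -> SceneImage:
    """Resample a scene to the target pixel size with bilinear interpolation.

    The output spans the same ground footprint; the new dimensions are
    ``floor(extent / target)``. A scene already at the target size is
    returned unchanged.
    """
    if target_pixel_size_m <= 0:
        raise ValueError("target pixel size must be positive")
    if scene.pixel_size_m == target_pixel_size_m:
        return scene
    h, w = scene.shape
    new_h = int(h * scene.pixel_size_m / target_pixel_size_m)
    new_w = int(w * scene.pixel_size_m / target_pixel_size_m)
    if new_h < 1 or new_w < 1:
        raise ValueError("target pixel size exceeds the scene footprint")
    resampled = transform.resize(
        scene.pixels, (new_h, new_w), order=1, anti_aliasing=False, clip=True
    )
    mask = None
    if scene.exclusion_mask is not None:
        mask = (
            transform.resize(
                scene.exclusion_mask.astype(float),
                (new_h, new_w),
                order=0,
                anti_aliasing=False,
            )
            > 0.5
        )
    return replace(
        scene,
        pixels=np.clip(resampled, 0.0, 1.0),
        pixel_size_m=target_pixel_size_m,
        exclusion_mask=mask,
    )


def enhance(scene: SceneImage, params: EnhanceParams | None = None) -> SceneImage:
    """Apply the deterministic enhancement sequence to a scene.

    Order: (1) linear contrast expansion about mid-gray, (2) vibrance-style
    saturation boost of low-saturation pixels, (3) unsharp mask. The output
    is clipped to [0, 1].
    """
    if params is None:
        params = EnhanceParams()
    px = scene.pixels

    if params.contrast > 0:
        px = 0.5 + (1.0 + params.contrast) * (px - 0.5)
        px = np.clip(px, 0.0, 1.0)

    if params.vibrance > 0:
        hsv = color.rgb2hsv(px)
        s = hsv[..., 1]
        hsv[..., 1] = np.clip(s * (1.0 + params.vibrance * (1.0 - s)), 0.0, 1.0)
        px = color.hsv2rgb(hsv)

    if params.sharpen_amount > 0:
        blurred = np.empty_like(px)
        for c in range(3):
            blurred[..., c] = ndimage.gaussian_filter(
                px[..., c], sigma=params.sharpen_radius
            )
        px = px + params.sharpen_amount * (px - blurred)
        px = np.clip(px, 0.0, 1.0)

    return replace(scene, pixels=px)


def rgb_to_intensity(scene: SceneImage) -> IntensityImage:
    """Intensity channel of the RGB-to-IHS transform: per-pixel channel mean.

    The three color channels of fjord scenes are highly correlated; the
    intensity channel alone suffices to delineate bright ice and dark
    water.
    """
    return IntensityImage(
        values=scene.pixels.mean(axis=2), pixel_size_m=scene.pixel_size_m
    )


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_label_raster(labels: np.ndarray, path: str | Path) -> Path:
    """Write a class label grid as a paletted PNG.

    Palette indices are the class codes themselves (0 excluded, 1 water,
    2 brash, 3 iceberg), so a read-back reproduces the grid exactly.
    """
    path = Path(path)
    labels = np.asarray(labels)
    im = Image.fromarray(labels.astype(np.uint8), mode="P")
    palette = []
    for i in range(256):
        palette.extend(LABEL_PALETTE.get(i, (0, 0, 0)))
    im.putpalette(palette)
    im.save(path)
    return path


def read_label_raster(path: str | Path) -> np.ndarray:
    """Read a label raster written by :func:`write_label_raster`."""
    with Image.open(path) as im:
        if im.mode != "P":
            raise ValueError("label raster must be a paletted PNG")
        return np.asarray(im).astype(np.int32)


def iceberg_polygons(objects, shape: tuple[int, int], pixel_size_m: float) -> list:
    """Trace each iceberg's outline as a polygon in meter coordinates.

    Outlines are marching-squares contours of the object mask at level 0.5,
    in (x=east, y=south-from-top) meters; intended for GeoJSON export and
    visualization, not for the perimeter metric (which uses the crack
    boundary).
    """
    polys = []
    for obj in objects:
        mask = obj.mask(shape)
        padded = np.pad(mask.astype(float), 1)
        contours = measure.find_contours(padded, 0.5)
        rings = [
            [
                (float((c - 1.0) * pixel_size_m), float((r - 1.0) * pixel_size_m))
                for r, c in contour
            ]
            for contour in contours
        ]
        polys.append(rings)
    return polys


def write_outputs(
    class_map,
    objects,
    stats,
    out_dir: str | Path,
    pixel_size_m: float | None = None,
) -> dict[str, Path]:
    """Write the per-scene products: label raster, iceberg GeoJSON, stats CSV.

    All inputs must come from the same scene. Returns the written paths
    keyed by product name.
    """
    from dataclasses import asdict

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    labels = np.asarray(getattr(class_map, "labels", class_map))
    ps = pixel_size_m if pixel_size_m is not None else getattr(stats, "pixel_size_m", None)
    scene_id = getattr(stats, "scene_id", "scene")

    raster_path = write_label_raster(labels, out_dir / f"{scene_id}_labels.png")

    features = []
    rings_list = iceberg_polygons(objects, labels.shape, ps or 1.0)
    for obj, rings in zip(objects, rings_list):
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "Polygon" if len(rings) == 1 else "MultiPolygon",
                    "coordinates": rings if len(rings) == 1 else [[r] for r in rings],
                },
                "properties": {
                    "object_id": obj.object_id,
                    "area_m2": obj.geometry.area_m2,
                    "angularity": obj.geometry.angularity,
                },
            }
        )
    geojson_path = out_dir / f"{scene_id}_icebergs.geojson"
    geojson_path.write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )

    csv_path = out_dir / f"{scene_id}_stats.csv"
    pd.DataFrame([asdict(stats)]).to_csv(csv_path, index=False)

    return {"label_raster": raster_path, "icebergs": geojson_path, "stats": csv_path}
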