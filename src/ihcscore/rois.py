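"""Reading, validating and rasterizing pathologist region annotations.

Annotations arrive as a GeoJSON FeatureCollection of polygons in image pixel
coordinates (origin top-left, x rightward, y downward), each carrying a
``label`` property that must be ``"tumor"`` or ``"background"``.  Multiple
polygons may share a label; they are unioned.  Rasterization follows the
pixel-center rule: pixel (row r, column c) belongs to a region iff the point
(c + 0.5, r + 0.5) lies inside the polygon union (even-odd rule).  Polygon
holes are not supported.

Tissue-free areas such as empty fat vacuoles are deliberately NOT excluded:
the scoring protocol measures every pixel inside an annotated region.  An
optional tissue filter (:func:`tissue_mask`) exists for diagnostics but is
off by default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import shapely
from shapely.geometry import Polygon
from shapely.ops import unary_union

from .errors import (
    AnnotationSchemaError,
    EmptyROIError,
    GeometryError,
    InvalidParameterError,
    OverlappingROIError,
)

VALID_LABELS = ("tumor", "background")

__all__ = [
    "ROI",
    "ROISet",
    "VALID_LABELS",
    "read_annotations",
    "write_annotations",
    "rasterize",
    "save_mask_png",
    "tissue_mask",
]


@dataclass(frozen=True)
class ROI:
    """A labeled polygon in pixel coordinates; the ring closes implicitly."""

    label: str
    vertices: np.ndarray  # (n, 2) array of (x, y)

    def __post_init__(self) -> None:
        if self.label not in VALID_LABELS:
            raise AnnotationSchemaError(
                f"unknown ROI label {self.label!r}; expected one of {VALID_LABELS}"
            )
        verts = np.asarray(self.vertices, dtype=np.float64)
        if verts.ndim != 2 or verts.shape[1] != 2 or verts.shape[0] < 3:
            raise GeometryError(
                f"ROI polygon needs >= 3 (x, y) vertices, got shape {verts.shape}"
            )
        if not np.all(np.isfinite(verts)):
            raise GeometryError("ROI vertices must be finite")
        poly = Polygon(verts)
        if not poly.is_valid or poly.area == 0:
            raise GeometryError(
                f"ROI polygon with label {self.label!r} is degenerate or self-intersecting"
            )
        object.__setattr__(self, "vertices", verts)

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)


@dataclass(frozen=True)
class ROISet:
    """Tumor and adjacent-healthy annotations, plus boolean masks once rasterized."""

    rois: tuple[ROI, ...]
    masks: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "rois", tuple(self.rois))

    def labels(self) -> tuple[str, ...]:
        return tuple(sorted({r.label for r in self.rois}))

    def polygons(self, label: str):
        return [r.polygon for r in self.rois if r.label == label]

    def mask(self, label: str) -> np.ndarray:
        if self.masks is None:
            raise InvalidParameterError("ROISet has not been rasterized yet")
        if label not in self.masks:
            raise InvalidParameterError(f"no mask for label {label!r}")
        return self.masks[label]

    def swapped_labels(self) -> "ROISet":
        """Tumor and background exchanged (used for ratio-symmetry checks)."""
        swap = {"tumor": "background", "background": "tumor"}
        rois = tuple(ROI(swap[r.label], r.vertices) for r in self.rois)
        masks = None
        if self.masks is not None:
            masks = {swap[k]: v for k, v in self.masks.items()}
        return ROISet(rois=rois, masks=masks)


def _parse_feature(index: int, feature: dict) -> ROI:
    if feature.get("type") != "Feature":
        raise AnnotationSchemaError(f"feature {index}: expected type 'Feature'")
    props = feature.get("properties") or {}
    label = props.get("label")
    if label is None:
        raise AnnotationSchemaError(f"feature {index}: missing 'label' property")
    if label not in VALID_LABELS:
        raise AnnotationSchemaError(
            f"feature {index}: unknown label {label!r}; expected one of {VALID_LABELS}"
        )
    geom = feature.get("geometry") or {}
    if geom.get("type") != "Polygon":
        raise AnnotationSchemaError(
            f"feature {index}: geometry must be a Polygon, got {geom.get('type')!r}"
        )
    rings = geom.get("coordinates") or []
    if len(rings) == 0:
        raise GeometryError(f"feature {index}: polygon has no rings")
    if len(rings) > 1:
        raise GeometryError(
            f"feature {index}: polygon holes (interior rings) are not supported"
        )
    ring = np.asarray(rings[0], dtype=np.float64)
    if ring.ndim != 2 or ring.shape[1] != 2:
        raise GeometryError(f"feature {index}: ring must be a list of [x, y] pairs")
    # GeoJSON rings repeat the first vertex; drop the closing duplicate.
    if ring.shape[0] >= 2 and np.allclose(ring[0], ring[-1]):
        ring = ring[:-1]
    if ring.shape[0] < 3:
        raise GeometryError(f"feature {index}: polygon needs at least 3 distinct vertices")
    try:
        return ROI(label=label, vertices=ring)
    except GeometryError as exc:
        raise GeometryError(f"feature {index}: {exc}") from exc


def read_annotations(path: str | Path) -> ROISet:
    """Read a GeoJSON FeatureCollection of labeled polygons (masks unset)."""
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise AnnotationSchemaError(
            f"{path}: expected a GeoJSON FeatureCollection, got {doc.get('type')!r}"
        )
    features = doc.get("features") or []
    if not features:
        raise AnnotationSchemaError(f"{path}: FeatureCollection has no features")
    rois = tuple(_parse_feature(i, f) for i, f in enumerate(features))
    return ROISet(rois=rois)


def write_annotations(roiset: ROISet, path: str | Path) -> None:
    """Write ROIs as a GeoJSON FeatureCollection in pixel coordinates."""
    features = []
    for roi in roiset.rois:
        ring = roi.vertices.tolist()
        ring.append(ring[0])  # close the ring per RFC 7946
        features.append(
            {
                "type": "Feature",
                "properties": {"label": roi.label},
                "geometry": {"type": "Polygon", "coordinates": [ring]},
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def _label_mask(polygons, height: int, width: int) -> np.ndarray:
    geom = unary_union(polygons)
    xs = np.arange(width, dtype=np.float64) + 0.5
    ys = np.arange(height, dtype=np.float64) + 0.5
    gx, gy = np.meshgrid(xs, ys)
    inside = shapely.contains_xy(geom, gx.ravel(), gy.ravel())
    return inside.reshape(height, width)


def rasterize(roiset: ROISet, height: int, width: int) -> ROISet:
    """Rasterize tumor and background polygons to boolean masks.

    Requires at least one polygon of each label; masks must be disjoint and
    non-empty within the image bounds.
    """
    if height < 1 or width < 1:
        raise InvalidParameterError(f"image dimensions must be positive, got {height}x{width}")
    present = {r.label for r in roiset.rois}
    missing = [lbl for lbl in VALID_LABELS if lbl not in present]
    if missing:
        raise AnnotationSchemaError(f"annotation set is missing label(s): {', '.join(missing)}")
    masks: dict[str, np.ndarray] = {}
    for label in VALID_LABELS:
        mask = _label_mask(roiset.polygons(label), height, width)
        if not mask.any():
            raise EmptyROIError(
                f"{label} mask is empty within the {height}x{width} image "
                "(polygon outside image bounds?)"
            )
        masks[label] = mask
    overlap = int(np.count_nonzero(masks["tumor"] & masks["background"]))
    if overlap:
        raise OverlappingROIError(
            f"tumor and background masks overlap on {overlap} pixel(s)"
        )
    return replace(roiset, masks=masks)


def save_mask_png(mask: np.ndarray, path: str | Path) -> None:
    """Export a boolean mask as an 8-bit PNG (0 outside, 255 inside)."""
    iio.imwrite(Path(path), (np.asarray(mask, bool) * np.uint8(255)))


def tissue_mask(pixels: np.ndarray, white_threshold: float = 248.0) -> np.ndarray:
    """Heuristic tissue detector: pixels whose channel minimum falls below a
    near-white threshold.  Diagnostics only — the scoring protocol keeps
    tissue-free pixels (fat vacuoles) inside the measured regions.
    """
    return np.asarray(pixels, dtype=np.float64).min(axis=-1) < white_threshold
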