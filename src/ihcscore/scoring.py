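"""The five-step objective DAB scoring protocol for one slide.

Given an RGB tile, pathologist ROIs and a stain model, the pipeline
(1) rasterizes the tumor and adjacent-healthy regions, (2) unmixes the image
and re-renders only the DAB channel, (3) collapses the rendered image to
grayscale, (4) inverts it so high values mean dense DAB deposition, and
(5) reports mean, standard deviation and pixel count per region, plus the
tumor-to-background ratio (TBR = tumor mean / background mean).  A TBR
below 1 — healthy tissue staining more than tumor — is legal and flagged.

Every pixel inside a region counts, including tissue-free holes; there is
no correction for cell density.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import matplotlib
import numpy as np

from .errors import EmptyROIError, InvalidParameterError, StateError, UndefinedTBRError
from .rois import ROISet, rasterize
from .stains import RGBImage, StainModel, deconvolve, render_stain, rgb_to_od

DEFAULT_GRAYSCALE_WEIGHTS = (1.0 / 3.0, 1.0 / 3.0, 1.0 / 3.0)
LUMINANCE_WEIGHTS = (0.299, 0.587, 0.114)

__all__ = [
    "GrayscaleRaster",
    "ROIStats",
    "SlideScore",
    "GradientMap",
    "to_grayscale",
    "invert",
    "measure_roi",
    "compute_tbr",
    "score_slide",
    "gradient_map",
    "DEFAULT_GRAYSCALE_WEIGHTS",
    "LUMINANCE_WEIGHTS",
]


@dataclass(frozen=True)
class GrayscaleRaster:
    """H x W raster in [0, 255]; when ``inverted`` high value = dense DAB."""

    values: np.ndarray
    inverted: bool = False

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=np.float64)
        if vals.ndim != 2:
            raise InvalidParameterError(f"expected 2-D raster, got shape {vals.shape}")
        if not np.all(np.isfinite(vals)) or vals.min() < 0 or vals.max() > 255:
            raise InvalidParameterError("grayscale values must be finite and within [0, 255]")
        object.__setattr__(self, "values", vals)


@dataclass(frozen=True)
class ROIStats:
    """Mean / sample SD / pixel count of inverted-grayscale intensity in a region."""

    mean: float
    sd: float
    n_pixels: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.mean <= 255.0):
            raise InvalidParameterError(f"mean {self.mean} outside [0, 255]")
        if self.sd < 0:
            raise InvalidParameterError(f"sd must be >= 0, got {self.sd}")
        if self.n_pixels < 1:
            raise InvalidParameterError("ROI must contain at least one pixel")


@dataclass(frozen=True)
class SlideScore:
    """Per-sample output of the scoring protocol."""

    sample_id: str
    biomarker: str
    tumor: ROIStats
    background: ROIStats
    tbr: float
    grayscale_weights: tuple[float, float, float] = DEFAULT_GRAYSCALE_WEIGHTS

    @property
    def below_unity(self) -> bool:
        """True when adjacent healthy tissue stained more than tumor."""
        return self.tbr < 1.0

    def as_row(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "biomarker": self.biomarker,
            "tumor_mean": self.tumor.mean,
            "tumor_sd": self.tumor.sd,
            "tumor_n": self.tumor.n_pixels,
            "bg_mean": self.background.mean,
            "bg_sd": self.background.sd,
            "bg_n": self.background.n_pixels,
            "tbr": self.tbr,
        }


@dataclass(frozen=True)
class GradientMap:
    """Color rendering of a scalar raster with its scaling bounds."""

    image: RGBImage
    vmin: float
    vmax: float
    colormap: str


def to_grayscale(
    image: RGBImage,
    weights: Sequence[float] = DEFAULT_GRAYSCALE_WEIGHTS,
) -> GrayscaleRaster:
    """Weighted channel average; weights must be non-negative and sum to 1.

    The default is the unweighted channel mean.  Luminance weights
    (:data:`LUMINANCE_WEIGHTS`) are available for workflows that prefer a
    perceptual conversion.
    """
    w = np.asarray(weights, dtype=np.float64)
    if w.shape != (3,) or np.any(w < 0):
        raise InvalidParameterError(f"weights must be 3 non-negative values, got {weights!r}")
    if abs(w.sum() - 1.0) > 1e-9:
        raise InvalidParameterError(f"grayscale weights must sum to 1, got {w.sum()!r}")
    return GrayscaleRaster(values=image.pixels @ w, inverted=False)


def invert(g: GrayscaleRaster) -> GrayscaleRaster:
    """Flip the intensity scale (255 - value) so high values mean dense DAB."""
    if g.inverted:
        raise StateError("raster is already inverted")
    return GrayscaleRaster(values=255.0 - g.values, inverted=True)


def measure_roi(g: GrayscaleRaster, mask: np.ndarray) -> ROIStats:
    """Mean and sample (n-1) standard deviation over the masked pixels."""
    if not g.inverted:
        raise StateError("measure_roi expects the inverted raster (step 4 before step 5)")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != g.values.shape:
        raise InvalidParameterError(
            f"mask shape {mask.shape} does not match raster shape {g.values.shape}"
        )
    vals = g.values[mask]
    if vals.size == 0:
        raise EmptyROIError("ROI mask selects no pixels")
    if vals.size == 1:
        warnings.warn("ROI contains a single pixel; SD reported as 0", stacklevel=2)
        return ROIStats(mean=float(vals[0]), sd=0.0, n_pixels=1)
    return ROIStats(
        mean=float(vals.mean()),
        sd=float(vals.std(ddof=1)),
        n_pixels=int(vals.size),
    )


def compute_tbr(tumor: ROIStats, background: ROIStats) -> float:
    """Tumor mean divided by adjacent-healthy mean.

    Zero background mean makes the ratio undefined (an error, not infinity).
    """
    if background.mean == 0:
        raise UndefinedTBRError("background mean intensity is 0; TBR undefined")
    return tumor.mean / background.mean


def _step(n: int, name: str):
    """Context wrapper tagging stage failures with their protocol step."""

    class _StepContext:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, Exception):
                exc.args = (f"step {n} ({name}): {exc.args[0] if exc.args else ''}",) + exc.args[1:]
            return False

    return _StepContext()


def score_slide(
    image: RGBImage,
    roiset: ROISet,
    model: StainModel,
    *,
    sample_id: str = "",
    biomarker: str = "",
    grayscale_weights: Sequence[float] = DEFAULT_GRAYSCALE_WEIGHTS,
    i0: float | Sequence[float] = 255.0,
    eps: float = 1.0,
    stain: str = "dab",
    keep_intermediates: bool = False,
) -> SlideScore | tuple[SlideScore, dict]:
    """Run the full five-step protocol on one slide.

    Measurement happens on the grayscale-inverted re-rendered single-stain
    image (mirroring the protocol's step order), not directly on the raw
    density channel.  With ``keep_intermediates=True`` the intermediate
    rasters are returned for audit alongside the score.
    """
    h, w = image.shape
    with _step(1, "ROI rasterization"):
        if roiset.masks is None:
            roiset = rasterize(roiset, h, w)
        tumor_mask = roiset.mask("tumor")
        bg_mask = roiset.mask("background")
        if tumor_mask.shape != (h, w):
            raise InvalidParameterError(
                f"mask shape {tumor_mask.shape} does not match image shape {(h, w)}"
            )
    with _step(2, "stain separation"):
        od = rgb_to_od(image, i0=i0, eps=eps)
        density = deconvolve(od, model)
        dab = density.channel(stain)
        rendered = render_stain(dab, model.stain_vector(stain), i0=i0, bit_depth=image.bit_depth)
    with _step(3, "grayscale conversion"):
        gray = to_grayscale(rendered, weights=grayscale_weights)
    with _step(4, "inversion"):
        inv = invert(gray)
    with _step(5, "ROI measurement"):
        tumor_stats = measure_roi(inv, tumor_mask)
        bg_stats = measure_roi(inv, bg_mask)
        tbr = compute_tbr(tumor_stats, bg_stats)
    score = SlideScore(
        sample_id=sample_id,
        biomarker=biomarker,
        tumor=tumor_stats,
        background=bg_stats,
        tbr=tbr,
        grayscale_weights=tuple(float(x) for x in np.asarray(grayscale_weights)),
    )
    if keep_intermediates:
        return score, {
            "density": density,
            "rendered_stain": rendered,
            "grayscale": gray,
            "inverted": inv,
        }
    return score


def gradient_map(
    values: np.ndarray | GrayscaleRaster,
    colormap: str = "viridis",
) -> GradientMap:
    """Render a scalar raster through a perceptually monotone colormap.

    Values are min-max scaled; the bounds are recorded in the result.  A
    constant raster renders at the colormap midpoint with a warning.
    """
    arr = values.values if isinstance(values, GrayscaleRaster) else np.asarray(values, np.float64)
    if arr.ndim != 2 or not np.all(np.isfinite(arr)):
        raise InvalidParameterError("gradient_map expects a finite 2-D raster")
    vmin, vmax = float(arr.min()), float(arr.max())
    if vmax == vmin:
        warnings.warn("constant raster: rendering at colormap midpoint", stacklevel=2)
        scaled = np.full(arr.shape, 0.5)
    else:
        scaled = (arr - vmin) / (vmax - vmin)
    cmap = matplotlib.colormaps[colormap]
    rgba = cmap(scaled)
    rgb = np.clip(np.rint(rgba[..., :3] * 255.0), 0, 255)
    return GradientMap(
        image=RGBImage(pixels=rgb, bit_depth=8),
        vmin=vmin,
        vmax=vmax,
        colormap=colormap,
    )
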