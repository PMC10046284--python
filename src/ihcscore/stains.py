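"""Color deconvolution of brightfield histology images.

A transmitted-light image of a stained section follows the Beer–Lambert law:
the optical density of each RGB channel is (to good approximation) a linear
combination of the densities of the individual chromogens, weighted by each
stain's characteristic absorbance vector.  Unmixing therefore reduces to a
3x3 linear solve per pixel once the stain vectors are known.  This module
implements the forward transform (RGB -> optical density), the unmixing
(optical density -> per-stain density), and the re-rendering of a single
stain channel back into RGB, which is how the brown DAB signal is isolated
before intensity measurement.

Stain vectors are never estimated from data here; they come from a preset
(``data/stain_presets.yaml``) or are supplied explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import tifffile
import yaml

from .errors import InvalidParameterError, SingularStainMatrixError

__all__ = [
    "RGBImage",
    "ODImage",
    "StainModel",
    "StainDensityImage",
    "rgb_to_od",
    "build_stain_model",
    "deconvolve",
    "render_stain",
    "load_stain_preset",
    "available_presets",
    "hdab_model",
]


@dataclass(frozen=True)
class RGBImage:
    """An H x W x 3 raster of red/green/blue intensities in [0, 255].

    ``bit_depth`` is 8 for ordinary scanner output (integral values); the
    string ``"continuous"`` marks a real-valued raster used when quantization
    must not limit numerical checks.
    """

    pixels: np.ndarray
    bit_depth: int | str = 8

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 3 or px.shape[2] != 3 or px.shape[0] < 1 or px.shape[1] < 1:
            raise InvalidParameterError(f"expected H x W x 3 raster, got shape {px.shape}")
        if not np.all(np.isfinite(px)):
            raise InvalidParameterError("pixel values must be finite")
        if px.min() < 0 or px.max() > 255:
            raise InvalidParameterError(
                f"pixel values outside [0, 255]: min={px.min():.3f} max={px.max():.3f}"
            )
        if self.bit_depth not in (8, "continuous"):
            raise InvalidParameterError(f"bit_depth must be 8 or 'continuous', got {self.bit_depth!r}")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    def to_uint8(self) -> np.ndarray:
        return np.clip(np.rint(self.pixels), 0, 255).astype(np.uint8)

    @classmethod
    def load(cls, path: str | Path) -> "RGBImage":
        """Read a PNG or baseline TIFF tile as an 8-bit RGB image."""
        path = Path(path)
        if path.suffix.lower() in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        else:
            arr = iio.imread(path)
        arr = np.asarray(arr)
        if arr.ndim == 2:
            arr = np.stack([arr] * 3, axis=-1)
        if arr.shape[-1] == 4:  # drop alpha
            arr = arr[..., :3]
        return cls(arr.astype(np.float64), bit_depth=8)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix.lower() in (".tif", ".tiff"):
            tifffile.imwrite(path, self.to_uint8())
        else:
            iio.imwrite(path, self.to_uint8())


@dataclass(frozen=True)
class ODImage:
    """Per-channel optical density (-log10 transmittance), non-negative."""

    od: np.ndarray
    i0: np.ndarray

    def __post_init__(self) -> None:
        od = np.asarray(self.od, dtype=np.float64)
        i0 = np.broadcast_to(np.asarray(self.i0, dtype=np.float64), (3,)).copy()
        if not np.all(np.isfinite(od)):
            raise InvalidParameterError("optical densities must be finite")
        object.__setattr__(self, "od", od)
        object.__setattr__(self, "i0", i0)


@dataclass(frozen=True)
class StainModel:
    """Named stain absorbance vectors and the matching 3x3 unmixing matrix.

    ``stain_matrix`` holds the row-normalized (unit Euclidean norm) stain
    vectors; ``unmix_matrix`` is its inverse, applied to OD triples to
    recover per-stain densities.
    """

    names: tuple[str, ...]
    raw_vectors: np.ndarray
    stain_matrix: np.ndarray
    unmix_matrix: np.ndarray

    def stain_index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise InvalidParameterError(
                f"stain {name!r} not in model (has {', '.join(self.names)})"
            ) from None

    def stain_vector(self, name: str) -> np.ndarray:
        return self.stain_matrix[self.stain_index(name)]


@dataclass(frozen=True)
class StainDensityImage:
    """Per-stain density rasters aligned with ``stain_names``."""

    density: np.ndarray  # H x W x n_stains
    stain_names: tuple[str, ...]

    def channel(self, name: str) -> np.ndarray:
        try:
            idx = self.stain_names.index(name)
        except ValueError:
            raise InvalidParameterError(
                f"stain {name!r} not present (has {', '.join(self.stain_names)})"
            ) from None
        return self.density[..., idx]


def rgb_to_od(
    image: RGBImage,
    i0: float | Sequence[float] = 255.0,
    eps: float = 1.0,
) -> ODImage:
    """Convert transmitted intensities to optical density.

    ``od[c] = -log10((pixel[c] + eps) / (i0[c] + eps))`` clipped below at 0,
    so blank glass (pixel == i0) maps to exactly zero density.  ``eps`` keeps
    the logarithm finite at fully absorbed (zero-intensity) pixels; the
    default of one 8-bit gray level matches the blank-glass convention of
    255-count scanners.
    """
    i0_arr = np.broadcast_to(np.asarray(i0, dtype=np.float64), (3,))
    if np.any(i0_arr <= 0):
        raise InvalidParameterError(f"i0 must be positive, got {i0_arr}")
    if not eps > 0:
        raise InvalidParameterError(f"eps must be positive, got {eps}")
    od = -np.log10((image.pixels + eps) / (i0_arr + eps))
    return ODImage(od=np.clip(od, 0.0, None), i0=i0_arr)


def _complete_third_vector(v1: np.ndarray, v2: np.ndarray) -> np.ndarray:
    """Orthogonal complement of two unit stain vectors, made physical.

    The cross product gives the direction; negative components are zeroed
    (absorbances cannot be negative) and the result re-normalized.
    """
    v3 = np.cross(v1, v2)
    v3 = np.where(v3 < 0, 0.0, v3)
    norm = np.linalg.norm(v3)
    if norm < 1e-12:
        raise SingularStainMatrixError(
            "cannot complete third stain vector: first two vectors are collinear"
        )
    return v3 / norm


def build_stain_model(
    raw_vectors: Sequence[Sequence[float]],
    names: Sequence[str],
) -> StainModel:
    """Build a stain model from two or three RGB absorbance triples.

    Rows are normalized to unit Euclidean norm.  When only two stains are
    supplied the third row is completed as the (non-negative, re-normalized)
    orthogonal complement of the first two and named ``"residual"``.
    """
    raw = np.asarray(raw_vectors, dtype=np.float64)
    names = list(names)
    if raw.shape not in ((2, 3), (3, 3)):
        raise InvalidParameterError(f"expected 2 or 3 stain vectors of length 3, got shape {raw.shape}")
    if len(names) != raw.shape[0]:
        raise InvalidParameterError("number of names must match number of vectors")
    if np.any(raw < 0):
        raise InvalidParameterError("stain absorbance vectors must be non-negative")
    norms = np.linalg.norm(raw, axis=1)
    if np.any(norms <= 0):
        raise InvalidParameterError("each stain vector must have positive norm")
    rows = raw / norms[:, None]
    if rows.shape[0] == 2:
        rows = np.vstack([rows, _complete_third_vector(rows[0], rows[1])])
        names = names + ["residual"]
    # Pairwise collinearity check gives a clearer error than a bare inversion failure.
    for i in range(3):
        for j in range(i + 1, 3):
            if abs(abs(float(rows[i] @ rows[j])) - 1.0) < 1e-10:
                raise SingularStainMatrixError(
                    f"stain vectors {names[i]!r} and {names[j]!r} are collinear"
                )
    cond = np.linalg.cond(rows)
    if not np.isfinite(cond) or cond > 1e12:
        raise SingularStainMatrixError(f"stain matrix is singular (condition number {cond:.3g})")
    unmix = np.linalg.inv(rows)
    return StainModel(
        names=tuple(names),
        raw_vectors=raw,
        stain_matrix=rows,
        unmix_matrix=unmix,
    )


def deconvolve(od: ODImage, model: StainModel, clip_negative: bool = True) -> StainDensityImage:
    """Unmix an optical-density image into per-stain densities.

    Small negative densities arise from noise and stain-model mismatch;
    they are clipped to zero by default because densities are physical
    concentrations.  Pass ``clip_negative=False`` for diagnostics.
    """
    arr = np.asarray(od.od)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise InvalidParameterError(f"expected H x W x 3 OD raster, got shape {arr.shape}")
    density = arr @ model.unmix_matrix
    if clip_negative:
        density = np.clip(density, 0.0, None)
    return StainDensityImage(density=density, stain_names=model.names)


def render_stain(
    density: np.ndarray,
    stain_vector: Sequence[float],
    i0: float | Sequence[float] = 255.0,
    bit_depth: int | str = 8,
) -> RGBImage:
    """Re-render a single stain density field as an RGB image.

    Inverts Beer–Lambert for one stain: ``channel[c] = i0[c] * 10**(-v[c] * d)``.
    In 8-bit mode values are rounded to the integer grid; continuous mode
    keeps real values for quantization-free analysis.
    """
    d = np.asarray(density, dtype=np.float64)
    if np.any(d < 0):
        raise InvalidParameterError("stain densities must be non-negative for rendering")
    v = np.asarray(stain_vector, dtype=np.float64)
    if v.shape != (3,):
        raise InvalidParameterError(f"stain vector must have 3 components, got shape {v.shape}")
    i0_arr = np.broadcast_to(np.asarray(i0, dtype=np.float64), (3,))
    pixels = i0_arr * np.power(10.0, -d[..., None] * v)
    pixels = np.clip(pixels, 0.0, 255.0)
    if bit_depth == 8:
        pixels = np.clip(np.rint(pixels), 0, 255)
    return RGBImage(pixels=pixels, bit_depth=bit_depth)


def available_presets() -> dict[str, dict]:
    """Parsed contents of the bundled stain-preset config."""
    text = resources.files("ihcscore").joinpath("data/stain_presets.yaml").read_text()
    return yaml.safe_load(text)


def load_stain_preset(name: str = "hdab") -> StainModel:
    """Build a :class:`StainModel` from a named preset in the bundled config."""
    presets = available_presets()
    if name not in presets:
        raise InvalidParameterError(
            f"unknown stain preset {name!r}; available: {', '.join(sorted(presets))}"
        )
    stains = presets[name]["stains"]
    return build_stain_model(list(stains.values()), list(stains.keys()))


def hdab_model() -> StainModel:
    """The hematoxylin / eosin / DAB model used throughout the pipeline."""
    return load_stain_preset("hdab")
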