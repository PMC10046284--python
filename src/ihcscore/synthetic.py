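"""Seeded synthetic H-DAB slides with known ground truth.

The study tissue this package targets is not publicly deposited, so testing
and calibration rest on phantoms: Beer–Lambert forward renderings of a
hematoxylin counterstain plus a DAB chromogen whose density differs between
a central elliptical "tumor" and a surrounding annular "adjacent healthy"
region, separated by a thin unannotated border band.  The phantoms are
statistical, not morphological — no nuclei or fascicles — but they carry the
features the scoring chain is sensitive to: within-region texture (so ROI
standard deviations are realistic), Gaussian optical-density pixel noise,
8-bit quantization, and empty fat vacuoles (white tissue-free holes inside
the healthy region that deliberately stay part of the measurements).

Cohort presets encode a 17-case cohort per biomarker with an 11/6
preoperative-therapy split.  Each case has a deterministic target for the
inverted-grayscale tumor intensity and for the tumor-to-background ratio;
DAB densities are obtained by inverting the noiseless scoring map with
bracketed root-finding, so recovering the targets through the full pipeline
is a genuine round trip through the image domain.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.optimize import brentq

from .errors import CalibrationError, InvalidParameterError, PhantomSpecError
from .rois import ROI, ROISet, rasterize, write_annotations
from .scoring import DEFAULT_GRAYSCALE_WEIGHTS
from .stains import RGBImage, StainModel, hdab_model

__all__ = [
    "PhantomSpec",
    "SyntheticSlide",
    "CaseTarget",
    "CohortPreset",
    "PRESETS",
    "COHORT_CHARACTERISTICS",
    "inverted_gray_of_density",
    "calibrate_dab",
    "forward_model",
    "default_geometry",
    "simulate_cohort",
    "build_cohort",
    "get_preset",
]

# Default counterstain density (OD units along the hematoxylin vector): a
# moderate, spatially uniform nuclear counterstain.
DEFAULT_HEMATOXYLIN_DENSITY = 0.3
DEFAULT_NOISE_SD = 0.03  # OD units
DEFAULT_VACUOLE_FRACTION = 0.05
_DAB_DENSITY_CEILING = 10.0  # physically plausible upper OD density bound


# ---------------------------------------------------------------------------
# Closed-form scoring map and its inverse
# ---------------------------------------------------------------------------

def inverted_gray_of_density(
    d: float | np.ndarray,
    model: StainModel | None = None,
    stain: str = "dab",
    weights: Sequence[float] = DEFAULT_GRAYSCALE_WEIGHTS,
) -> float | np.ndarray:
    """Noiseless inverted-grayscale intensity of a pure stain density.

    f(d) = 255 * (1 - sum_c w_c * 10**(-v_c * d)) — the composition of
    single-stain rendering, grayscale conversion and inversion, without
    quantization.  Strictly increasing in d for any stain vector with a
    positive component.
    """
    model = model or hdab_model()
    v = model.stain_vector(stain)
    w = np.asarray(weights, dtype=np.float64)
    d_arr = np.asarray(d, dtype=np.float64)
    trans = np.power(10.0, -np.multiply.outer(d_arr, v)) @ w
    out = 255.0 * (1.0 - trans)
    return float(out) if np.isscalar(d) or d_arr.ndim == 0 else out


def calibrate_dab(
    target_intensity: float,
    model: StainModel | None = None,
    stain: str = "dab",
    weights: Sequence[float] = DEFAULT_GRAYSCALE_WEIGHTS,
    d_max: float = _DAB_DENSITY_CEILING,
) -> float:
    """Invert the noiseless scoring map: find d with |f(d) - target| <= 1e-6.

    Uses bracketed root-finding on the monotone closed form.  Targets at or
    above the attainable ceiling f(d_max) raise a calibration error stating
    that maximum.
    """
    model = model or hdab_model()
    f = lambda d: inverted_gray_of_density(d, model, stain, weights)
    attainable = f(d_max)
    if target_intensity < 0 or target_intensity >= attainable:
        raise CalibrationError(
            f"target intensity {target_intensity} outside attainable range "
            f"[0, {attainable:.6f}) for stain {stain!r}"
        )
    if target_intensity == 0:
        return 0.0
    d = brentq(lambda x: f(x) - target_intensity, 0.0, d_max, xtol=1e-12, rtol=8.9e-16)
    if abs(f(d) - target_intensity) > 1e-6:
        raise CalibrationError(f"root-finding did not converge for target {target_intensity}")
    return float(d)


# ---------------------------------------------------------------------------
# Phantom specification and forward model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomSpec:
    """Complete, seed-deterministic recipe for one synthetic slide.

    ``dab_density_tumor`` / ``dab_density_background`` are the mean DAB
    densities of the two regions; the texture amplitudes modulate a smooth
    seeded field around those means (density units, 1 SD within the ROI).
    Regenerating from an identical spec reproduces the image bit-for-bit.
    """

    height: int
    width: int
    tumor_polygon: np.ndarray
    background_polygons: tuple[np.ndarray, ...]
    dab_density_tumor: float
    dab_density_background: float
    hematoxylin_density: float = DEFAULT_HEMATOXYLIN_DENSITY
    texture_amplitude_tumor: float = 0.0
    texture_amplitude_background: float = 0.0
    pixel_noise_sd: float = DEFAULT_NOISE_SD
    vacuole_fraction: float = DEFAULT_VACUOLE_FRACTION
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise PhantomSpecError(f"canvas must be positive, got {self.height}x{self.width}")
        for name in (
            "dab_density_tumor",
            "dab_density_background",
            "hematoxylin_density",
            "texture_amplitude_tumor",
            "texture_amplitude_background",
            "pixel_noise_sd",
        ):
            val = getattr(self, name)
            if not np.isfinite(val) or val < 0:
                raise PhantomSpecError(f"{name} must be finite and >= 0, got {val}")
        if not (0.0 <= self.vacuole_fraction <= 0.3):
            raise PhantomSpecError(
                f"vacuole_fraction must lie in [0, 0.3], got {self.vacuole_fraction}"
            )
        tumor = np.asarray(self.tumor_polygon, dtype=np.float64)
        bgs = tuple(np.asarray(p, dtype=np.float64) for p in self.background_polygons)
        for poly in (tumor, *bgs):
            if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
                raise PhantomSpecError("polygons must be (n>=3, 2) vertex arrays")
            if (
                poly[:, 0].min() < 0
                or poly[:, 1].min() < 0
                or poly[:, 0].max() > self.width
                or poly[:, 1].max() > self.height
            ):
                raise PhantomSpecError("phantom geometry extends outside the canvas")
        object.__setattr__(self, "tumor_polygon", tumor)
        object.__setattr__(self, "background_polygons", bgs)

    def roiset(self) -> ROISet:
        rois = [ROI("tumor", self.tumor_polygon)]
        rois += [ROI("background", p) for p in self.background_polygons]
        return ROISet(rois=tuple(rois))


@dataclass(frozen=True)
class SyntheticSlide:
    """A rendered phantom with its annotations and pre-noise ground truth."""

    image: RGBImage
    roiset: ROISet
    truth: dict[str, np.ndarray]
    spec: PhantomSpec


def default_geometry(height: int, width: int) -> tuple[np.ndarray, tuple[np.ndarray, ...]]:
    """Central elliptical tumor plus a 4-sector annular healthy region.

    The annulus starts one border band (2% of the short canvas side, ~10 px
    at 512) outside the tumor ellipse, mimicking an unannotated tumor-border
    line.  The annulus is expressed as four ring sectors so no polygon needs
    interior rings.
    """
    s = float(min(height, width))
    cx, cy = width / 2.0, height / 2.0
    ax_t, ay_t = 0.293 * s, 0.234 * s
    border = 0.02 * s
    ax_i, ay_i = ax_t + border, ay_t + border
    ax_o, ay_o = 0.459 * s, 0.420 * s

    theta = np.linspace(0.0, 2.0 * np.pi, 65)[:-1]
    tumor = np.column_stack([cx + ax_t * np.cos(theta), cy + ay_t * np.sin(theta)])

    sectors = []
    n_arc = 17
    for k in range(4):
        t0, t1 = k * np.pi / 2.0, (k + 1) * np.pi / 2.0
        arc = np.linspace(t0, t1, n_arc)
        outer = np.column_stack([cx + ax_o * np.cos(arc), cy + ay_o * np.sin(arc)])
        inner = np.column_stack([cx + ax_i * np.cos(arc[::-1]), cy + ay_i * np.sin(arc[::-1])])
        sectors.append(np.vstack([outer, inner]))
    return tumor, tuple(sectors)


def _stochastic_fields(
    height: int,
    width: int,
    seed: int,
    bg_mask: np.ndarray,
    vacuole_fraction: float,
) -> tuple[np.ndarray, np.ndarray, np.random.Generator]:
    """Seeded texture field, vacuole mask and the noise generator.

    Returns the raw smooth texture (unnormalized), the boolean vacuole mask
    (discs inside the background region covering ~``vacuole_fraction`` of
    it), and a generator reserved for pixel noise.  Calling this twice with
    the same arguments yields identical fields.
    """
    ss = np.random.SeedSequence(seed)
    tex_seed, vac_seed, noise_seed = ss.spawn(3)
    s = float(min(height, width))

    tex_rng = np.random.default_rng(tex_seed)
    texture = gaussian_filter(tex_rng.standard_normal((height, width)), sigma=0.02 * s)

    vac_rng = np.random.default_rng(vac_seed)
    vacuoles = np.zeros((height, width), dtype=bool)
    bg_count = int(bg_mask.sum())
    if vacuole_fraction > 0 and bg_count > 0:
        target = vacuole_fraction * bg_count
        covered = 0
        r_lo, r_hi = max(2.0, 0.008 * s), max(3.0, 0.02 * s)
        for _ in range(5000):
            if covered >= target:
                break
            x = vac_rng.uniform(0, width)
            y = vac_rng.uniform(0, height)
            r = vac_rng.uniform(r_lo, r_hi)
            iy, ix = int(y), int(x)
            if not (0 <= iy < height and 0 <= ix < width and bg_mask[iy, ix]):
                continue
            y0, y1 = max(0, int(y - r) - 1), min(height, int(y + r) + 2)
            x0, x1 = max(0, int(x - r) - 1), min(width, int(x + r) + 2)
            yy, xx = np.mgrid[y0:y1, x0:x1]
            disc = (yy + 0.5 - y) ** 2 + (xx + 0.5 - x) ** 2 <= r * r
            new = disc & bg_mask[y0:y1, x0:x1] & ~vacuoles[y0:y1, x0:x1]
            covered += int(new.sum())
            vacuoles[y0:y1, x0:x1] |= disc
    return texture, vacuoles, np.random.default_rng(noise_seed)


def _normalize_in(field: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Shift/scale a field to zero mean, unit SD over the masked pixels."""
    vals = field[mask]
    sd = vals.std()
    if sd == 0:
        return np.zeros_like(field)
    return (field - vals.mean()) / sd


def forward_model(spec: PhantomSpec, model: StainModel | None = None) -> SyntheticSlide:
    """Render a phantom slide from its spec (deterministic given the seed).

    Per pixel: OD = hematoxylin_density * v_H + dab_density(region) * v_DAB
    + Gaussian OD noise; intensity = 255 * 10**(-OD), quantized to 8 bits.
    Vacuole pixels are forced to blank glass.  Ground-truth density fields
    are stored pre-noise.
    """
    model = model or hdab_model()
    h, w = spec.height, spec.width
    roiset = rasterize(spec.roiset(), h, w)
    tumor_mask = roiset.mask("tumor")
    bg_mask = roiset.mask("background")

    texture, vacuoles, noise_rng = _stochastic_fields(h, w, spec.seed, bg_mask, spec.vacuole_fraction)
    tex_tumor = _normalize_in(texture, tumor_mask)
    tex_bg = _normalize_in(texture, bg_mask)

    dab = np.where(
        tumor_mask,
        spec.dab_density_tumor + spec.texture_amplitude_tumor * tex_tumor,
        spec.dab_density_background + spec.texture_amplitude_background * tex_bg,
    )
    dab = np.clip(dab, 0.0, None)
    hema = np.full((h, w), spec.hematoxylin_density)
    dab[vacuoles] = 0.0
    hema[vacuoles] = 0.0

    v_h = model.stain_vector("hematoxylin")
    v_d = model.stain_vector("dab")
    od = hema[..., None] * v_h + dab[..., None] * v_d
    if spec.pixel_noise_sd > 0:
        od = od + noise_rng.normal(0.0, spec.pixel_noise_sd, size=od.shape)
    pixels = np.clip(255.0 * np.power(10.0, -od), 0.0, 255.0)
    pixels[vacuoles] = 255.0
    pixels = np.clip(np.rint(pixels), 0, 255)

    return SyntheticSlide(
        image=RGBImage(pixels=pixels, bit_depth=8),
        roiset=roiset,
        truth={"hematoxylin": hema, "dab": dab},
        spec=spec,
    )


# ---------------------------------------------------------------------------
# Region calibration: pin measured mean and SD to targets
# ---------------------------------------------------------------------------

_MAX_CAL_SAMPLES = 20000


def _calibrate_region(
    target_mean: float,
    target_sd: float,
    texture_vals: np.ndarray,
    vacuole_flags: np.ndarray,
    f: Callable[[np.ndarray], np.ndarray],
    d_max: float = _DAB_DENSITY_CEILING,
) -> tuple[float, float]:
    """Solve (mean density, texture amplitude) so the noiseless inverted-gray
    statistics over a region's pixels hit the targets.

    ``texture_vals`` are the normalized texture values at the region's ROI
    pixels and ``vacuole_flags`` marks pixels that will be blank glass
    (contributing intensity 0).  Nested bracketed root-finding: the inner
    solve pins the mean for a trial amplitude, the outer solve pins the SD.
    When the target SD is below the structural floor (vacuole speckle at
    zero amplitude) the amplitude is held at 0.
    """
    t = np.asarray(texture_vals, dtype=np.float64)
    vac = np.asarray(vacuole_flags, dtype=bool)
    if t.size != vac.size or t.size == 0:
        raise CalibrationError("calibration needs matching, non-empty pixel samples")
    if t.size > _MAX_CAL_SAMPLES:
        stride = int(np.ceil(t.size / _MAX_CAL_SAMPLES))
        t, vac = t[::stride], vac[::stride]
    tissue = ~vac
    frac_tissue = float(tissue.mean())
    if frac_tissue == 0:
        raise CalibrationError("region is entirely vacuole; cannot calibrate")
    max_mean = frac_tissue * float(f(np.array([d_max]))[0])
    if not (0.0 <= target_mean < max_mean):
        raise CalibrationError(
            f"target mean {target_mean} outside attainable range [0, {max_mean:.3f})"
        )

    t_tissue = t[tissue]

    def stats_for(amplitude: float) -> tuple[float, float]:
        def mean_at(dbar: float) -> float:
            g = np.zeros(t.size)
            g[tissue] = f(np.clip(dbar + amplitude * t_tissue, 0.0, None))
            return float(g.mean())

        if mean_at(0.0) > target_mean:
            raise CalibrationError("texture amplitude alone overshoots the target mean")
        dbar = brentq(lambda x: mean_at(x) - target_mean, 0.0, d_max, xtol=1e-10)
        g = np.zeros(t.size)
        g[tissue] = f(np.clip(dbar + amplitude * t_tissue, 0.0, None))
        return float(dbar), float(g.std(ddof=1))

    dbar0, sd0 = stats_for(0.0)
    if target_sd <= sd0:
        return dbar0, 0.0

    def sd_gap(a: float) -> float:
        try:
            _, sd = stats_for(a)
        except CalibrationError:
            return 1e6  # amplitude infeasible: SD effectively too large
        return sd - target_sd

    a_hi = max(target_sd / 200.0, 1e-3)
    for _ in range(20):
        if sd_gap(a_hi) > 0:
            break
        a_hi *= 2.0
        if a_hi > 5.0:
            raise CalibrationError(
                f"cannot reach within-region SD {target_sd} with any feasible texture amplitude"
            )
    amplitude = brentq(sd_gap, 0.0, a_hi, xtol=1e-8)
    dbar, _ = stats_for(amplitude)
    return dbar, amplitude


# ---------------------------------------------------------------------------
# Cohort presets
# ---------------------------------------------------------------------------

#: Characteristics of the 17-case cohort the generator emulates: patient id,
#: gender, age, tumor location, histological grade (three-tier), whether
#: preoperative therapy was given, and the categorical therapy-response
#: score (metadata only; "E" means >= 50% stainable tumor cells).
COHORT_CHARACTERISTICS: tuple[dict, ...] = tuple(
    dict(zip(("patient_id", "gender", "age", "location", "grade", "preoperative_therapy", "response_score"), row))
    for row in [
        (1, "Female", 77, "Upper extremity", 2, "None", "Not applicable"),
        (2, "Male", 56, "Upper extremity", 1, "None", "Not applicable"),
        (3, "Female", 62, "Lower extremity", 1, "Radiotherapy", "E"),
        (4, "Male", 68, "Trunk", 1, "None", "Not applicable"),
        (5, "Male", 55, "Lower extremity", 2, "None", "Not applicable"),
        (6, "Female", 81, "Trunk", 3, "None", "Not applicable"),
        (7, "Female", 63, "Upper extremity", 2, "None", "Not applicable"),
        (8, "Male", 47, "Lower extremity", 1, "Radiotherapy", "E"),
        (9, "Male", 64, "Upper extremity", 2, "Radiotherapy", "E"),
        (10, "Female", 64, "Upper extremity", 3, "Radiotherapy", "E"),
        (11, "Male", 78, "Lower extremity", 2, "Radiotherapy", "E"),
        (12, "Male", 49, "Lower extremity", 2, "Radiotherapy", "E"),
        (13, "Female", 70, "Lower extremity", 2, "Radiotherapy", "E"),
        (14, "Male", 70, "Trunk", 2, "Radiotherapy", "E"),
        (15, "Male", 79, "Lower extremity", 3, "Chemotherapy", "E"),
        (16, "Female", 67, "Upper extremity", 2, "Radiotherapy", "E"),
        (17, "Female", 66, "Upper extremity", 2, "Radiotherapy", "E"),
    ]
)

_PREOP_PATIENTS = tuple(
    r["patient_id"] for r in COHORT_CHARACTERISTICS if r["preoperative_therapy"] != "None"
)
_NON_PREOP_PATIENTS = tuple(
    r["patient_id"] for r in COHORT_CHARACTERISTICS if r["preoperative_therapy"] == "None"
)


@dataclass(frozen=True)
class CaseTarget:
    """Deterministic per-case targets: inverted-gray tumor mean and TBR."""

    patient_id: int
    tumor_intensity: float
    tbr: float
    preop: bool

    @property
    def background_intensity(self) -> float:
        return self.tumor_intensity / self.tbr


@dataclass(frozen=True)
class CohortPreset:
    """A 17-case biomarker preset with an 11/6 preoperative-therapy split.

    The per-case target lists are fixed deterministic constants: the
    subgroup arithmetic means of tumor intensity and TBR equal the encoded
    summary values exactly, so acceptance tolerances are attributable solely
    to the imaging chain.  ``tumor_sd_target`` is the within-tumor-ROI
    standard deviation the texture field is calibrated to.
    """

    name: str
    biomarker: str
    cases: tuple[CaseTarget, ...]
    tumor_sd_target: float
    pixel_noise_sd: float = DEFAULT_NOISE_SD
    vacuole_fraction: float = DEFAULT_VACUOLE_FRACTION
    hematoxylin_density: float = DEFAULT_HEMATOXYLIN_DENSITY

    def __post_init__(self) -> None:
        if len(self.cases) != 17:
            raise InvalidParameterError(f"preset {self.name}: expected 17 cases, got {len(self.cases)}")
        n_preop = sum(c.preop for c in self.cases)
        if n_preop != 11 or len(self.cases) - n_preop != 6:
            raise InvalidParameterError(
                f"preset {self.name}: preoperative split must be 11/6, got {n_preop}/{len(self.cases) - n_preop}"
            )

    def n_tbr_below_1(self) -> int:
        return sum(c.tbr < 1.0 for c in self.cases)


def _make_preset(
    name: str,
    biomarker: str,
    preop_intensity: Sequence[float],
    preop_tbr: Sequence[float],
    non_preop_intensity: Sequence[float],
    non_preop_tbr: Sequence[float],
    tumor_sd_target: float,
) -> CohortPreset:
    cases = [
        CaseTarget(pid, ti, r, True)
        for pid, ti, r in zip(_PREOP_PATIENTS, preop_intensity, preop_tbr, strict=True)
    ] + [
        CaseTarget(pid, ti, r, False)
        for pid, ti, r in zip(_NON_PREOP_PATIENTS, non_preop_intensity, non_preop_tbr, strict=True)
    ]
    cases.sort(key=lambda c: c.patient_id)
    return CohortPreset(name=name, biomarker=biomarker, cases=tuple(cases), tumor_sd_target=tumor_sd_target)


# Per-case targets.  Subgroup means are exact: TEM-1 tumor intensity 85
# (preop) / 74 (none) with TBR 3.5 / 2.2; VEGF-A 96 / 73 with 2.7 / 1.8;
# PDGFR-alpha 70 / 52 with 1.9 / 1.5.  TEM-1 keeps every TBR above 1;
# VEGF-A and PDGFR-alpha each contain exactly three cases with TBR < 1.
# Within-case spreads are heuristic (intensities vary widely between cases)
# and chosen so the subgroup comparisons stay non-significant.
PRESETS: dict[str, CohortPreset] = {
    "TEM1": _make_preset(
        "TEM1",
        "TEM-1",
        preop_intensity=[45, 60, 70, 75, 80, 85, 90, 95, 105, 110, 120],
        preop_tbr=[1.1, 1.6, 2.1, 2.6, 3.1, 3.6, 4.1, 4.7, 5.3, 6.2, 4.1],
        non_preop_intensity=[50, 62, 70, 78, 86, 98],
        non_preop_tbr=[1.05, 1.2, 1.5, 2.1, 3.2, 4.15],
        tumor_sd_target=39.0,
    ),
    "VEGFA": _make_preset(
        "VEGFA",
        "VEGF-A",
        preop_intensity=[40, 60, 75, 85, 95, 102, 110, 118, 128, 145, 98],
        preop_tbr=[0.8, 0.9, 1.6, 2.0, 2.4, 2.8, 3.2, 3.6, 4.0, 4.4, 4.0],
        non_preop_intensity=[40, 55, 66, 78, 92, 107],
        non_preop_tbr=[0.9, 1.3, 1.7, 2.1, 2.3, 2.5],
        tumor_sd_target=45.0,
    ),
    "PDGFRA": _make_preset(
        "PDGFRA",
        "PDGFR-alpha",
        preop_intensity=[35, 46, 55, 62, 68, 74, 80, 88, 97, 110, 55],
        preop_tbr=[0.8, 0.9, 1.3, 1.6, 1.9, 2.1, 2.3, 2.5, 2.8, 3.0, 1.7],
        non_preop_intensity=[26, 38, 46, 55, 66, 81],
        non_preop_tbr=[0.9, 1.2, 1.4, 1.6, 1.8, 2.1],
        tumor_sd_target=36.0,
    ),
}


def get_preset(name: str) -> CohortPreset:
    if name not in PRESETS:
        raise InvalidParameterError(
            f"unknown cohort preset {name!r}; available: {', '.join(sorted(PRESETS))}"
        )
    return PRESETS[name]


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _case_seed(master_seed: int, preset_name: str, case_index: int) -> int:
    preset_tag = sorted(PRESETS).index(preset_name) if preset_name in PRESETS else 97
    ss = np.random.SeedSequence([int(master_seed), preset_tag, case_index])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def _build_case_spec(
    preset: CohortPreset,
    case: CaseTarget,
    case_index: int,
    master_seed: int,
    size: int,
    model: StainModel,
) -> PhantomSpec:
    """Calibrate one case's densities/texture so the measured statistics of
    a noiseless rendering match the case targets, and freeze them in a spec."""
    tumor_poly, bg_polys = default_geometry(size, size)
    seed = _case_seed(master_seed, preset.name, case_index)
    spec = PhantomSpec(
        height=size,
        width=size,
        tumor_polygon=tumor_poly,
        background_polygons=bg_polys,
        dab_density_tumor=0.0,
        dab_density_background=0.0,
        hematoxylin_density=preset.hematoxylin_density,
        pixel_noise_sd=preset.pixel_noise_sd,
        vacuole_fraction=preset.vacuole_fraction,
        seed=seed,
    )
    roiset = rasterize(spec.roiset(), size, size)
    tumor_mask = roiset.mask("tumor")
    bg_mask = roiset.mask("background")
    texture, vacuoles, _ = _stochastic_fields(size, size, seed, bg_mask, preset.vacuole_fraction)
    tex_tumor = _normalize_in(texture, tumor_mask)
    tex_bg = _normalize_in(texture, bg_mask)

    f = lambda d: inverted_gray_of_density(d, model)
    # Background SD target scales with the intensity contrast; the tumor
    # target is the biomarker's within-ROI SD.
    bg_target = case.background_intensity
    bg_sd_target = preset.tumor_sd_target * bg_target / case.tumor_intensity
    d_t, a_t = _calibrate_region(
        case.tumor_intensity,
        preset.tumor_sd_target,
        tex_tumor[tumor_mask],
        np.zeros(int(tumor_mask.sum()), dtype=bool),
        f,
    )
    d_b, a_b = _calibrate_region(
        bg_target,
        bg_sd_target,
        tex_bg[bg_mask],
        vacuoles[bg_mask],
        f,
    )
    return replace(
        spec,
        dab_density_tumor=d_t,
        dab_density_background=d_b,
        texture_amplitude_tumor=a_t,
        texture_amplitude_background=a_b,
    )


def simulate_cohort(
    preset: CohortPreset | str,
    master_seed: int = 42,
    size: int = 512,
    model: StainModel | None = None,
) -> tuple[list[SyntheticSlide], pd.DataFrame, pd.DataFrame]:
    """Generate the 17 slides of a preset in memory.

    Returns the slides, a metadata table mirroring the cohort
    characteristics (keyed by sample id), and a ground-truth table with the
    per-case targets and calibrated generator parameters.
    """
    if isinstance(preset, str):
        preset = get_preset(preset)
    model = model or hdab_model()
    slides: list[SyntheticSlide] = []
    meta_rows: list[dict] = []
    truth_rows: list[dict] = []
    characteristics = {r["patient_id"]: r for r in COHORT_CHARACTERISTICS}
    for idx, case in enumerate(preset.cases):
        spec = _build_case_spec(preset, case, idx, master_seed, size, model)
        slide = forward_model(spec, model)
        slides.append(slide)
        sample_id = f"{preset.name}_{case.patient_id:02d}"
        info = characteristics[case.patient_id]
        meta_rows.append(
            {
                "sample_id": sample_id,
                "patient_id": case.patient_id,
                "biomarker": preset.biomarker,
                **{k: info[k] for k in ("gender", "age", "location", "grade", "preoperative_therapy", "response_score")},
            }
        )
        truth_rows.append(
            {
                "sample_id": sample_id,
                "patient_id": case.patient_id,
                "target_tumor_intensity": case.tumor_intensity,
                "target_background_intensity": case.background_intensity,
                "target_tbr": case.tbr,
                "dab_density_tumor": spec.dab_density_tumor,
                "dab_density_background": spec.dab_density_background,
                "texture_amplitude_tumor": spec.texture_amplitude_tumor,
                "texture_amplitude_background": spec.texture_amplitude_background,
                "seed": spec.seed,
            }
        )
    return slides, pd.DataFrame(meta_rows), pd.DataFrame(truth_rows)


def build_cohort(
    preset: CohortPreset | str,
    out_dir: str | Path,
    master_seed: int = 42,
    size: int = 512,
    model: StainModel | None = None,
) -> tuple[list[SyntheticSlide], pd.DataFrame, pd.DataFrame]:
    """Generate a preset cohort and write PNG tiles, GeoJSON annotations,
    a metadata CSV and a ground-truth CSV to ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    slides, metadata, truth = simulate_cohort(preset, master_seed=master_seed, size=size, model=model)
    for slide, sample_id in zip(slides, metadata["sample_id"]):
        try:
            slide.image.save(out_dir / f"{sample_id}.png")
            write_annotations(slide.roiset, out_dir / f"{sample_id}.geojson")
        except OSError as exc:
            raise OSError(f"failed writing outputs for case {sample_id}: {exc}") from exc
    metadata.to_csv(out_dir / "metadata.csv", index=False)
    truth.to_csv(out_dir / "truth.csv", index=False)
    return slides, metadata, truth
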