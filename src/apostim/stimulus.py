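"""Triangular moth stimuli at exact Michelson contrast.

Pipeline per variant: simulate a reaction-diffusion field, upsample it to
print resolution, take a centred window, mirror it about the vertical
axis (moth wing symmetry), rasterize an apex-up isosceles triangle mask,
tone-normalize the masked pixels, and map them affinely onto the target
reflectance band so that the Michelson contrast

    C = (Rmax - Rmin) / (Rmax + Rmin)

over the patterned (masked) region equals the requested level while the
mean grey stays fixed across contrast conditions.  Tone normalization
rank-equalizes the masked grey-level distribution to uniform, which makes
the masked mean coincide with the band midpoint exactly; without it the
skewed reaction-diffusion amplitude distribution would let mean luminance
covary with contrast — the confound the design controls for.

Pixels are snapped to the 8-bit grid (k/255) before the achieved contrast
and mean are measured, so recorded values are exactly what a PNG export
contains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.ndimage import zoom as _ndzoom
from scipy.stats import rankdata

from .rd import RDParams, PatternField, classify_morphology, simulate

__all__ = [
    "StimulusSpec",
    "StimulusImage",
    "rescale_to_michelson",
    "mirror_and_crop",
    "generate_category",
    "measure_contrast",
    "triangle_mask",
    "save_stimuli",
]

logger = logging.getLogger(__name__)

MM_PER_INCH = 25.4
#: Michelson contrast levels used for the low/high conditions.
CONTRAST_LEVELS = {"low": 0.15, "high": 1.0}


@dataclass(frozen=True)
class StimulusSpec:
    """Geometry and photometric targets of one triangular stimulus."""

    contrast_level: float
    pattern_class: str  # "spots" | "stripes"
    variant_id: int = 0
    triangle_base_mm: float = 44.0
    triangle_height_mm: float = 37.0
    dpi: float = 600.0
    mean_reflectance: float = 0.5

    def __post_init__(self):
        if not 0.0 <= self.contrast_level <= 1.0:
            raise ValueError("contrast_level must be in [0, 1]")
        if self.pattern_class not in ("spots", "stripes"):
            raise ValueError("pattern_class must be 'spots' or 'stripes'")
        if not 0.0 < self.mean_reflectance < 1.0:
            raise ValueError("mean_reflectance must be in (0, 1)")
        lo = self.mean_reflectance * (1.0 - self.contrast_level)
        hi = self.mean_reflectance * (1.0 + self.contrast_level)
        if lo < 0.0 or hi > 1.0:
            m, c = self.mean_reflectance, self.contrast_level
            lo_m, hi_m = 0.0, 1.0 / (1.0 + c)
            raise ValueError(
                f"infeasible (contrast={c}, mean={m}): the stretched band "
                f"[{lo:.3f}, {hi:.3f}] leaves [0, 1]; feasible mean range is "
                f"({lo_m:.4f}, {hi_m:.4f}]"
            )

    @property
    def px_width(self) -> int:
        return int(round(self.triangle_base_mm / MM_PER_INCH * self.dpi))

    @property
    def px_height(self) -> int:
        return int(round(self.triangle_height_mm / MM_PER_INCH * self.dpi))


@dataclass(frozen=True)
class StimulusImage:
    """Print-ready greyscale triangle.

    ``pixels`` hold reflectance fractions snapped to the 8-bit grid;
    everything outside ``mask`` is background white (1.0).
    """

    pixels: np.ndarray
    mask: np.ndarray
    spec: StimulusSpec
    achieved_contrast: float
    achieved_mean: float
    rd_seed: int | None = None

    def to_uint8(self) -> np.ndarray:
        return np.round(self.pixels * 255.0).astype(np.uint8)


def measure_contrast(image: StimulusImage) -> dict:
    """Michelson contrast and mean grey over the masked pattern region."""
    vals = image.pixels[image.mask]
    if vals.size == 0:
        raise ValueError("stimulus mask is empty")
    rmin, rmax = float(vals.min()), float(vals.max())
    denom = rmax + rmin
    michelson = 0.0 if denom == 0 else (rmax - rmin) / denom
    return {"michelson": michelson, "mean": float(vals.mean())}


def rescale_to_michelson(
    field: PatternField | np.ndarray, target_contrast: float, mean_reflectance: float
) -> np.ndarray:
    """Affine-map field values so (Rmax-Rmin)/(Rmax+Rmin) hits the target.

    The band is centred on ``mean_reflectance``: Rmin = m(1-C) and
    Rmax = m(1+C).  Rank order is preserved (the map is affine with
    positive slope).  A constant field has no definable contrast.
    """
    values = field.values if isinstance(field, PatternField) else np.asarray(field, dtype=float)
    if not 0.0 <= target_contrast <= 1.0:
        raise ValueError("target_contrast must be in [0, 1]")
    lo = mean_reflectance * (1.0 - target_contrast)
    hi = mean_reflectance * (1.0 + target_contrast)
    if not (0.0 < mean_reflectance < 1.0) or lo < 0.0 or hi > 1.0:
        raise ValueError(
            f"infeasible (contrast={target_contrast}, mean={mean_reflectance}); "
            f"feasible mean range is (0, {1.0 / (1.0 + target_contrast):.4f}]"
        )
    if target_contrast == 0.0:
        return np.full_like(values, mean_reflectance, dtype=float)
    vmin, vmax = float(values.min()), float(values.max())
    if vmax - vmin < 1e-15:
        raise ValueError("constant field: Michelson contrast is undefined")
    return lo + (values - vmin) * ((hi - lo) / (vmax - vmin))


def triangle_mask(spec: StimulusSpec) -> np.ndarray:
    """Boolean raster of an apex-up isosceles triangle, base at the bottom.

    Pixel dimensions are round(mm / 25.4 * dpi); the mask is exactly
    mirror-symmetric about the vertical centre axis.
    """
    h, w = spec.px_height, spec.px_width
    y = np.arange(h, dtype=float)[:, None]
    x = np.arange(w, dtype=float)[None, :]
    cx = (w - 1) / 2.0
    half_width = (y / max(h - 1, 1)) * ((w - 1) / 2.0)
    return np.abs(x - cx) <= half_width + 1e-9


def _mirror(raster: np.ndarray, width: int) -> np.ndarray:
    """Build a width-``width`` image whose right half mirrors the left."""
    half = (width + 1) // 2
    if raster.shape[1] < half:
        raise ValueError(
            f"raster too narrow: needs at least {half} columns "
            f"(half the {width}-px triangle width), got {raster.shape[1]}"
        )
    out = np.empty((raster.shape[0], width), dtype=float)
    left = raster[:, :half]
    out[:, :half] = left
    # column c >= half mirrors column width-1-c (< half)
    out[:, half:] = left[:, [width - 1 - c for c in range(half, width)]]
    return out


def mirror_and_crop(raster: np.ndarray, spec: StimulusSpec) -> StimulusImage:
    """Mirror a grey raster into the triangular stimulus frame.

    The left half of the triangle comes from the raster's leading columns;
    the right half is its exact pixel mirror.  Outside the mask the image
    is background white.  Pixels are snapped to the 8-bit grid and the
    achieved contrast/mean are measured on the snapped masked pixels.
    """
    raster = np.asarray(raster, dtype=float)
    h, w = spec.px_height, spec.px_width
    if raster.shape[0] < h:
        raise ValueError(f"raster too short: needs at least {h} rows, got {raster.shape[0]}")
    full = _mirror(raster[:h], w)
    mask = triangle_mask(spec)
    pixels = np.ones((h, w), dtype=float)
    pixels[mask] = np.round(np.clip(full[mask], 0.0, 1.0) * 255.0) / 255.0
    m = measure_contrast(StimulusImage(pixels, mask, spec, 0.0, 0.0))
    return StimulusImage(pixels, mask, spec, m["michelson"], m["mean"])


def _equalize(values: np.ndarray) -> np.ndarray:
    """Rank-transform to a uniform [0, 1] distribution (ties averaged)."""
    n = values.size
    if n < 2:
        raise ValueError("need at least 2 pixels to equalize")
    return (rankdata(values, method="average") - 1.0) / (n - 1.0)


def _field_to_raster(field: PatternField, spec: StimulusSpec) -> np.ndarray:
    """Upsample the field isotropically and take a centred window covering
    the triangle height and half-width (the half that gets mirrored)."""
    h, w = spec.px_height, spec.px_width
    half = (w + 1) // 2
    fh, fw = field.values.shape
    z = max(h / fh, half / fw)
    big = _ndzoom(field.values, z, order=1, mode="grid-wrap", grid_mode=True)
    bh, bw = big.shape
    r0 = (bh - h) // 2
    c0 = (bw - half) // 2
    return big[r0 : r0 + h, c0 : c0 + half]


def _quantized_band(contrast: float, mean: float) -> tuple[int, int]:
    """Best 8-bit reflectance endpoints (a, b) for a Michelson target.

    Rounding the real endpoints m(1-C), m(1+C) independently can bias the
    quantized contrast by up to ~2% of a low target; instead pick the
    integer grey pair whose Michelson contrast (b-a)/(b+a) is closest to
    the target, tie-breaking on midpoint proximity to the mean.
    """
    lo = mean * (1.0 - contrast) * 255.0
    hi = mean * (1.0 + contrast) * 255.0
    best = None
    for a in range(max(int(np.floor(lo)) - 1, 0), min(int(np.ceil(lo)) + 2, 256)):
        for b in range(max(int(np.floor(hi)) - 1, a + 1), min(int(np.ceil(hi)) + 2, 256)):
            err = abs((b - a) / (b + a) - contrast)
            mid_err = abs((a + b) / 2.0 - mean * 255.0)
            key = (err, mid_err)
            if best is None or key < best[0]:
                best = (key, (a, b))
    return best[1]


def make_stimulus(field: PatternField, spec: StimulusSpec) -> StimulusImage:
    """Turn one pattern field into a finished stimulus.

    Tone-normalizes (rank-equalizes) the masked pixels before the affine
    Michelson map so that the masked mean equals ``mean_reflectance``
    exactly for every contrast level.
    """
    raster = _field_to_raster(field, spec)
    full = _mirror(raster, spec.px_width)
    mask = triangle_mask(spec)
    pixels = np.ones_like(full)
    masked = full[mask]
    if spec.contrast_level == 0.0:
        pixels[mask] = np.round(spec.mean_reflectance * 255.0) / 255.0
    else:
        a, b = _quantized_band(spec.contrast_level, spec.mean_reflectance)
        mapped = (a + _equalize(masked) * (b - a)) / 255.0
        pixels[mask] = np.round(mapped * 255.0) / 255.0
    m = measure_contrast(StimulusImage(pixels, mask, spec, 0.0, 0.0))
    return StimulusImage(
        pixels, mask, spec, m["michelson"], m["mean"], rd_seed=field.params.seed
    )


def generate_category(
    pattern_class: str,
    contrast_level: float,
    n_variants: int = 30,
    base_seed: int = 0,
    spec: StimulusSpec | None = None,
    rd_params: RDParams | None = None,
    max_retries: int = 5,
) -> tuple[list[StimulusImage], pd.DataFrame]:
    """Generate one category of stimuli (e.g. 30 high-contrast spots).

    Variants differ by reaction-diffusion seed (``base_seed + variant_id``);
    a variant whose field fails morphology classification for its class is
    regenerated from a deterministic fallback seed sequence (bounded
    retries, then a hard error).  Returns the images and a manifest frame
    with per-variant seed and achieved photometry.
    """
    if n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    if spec is None:
        spec = StimulusSpec(contrast_level=contrast_level, pattern_class=pattern_class)
    else:
        spec = replace(spec, contrast_level=contrast_level, pattern_class=pattern_class)
    if rd_params is None:
        rd_params = RDParams(regime=pattern_class)
    else:
        rd_params = replace(rd_params, regime=pattern_class)

    images: list[StimulusImage] = []
    rows = []
    retry_counter = 0
    for variant in range(n_variants):
        seed = base_seed + variant
        for attempt in range(max_retries + 1):
            fld = simulate(replace(rd_params, seed=seed))
            report = classify_morphology(fld)
            if report.label == pattern_class:
                break
            retry_counter += 1
            logger.warning(
                "variant %d (seed %d) classified as %s, expected %s; retrying",
                variant, seed, report.label, pattern_class,
            )
            seed = base_seed + 100_000 + retry_counter
        else:
            raise RuntimeError(
                f"variant {variant}: no {pattern_class} field found in "
                f"{max_retries} retries (last seed {seed})"
            )
        img = make_stimulus(fld, replace(spec, variant_id=variant))
        images.append(img)
        rows.append(
            {
                "variant_id": variant,
                "pattern_class": pattern_class,
                "contrast_level": contrast_level,
                "seed": seed,
                "achieved_contrast": img.achieved_contrast,
                "achieved_mean": img.achieved_mean,
                "px_width": spec.px_width,
                "px_height": spec.px_height,
            }
        )
    return images, pd.DataFrame(rows)


def save_stimuli(images: list[StimulusImage], manifest: pd.DataFrame, out_dir) -> None:
    """Export a category: one 8-bit grey PNG per variant plus manifest.csv."""
    import imageio.v3 as iio
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for img in images:
        name = (
            f"{img.spec.pattern_class}_{img.spec.contrast_level:g}_"
            f"{img.spec.variant_id:02d}.png"
        )
        iio.imwrite(out / name, img.to_uint8())
    manifest.to_csv(out / "manifest.csv", index=False)
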