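"""ROI measurement and normalized quantitative lesion features.

Signal intensities in conventional MR sequences carry no absolute scale, so
lesion signal is normalized to the ipsilateral masseter muscle: a single
circular ROI of 10-15 mm^2 is placed in the brightest solid portion of the
lesion and one in the muscle belly, and the feature is the ratio of the two
ROI means.  Diffusivity is the mean of three circular ROIs on the ADC map.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "RoiSpec",
    "QuantitativeFeatures",
    "QualitativeFindings",
    "roi_mean",
    "normalize_si",
    "adc_mean",
    "place_lesion_roi",
]


@dataclass(frozen=True)
class RoiSpec:
    """A circular region of interest on a 2-D image.

    The radius in pixels is derived from the physical area:
    ``r = sqrt(area / pi) / pixel_spacing``.  SI ROIs are conventionally
    10-15 mm^2; a spec outside that range is allowed but warned about.
    """

    center: tuple[float, float]  # (row, col) in pixels
    area_mm2: float
    pixel_spacing_mm: float

    def __post_init__(self) -> None:
        if self.area_mm2 <= 0:
            raise ValueError("area_mm2 must be > 0")
        if self.pixel_spacing_mm <= 0:
            raise ValueError("pixel_spacing_mm must be > 0")
        if not (10.0 <= self.area_mm2 <= 15.0):
            warnings.warn(
                f"ROI area {self.area_mm2:g} mm^2 outside the conventional "
                "10-15 mm^2 range",
                stacklevel=2,
            )

    @property
    def radius_px(self) -> float:
        return math.sqrt(self.area_mm2 / math.pi) / self.pixel_spacing_mm


@dataclass(frozen=True)
class QuantitativeFeatures:
    """Normalized signal-intensity ratios and ADC of one lesion.

    ``norm_t2_si`` and ``norm_t1_si`` are lesion-to-masseter ratios on the
    T2-weighted and late post-contrast T1-weighted sequences; ``adc`` is in
    1e-3 mm^2/s.  NaN marks a missing measurement.
    """

    norm_t2_si: float
    norm_t1_si: float
    adc: float = float("nan")

    def __post_init__(self) -> None:
        for name in ("norm_t2_si", "norm_t1_si", "adc"):
            v = getattr(self, name)
            if not math.isnan(v) and v <= 0:
                raise ValueError(f"{name} must be > 0 when present, got {v}")


@dataclass(frozen=True)
class QualitativeFindings:
    """Reader-recorded qualitative findings of one lesion.

    The ghosting sign -- indistinguishability of the tumor from surrounding
    parotid tissue on late post-contrast fat-saturated T1 images except for
    a thin peripheral enhancing ring -- is the finding the decision tree
    keys on; the remainder describe cystic components, capsule, SWI findings
    and homogeneity.
    """

    ghosting: bool
    protein_cysts: bool = False
    capsule: bool = False
    complete_capsule: bool = False
    calcifications: bool = False
    hemorrhage: bool = False
    homog_t2: bool = False
    homog_t1gd: bool = False

    def __post_init__(self) -> None:
        if self.complete_capsule and not self.capsule:
            raise ValueError("complete_capsule requires capsule")


def roi_mean(image: np.ndarray, spec: RoiSpec) -> float:
    """Mean signal over a circular ROI.

    A pixel belongs to the ROI when its center lies within the disk
    (pixel-center inclusion; no partial-volume weighting).  The disk must
    lie fully inside the image.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be 2-D")
    r0, c0 = spec.center
    rad = spec.radius_px
    if r0 - rad < -0.5 or c0 - rad < -0.5 \
            or r0 + rad > image.shape[0] - 0.5 or c0 + rad > image.shape[1] - 0.5:
        raise ValueError(
            f"ROI disk (center {spec.center}, radius {rad:.2f} px) exceeds "
            f"image bounds {image.shape}"
        )
    rows = np.arange(image.shape[0])[:, None]
    cols = np.arange(image.shape[1])[None, :]
    mask = (rows - r0) ** 2 + (cols - c0) ** 2 <= rad**2
    if not mask.any():
        raise ValueError("ROI contains no pixel centers; enlarge the area")
    return float(image[mask].mean())


def normalize_si(lesion_si: float, masseter_si: float) -> float:
    """Lesion-to-masseter signal-intensity ratio."""
    if masseter_si <= 0:
        raise ValueError(f"masseter_si must be > 0, got {masseter_si}")
    return lesion_si / masseter_si


def adc_mean(values) -> float:
    """Mean ADC over exactly three ROI readings (1e-3 mm^2/s)."""
    values = list(values)
    if len(values) != 3:
        raise ValueError(f"expected exactly 3 ADC readings, got {len(values)}")
    if any(v <= 0 for v in values):
        raise ValueError("ADC readings must be > 0")
    return float(np.mean(values))


def place_lesion_roi(
    image: np.ndarray,
    lesion_mask: np.ndarray,
    area_mm2: float = 12.0,
    pixel_spacing_mm: float = 0.5,
) -> RoiSpec:
    """Place the lesion SI ROI at the brightest solid portion of the lesion.

    Approximates the reading convention (ROI in the solid portion with the
    highest late post-contrast signal) by centering the disk on the maximum
    of a local-mean-filtered image restricted to the lesion mask.  This is a
    phantom-level approximation; it does no segmentation.
    """
    from scipy.ndimage import uniform_filter

    image = np.asarray(image, dtype=float)
    if image.shape != lesion_mask.shape:
        raise ValueError("image and lesion_mask shapes differ")
    if not lesion_mask.any():
        raise ValueError("empty lesion mask")
    rad = math.sqrt(area_mm2 / math.pi) / pixel_spacing_mm
    smoothed = uniform_filter(image, size=max(int(2 * rad), 1))
    masked = np.where(lesion_mask, smoothed, -np.inf)
    r0, c0 = np.unravel_index(int(np.argmax(masked)), masked.shape)
    return RoiSpec(center=(float(r0), float(c0)), area_mm2=area_mm2,
                   pixel_spacing_mm=pixel_spacing_mm)
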