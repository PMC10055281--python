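"""Per-cell microscopy quantification and gel lane densitometry.

The microscopy branch works on sum-Z-projected fluorescence images with
hand-drawn elliptical ROIs: it measures area, mean, standard deviation and
integrated density inside the ROI, classifies cells as punctate by an
intensity-dispersion statistic, and converts integrated density to a
concentration via an ellipsoid volume.

Note on the dispersion statistic: the classifier uses ``sd / sqrt(mean)``
(exposed as ``cv_sqrt_mean``), which is *not* the standard coefficient of
variation ``sd / mean``; the threshold (30) belongs to this definition.

The gel branch quantifies SDS-resistant polymer smears from semi-denaturing
detergent agarose gels (SDD-AGE): rolling-ball background subtraction,
10-pixel-wide lane profiles, and normalization of each profile to unit
integral, with center-of-mass and quartile migration summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import pi
from typing import Optional

import numpy as np
from skimage.draw import ellipse as _draw_ellipse
from skimage.restoration import rolling_ball

__all__ = [
    "EllipseROI",
    "CellImageStats",
    "LaneProfile",
    "cell_stats",
    "cell_volume",
    "cell_concentration",
    "subtract_background",
    "lane_profile",
    "synthetic_cell_image",
    "synthetic_gel_image",
]

PUNCTATE_CV_THRESHOLD = 30.0


@dataclass(frozen=True)
class EllipseROI:
    """Elliptical region of interest in pixel coordinates.

    ``r``/``c`` is the center (row, column); ``r_radius``/``c_radius`` the
    half-axes in pixels; ``rotation`` in radians.
    """

    r: float
    c: float
    r_radius: float
    c_radius: float
    rotation: float = 0.0

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        rr, cc = _draw_ellipse(
            self.r, self.c, self.r_radius, self.c_radius,
            shape=shape, rotation=self.rotation,
        )
        m = np.zeros(shape, dtype=bool)
        m[rr, cc] = True
        return m


@dataclass
class CellImageStats:
    """Quantities measured for one cell ROI on the sum projection."""

    area: int  # px^2
    mean: float
    sd: float
    integrated_density: float  # mean * area
    cv_sqrt_mean: float  # sd / sqrt(mean)
    punctate: bool
    major: Optional[float] = None  # axes in um
    minor: Optional[float] = None
    volume: Optional[float] = None  # um^3
    concentration: Optional[float] = None  # fluorescence / um^3

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def cell_stats(
    pixels: np.ndarray,
    roi: EllipseROI,
    major_um: float | None = None,
    minor_um: float | None = None,
    semi_axes: bool = False,
) -> CellImageStats:
    """Measure a cell ROI on a sum-projected image (float64 statistics).

    When the fitted ellipse axes (in microns) are given, the ellipsoid volume
    and concentration (integrated density / volume) are filled in too.
    """
    img = np.asarray(pixels, dtype=np.float64)
    mask = roi.mask(img.shape)
    if not mask.any():
        raise ValueError("ROI covers no pixels")
    vals = img[mask]
    area = int(mask.sum())
    mean = float(vals.mean())
    sd = float(vals.std(ddof=0))
    integrated = mean * area
    cv = float(sd / np.sqrt(mean)) if mean > 0 else 0.0
    stats = CellImageStats(
        area=area,
        mean=mean,
        sd=sd,
        integrated_density=integrated,
        cv_sqrt_mean=cv,
        punctate=bool(cv > PUNCTATE_CV_THRESHOLD),
    )
    if major_um is not None and minor_um is not None:
        stats.major = major_um
        stats.minor = minor_um
        stats.volume = cell_volume(major_um, minor_um, semi_axes=semi_axes)
        stats.concentration = cell_concentration(integrated, stats.volume)
    return stats


def cell_volume(major: float, minor: float, semi_axes: bool = False) -> float:
    """Ellipsoid volume from the fitted ellipse, ``(4/3) * pi * major * minor^2``.

    The default treats ``major``/``minor`` as printed by the Fiji ellipse fit
    (full axes, no /8 factor); ``semi_axes=True`` applies the conventional
    semi-axis geometry ``(4/3) * pi * (major/2) * (minor/2)^2``.
    """
    if major <= 0 or minor <= 0:
        raise ValueError("ellipse axes must be positive")
    if semi_axes:
        return (4.0 / 3.0) * pi * (major / 2.0) * (minor / 2.0) ** 2
    return (4.0 / 3.0) * pi * major * minor * minor


def cell_concentration(integrated_density: float, volume: float) -> float:
    """Fluorescence per cubic micron: integrated density over ellipsoid volume."""
    if volume <= 0:
        raise ValueError("volume must be positive")
    return integrated_density / volume


def subtract_background(image: np.ndarray, radius_px: float = 200.0) -> np.ndarray:
    """Rolling-ball background subtraction (morphological, grayscale)."""
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("subtract_background expects a 2-D grayscale image")
    if radius_px >= min(img.shape):
        raise ValueError(
            f"rolling-ball radius {radius_px} px must be smaller than the image "
            f"({img.shape[0]} x {img.shape[1]})"
        )
    background = rolling_ball(img, radius=radius_px)
    return img - background


@dataclass
class LaneProfile:
    """A background-subtracted, width-averaged gel lane intensity profile."""

    positions: np.ndarray  # px along migration
    intensity: np.ndarray
    normalized: np.ndarray  # unit trapezoid integral

    @property
    def center_of_mass(self) -> float:
        w = np.clip(self.intensity, 0.0, None)
        total = w.sum()
        if total <= 0:
            return np.nan
        return float(np.sum(self.positions * w) / total)

    def quartiles(self) -> tuple[float, float, float]:
        w = np.clip(self.intensity, 0.0, None)
        cdf = np.cumsum(w)
        if cdf[-1] <= 0:
            return (np.nan, np.nan, np.nan)
        cdf = cdf / cdf[-1]
        return tuple(
            float(np.interp(q, cdf, self.positions)) for q in (0.25, 0.5, 0.75)
        )


def _normalize(positions: np.ndarray, intensity: np.ndarray) -> np.ndarray:
    integral = np.trapezoid(intensity, positions)
    if integral <= 0:
        raise ValueError("cannot normalize a profile with non-positive integral")
    return intensity / integral


def lane_profile(
    image: np.ndarray, anchor_col: int, width_px: int = 10
) -> LaneProfile:
    """Average a ``width_px``-wide vertical band into a migration profile.

    ``anchor_col`` is the left column of the band; migration runs along rows.
    The normalized profile integrates to 1 (trapezoid rule).  Normalization is
    idempotent: normalizing an already-normalized profile changes nothing.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("lane_profile expects a 2-D image")
    if anchor_col < 0 or anchor_col + width_px > img.shape[1]:
        raise ValueError("lane band falls outside the image")
    band = img[:, anchor_col : anchor_col + width_px]
    intensity = band.mean(axis=1)
    positions = np.arange(img.shape[0], dtype=np.float64)
    return LaneProfile(
        positions=positions,
        intensity=intensity,
        normalized=_normalize(positions, intensity),
    )


# --------------------------------------------------------------------------
# synthetic test-image generators


def synthetic_cell_image(
    shape: tuple[int, int] = (64, 64),
    total_intensity: float = 1e5,
    punctate_fraction: float = 0.0,
    focus_px: int = 3,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray, EllipseROI]:
    """A single synthetic cell: diffuse signal with an optional bright focus.

    ``punctate_fraction`` of the total intensity is concentrated in a
    ``focus_px``-pixel spot; the rest is spread uniformly over the cell ROI.
    """
    rng = np.random.default_rng(seed)
    img = rng.normal(0.0, noise_sd, shape).astype(np.float64)
    roi = EllipseROI(shape[0] / 2, shape[1] / 2, shape[0] * 0.35, shape[1] * 0.3)
    mask = roi.mask(shape)
    n_px = int(mask.sum())
    diffuse = total_intensity * (1.0 - punctate_fraction) / n_px
    img[mask] += diffuse
    if punctate_fraction > 0:
        rr, cc = np.nonzero(mask)
        pick = rng.choice(len(rr), size=min(focus_px, len(rr)), replace=False)
        img[rr[pick], cc[pick]] += total_intensity * punctate_fraction / len(pick)
    return img, roi


def synthetic_gel_image(
    shape: tuple[int, int] = (200, 120),
    lane_centers_frac: tuple[float, ...] = (0.3, 0.6),
    lane_cols: tuple[int, ...] = (20, 70),
    lane_width: int = 10,
    smear_sd_px: float = 12.0,
    amplitude: float = 500.0,
    background_gradient: float = 0.1,
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """Lanes of Gaussian smears on a smooth gradient background.

    Returns the image and the ground truth (per-lane smear centers in px and
    the clean lane integrals before background was added).
    """
    rng = np.random.default_rng(seed)
    rows = np.arange(shape[0], dtype=np.float64)
    img = np.zeros(shape, dtype=np.float64)
    # smooth background: linear gradient down the gel plus a broad dome
    grad = background_gradient * amplitude * (rows / shape[0])
    img += grad[:, None]
    truth = {"centers_px": [], "integrals": []}
    for center_frac, col in zip(lane_centers_frac, lane_cols):
        center = center_frac * shape[0]
        profile = amplitude * np.exp(-0.5 * ((rows - center) / smear_sd_px) ** 2)
        img[:, col : col + lane_width] += profile[:, None]
        truth["centers_px"].append(center)
        truth["integrals"].append(float(np.trapezoid(profile, rows)))
    img += rng.normal(0.0, amplitude * 1e-3, shape)
    return img, truth
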