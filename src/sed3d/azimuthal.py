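"""Azimuthal intensity profiles at the (200) ring and Bragg-azimuth extraction.

For each centered diffraction pattern a ring of square virtual detectors is
placed at the radius of the cellulose Iβ (200) reflection.  The mean
intensity inside each detector, as a function of azimuth, gives a 360-bin
profile; Friedel symmetry lets the two half-circles be folded (averaged) into
a 180-bin curve.  The curve's first-harmonic-to-DC Fourier ratio scores how
well-defined the Bragg peak is, and the azimuth of the maximum (with circular
parabolic sub-bin refinement) gives the per-pixel Bragg azimuth φ ∈ [0°, 180°).

Azimuth convention: 0° along +x (increasing detector column), increasing
counter-clockwise with "up" = decreasing detector row.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
import numpy as np

from .datamodel import FrameStack, GeometryError, ScalarMap

logger = logging.getLogger(__name__)


class UndefinedPeakError(Exception):
    """The azimuthal curve has no defined maximum (flat curve)."""


@dataclass(frozen=True)
class RingConfig:
    """Geometry of the virtual-detector ring.

    Parameters
    ----------
    radius_inv_A
        |g| of the targeted reflection in 1/Å.  Default 0.258 1/Å, the (200)
        g-vector of cellulose Iβ (d₂₀₀ ≈ 3.88 Å).
    detector_box_inv_A
        Side of each square virtual detector in 1/Å (default 0.04).
    n_detectors
        Number of detectors around the full circle (default 360; even).
    quality_threshold
        Default validity threshold on the first-harmonic-to-DC ratio,
        calibrated on the synthetic suite so pure-noise frames pass at most
        a few percent of the time at typical background counts.
    """

    radius_inv_A: float = 0.258
    detector_box_inv_A: float = 0.04
    n_detectors: int = 360
    quality_threshold: float = 0.05

    def __post_init__(self) -> None:
        if not self.radius_inv_A > 0:
            raise ValueError("radius_inv_A must be > 0")
        if not self.detector_box_inv_A > 0:
            raise ValueError("detector_box_inv_A must be > 0")
        if self.n_detectors % 2 != 0 or self.n_detectors <= 0:
            raise ValueError("n_detectors must be a positive even count")


@dataclass
class AzimuthalProfile:
    """Raw (360-bin) and folded (180-bin) azimuthal intensity curves."""

    raw: np.ndarray
    folded: np.ndarray
    quality: float

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        self.folded = np.asarray(self.folded, dtype=float)
        if self.raw.size != 2 * self.folded.size:
            raise ValueError("raw must have twice as many bins as folded")


@dataclass
class AzimuthMap:
    """Per-scan-pixel Bragg azimuth for one tilt.

    ``phi_deg`` is NaN wherever ``valid`` is False.
    """

    phi_deg: np.ndarray
    quality: np.ndarray
    valid: np.ndarray
    tilt_deg: float

    def __post_init__(self) -> None:
        self.phi_deg = np.asarray(self.phi_deg, dtype=float)
        self.quality = np.asarray(self.quality, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (self.phi_deg.shape == self.quality.shape == self.valid.shape):
            raise ValueError("phi_deg, quality and valid must share a shape")
        self.phi_deg = np.where(self.valid, self.phi_deg, np.nan)

    @property
    def shape(self) -> tuple[int, int]:
        return self.phi_deg.shape

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        ny, nx = self.shape
        rr, cc = np.mgrid[0:ny, 0:nx]
        pd.DataFrame(
            {
                "row": rr.ravel(),
                "col": cc.ravel(),
                "phi_deg": self.phi_deg.ravel(),
                "quality": self.quality.ravel(),
                "valid": self.valid.ravel().astype(int),
            }
        ).to_csv(path, index=False)

    def to_tiff(self, phi_path: str | Path, quality_path: str | Path) -> None:
        import tifffile

        tifffile.imwrite(str(phi_path), self.phi_deg.astype(np.float32))
        tifffile.imwrite(str(quality_path), self.quality.astype(np.float32))


# --------------------------------------------------------------------------
# Ring geometry (cached per detector shape / config)
# --------------------------------------------------------------------------


@lru_cache(maxsize=32)
def _ring_indices(
    shape: tuple[int, int],
    radius_inv_A: float,
    box_inv_A: float,
    n_detectors: int,
    recip_pixel: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Flat pixel indices and detector-bin ids for every (pixel, bin) pair.

    A pixel belongs to detector k when its center falls inside the square box
    of side ``box_inv_A`` centered on the ring at azimuth k·(360/n).  Boxes
    overlap at the default geometry; a pixel may contribute to several bins.
    Returns ``(pix_idx, bin_idx, counts)`` with ``counts[k]`` the number of
    pixels in bin k.
    """
    ky, kx = shape
    cy, cx = (ky - 1) / 2.0, (kx - 1) / 2.0
    half = box_inv_A / 2.0
    # detector-plane coordinates of pixel centers, in 1/Å, y up
    yy, xx = np.mgrid[0:ky, 0:kx]
    px = (xx - cx) * recip_pixel
    py = (cy - yy) * recip_pixel
    rad = np.hypot(px, py)
    # candidates: pixels within radius ± box diagonal
    margin = half * np.sqrt(2.0) + recip_pixel
    cand = np.flatnonzero(
        (np.abs(rad - radius_inv_A) <= margin).ravel()
    )
    cpx = px.ravel()[cand]
    cpy = py.ravel()[cand]
    ang = np.radians(np.arange(n_detectors) * 360.0 / n_detectors)
    bx = radius_inv_A * np.cos(ang)
    by = radius_inv_A * np.sin(ang)
    pix_list, bin_list = [], []
    for k in range(n_detectors):
        inside = (np.abs(cpx - bx[k]) <= half) & (np.abs(cpy - by[k]) <= half)
        idx = cand[inside]
        pix_list.append(idx)
        bin_list.append(np.full(idx.size, k, dtype=np.int32))
    pix_idx = np.concatenate(pix_list)
    bin_idx = np.concatenate(bin_list)
    counts = np.bincount(bin_idx, minlength=n_detectors)
    if np.any(counts == 0):
        raise GeometryError(
            "some virtual detectors contain no pixels; the ring is too fine "
            "for this detector sampling"
        )
    return pix_idx, bin_idx, counts


def _check_ring_fits(shape: tuple[int, int], cfg: RingConfig, recip_pixel: float) -> None:
    ky, kx = shape
    extent = min((ky - 1) / 2.0, (kx - 1) / 2.0) * recip_pixel
    if cfg.radius_inv_A + cfg.detector_box_inv_A / 2.0 > extent:
        raise GeometryError(
            f"ring radius {cfg.radius_inv_A} ± box {cfg.detector_box_inv_A / 2} 1/Å "
            f"does not fit on a detector extending to {extent:.4f} 1/Å"
        )


# --------------------------------------------------------------------------
# Profiles, quality, peak
# --------------------------------------------------------------------------


def ring_profile(
    pattern: np.ndarray, cfg: RingConfig, recip_pixel: float
) -> AzimuthalProfile:
    """Azimuthal intensity profile of one centered pattern.

    Bin k holds the mean intensity inside the square virtual detector at
    azimuth k·(360/n_detectors) degrees on the ring; the folded curve
    averages antipodal bins.
    """
    pattern = np.asarray(pattern, dtype=float)
    _check_ring_fits(pattern.shape, cfg, recip_pixel)
    pix_idx, bin_idx, counts = _ring_indices(
        pattern.shape,
        cfg.radius_inv_A,
        cfg.detector_box_inv_A,
        cfg.n_detectors,
        recip_pixel,
    )
    sums = np.bincount(bin_idx, weights=pattern.ravel()[pix_idx], minlength=cfg.n_detectors)
    raw = sums / counts
    half = cfg.n_detectors // 2
    folded = 0.5 * (raw[:half] + raw[half:])
    return AzimuthalProfile(raw=raw, folded=folded, quality=quality_ratio(folded))


def quality_ratio(folded: np.ndarray) -> float:
    """First-harmonic-to-DC ratio |F₁|/|F₀| of the folded azimuthal curve.

    Higher values indicate a more defined (single) Bragg peak; an all-zero
    curve scores 0.
    """
    folded = np.asarray(folded, dtype=float)
    if np.any(folded < 0):
        raise ValueError("folded curve must be non-negative")
    F = np.fft.rfft(folded)
    dc = np.abs(F[0])
    if dc == 0:
        return 0.0
    return float(np.abs(F[1]) / dc)


def peak_azimuth(folded: np.ndarray, refine: bool = True) -> float:
    """Azimuth (degrees in [0, 180)) of the folded curve's global maximum.

    With ``refine`` a circular three-point parabolic interpolation sharpens
    the estimate to sub-bin precision.  Ties break to the lowest bin index.
    """
    folded = np.asarray(folded, dtype=float)
    if not np.all(np.isfinite(folded)):
        raise ValueError("folded curve must be finite")
    if np.ptp(folded) == 0:
        raise UndefinedPeakError("flat azimuthal curve has no defined peak")
    n = folded.size
    width = 180.0 / n
    j = int(np.argmax(folded))
    if not refine:
        return (j * width) % 180.0
    ym, y0, yp = folded[(j - 1) % n], folded[j], folded[(j + 1) % n]
    denom = ym - 2.0 * y0 + yp
    delta = 0.0 if denom == 0 else 0.5 * (ym - yp) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    return ((j + delta) * width) % 180.0


def azimuth_map(
    stack: FrameStack,
    cfg: RingConfig,
    quality_threshold: float | None = None,
    refine: bool = True,
) -> AzimuthMap:
    """Per-pixel Bragg azimuth, quality and validity for one (centered) tilt stack.

    A pixel is valid when its frame is usable, its profile has a defined
    maximum, and its quality ratio reaches the threshold.  Geometry problems
    on individual frames mark those pixels invalid; they never abort the map.
    """
    if quality_threshold is None:
        quality_threshold = cfg.quality_threshold
    recip_pixel = stack.meta.recip_pixel_inv_A
    ny, nx = stack.scan_shape
    _check_ring_fits(stack.meta.camera_shape, cfg, recip_pixel)
    pix_idx, bin_idx, counts = _ring_indices(
        tuple(stack.meta.camera_shape),
        cfg.radius_inv_A,
        cfg.detector_box_inv_A,
        cfg.n_detectors,
        recip_pixel,
    )
    half = cfg.n_detectors // 2
    phi = np.full((ny, nx), np.nan)
    quality = np.zeros((ny, nx))
    valid = np.zeros((ny, nx), dtype=bool)
    flat = stack.data.reshape(ny * nx, -1)
    frame_ok = stack.valid_frames.ravel()
    for i in range(ny * nx):
        if not frame_ok[i]:
            continue
        sums = np.bincount(
            bin_idx, weights=flat[i][pix_idx], minlength=cfg.n_detectors
        )
        raw = sums / counts
        folded = 0.5 * (raw[:half] + raw[half:])
        q = quality_ratio(folded)
        quality.flat[i] = q
        if q < quality_threshold or np.ptp(folded) == 0:
            continue
        phi.flat[i] = peak_azimuth(folded, refine=refine)
        valid.flat[i] = True
    return AzimuthMap(phi_deg=phi, quality=quality, valid=valid, tilt_deg=stack.meta.tilt_deg)
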