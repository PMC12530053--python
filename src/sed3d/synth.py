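"""Synthetic phantoms and forward-modelled SED observables.

The generator emulates the structures the reconstruction targets: plant cell
walls built from concentric layers of helically wound cellulose fibrils with
alternating handedness.  Two phantom geometries are provided — concentric
annuli (a transversely sectioned cell around a lumen) and stacked horizontal
bands (a longitudinal section) — plus no-signal regions (lumen, embedding
resin, middle lamella).

Forward model: a fibril axis â observed at tilt ω about the vertical (y)
axis diffracts at azimuth φ such that q′ = [cos φ, sin φ, 0] ⊥ R_y(ω)â;
azimuthal measurement noise is wrapped-Gaussian (period 180°).  Rendered
diffraction patterns contain the direct beam, a Poisson background and the
antipodal (200) Bragg spot pair on the ring (a uniform ring for degenerate,
beam-parallel fibrils).  Tilted scans sample the specimen on the
foreshortened grid, as tilting a flat section does.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .azimuthal import AzimuthMap, RingConfig
from .datamodel import AcquisitionMeta, FrameStack, ScalarMap
from .analysis import axis_from_angles
from .reconstruct import rotation_y

logger = logging.getLogger(__name__)


class PhantomSpecError(Exception):
    """A phantom layer specification is inconsistent (e.g. overlapping layers)."""


@dataclass
class NoiseSpec:
    """Noise model for simulated observables.

    ``azimuth_sigma_deg`` is the circular (wrapped-Gaussian, period 180°)
    noise on Bragg azimuths — default 3°, the scale consistent with the
    dispersion of reconstructed orientations in real cell-wall data.
    ``background_level`` (Poisson mean per detector pixel) and ``peak_snr``
    (Bragg peak amplitude over background) control rendered frames.  The seed
    is recorded in simulation outputs.
    """

    azimuth_sigma_deg: float = 3.0
    background_level: float = 2.0
    peak_snr: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.azimuth_sigma_deg < 0:
            raise ValueError("azimuth_sigma_deg must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class LayerSpec:
    """One phantom layer.

    For annular geometry the layer occupies radii [r_in_px, r_out_px); for
    band geometry rows [r_in_px, r_out_px).  Orientation is either constant
    (``in_plane_deg``/``out_of_plane_deg``) or helical (``helix_angle_deg`` +
    ``handedness``, annular geometry only), where the axis follows the local
    hoop tangent tilted by the helix angle toward the cell axis (beam, z).
    """

    r_in_px: float
    r_out_px: float
    in_plane_deg: float | None = None
    out_of_plane_deg: float | None = None
    helix_angle_deg: float | None = None
    handedness: str = "right"
    label: int = 0

    def __post_init__(self) -> None:
        constant = self.in_plane_deg is not None and self.out_of_plane_deg is not None
        helical = self.helix_angle_deg is not None
        if constant == helical:
            raise PhantomSpecError(
                "a layer needs either (in_plane_deg, out_of_plane_deg) or helix_angle_deg"
            )
        if not self.r_out_px > self.r_in_px >= 0:
            raise PhantomSpecError("layer radii must satisfy 0 <= r_in < r_out")


@dataclass
class Phantom:
    """Ground-truth axis field with region labels.

    ``axes`` is (ny, nx, 3) with NaN rows where there is no signal;
    ``labels`` holds layer ids (0 = lumen / resin / no signal).
    """

    axes: np.ndarray
    labels: np.ndarray
    step_nm: float
    layers: list[LayerSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.axes = np.asarray(self.axes, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.axes.shape[:2] != self.labels.shape or self.axes.shape[-1] != 3:
            raise ValueError("axes must be (ny, nx, 3) matching labels")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def has_signal(self) -> np.ndarray:
        return self.labels > 0


# --------------------------------------------------------------------------
# Phantom construction
# --------------------------------------------------------------------------


def make_phantom(
    shape: tuple[int, int],
    layers: Sequence[LayerSpec],
    geometry: str = "annular",
    center: tuple[float, float] | None = None,
    step_nm: float = 100.0,
) -> Phantom:
    """Assemble a ground-truth phantom from a layer list.

    ``geometry="annular"`` places layers as concentric annuli about
    ``center`` (transverse section, cell axis along the beam);
    ``geometry="bands"`` stacks them as horizontal row bands (longitudinal
    section).  Layers must not overlap.  Unclaimed pixels (lumen inside the
    innermost annulus, resin outside) carry label 0 and no axis.
    """
    ny, nx = shape
    if geometry not in ("annular", "bands"):
        raise ValueError(f"unknown phantom geometry {geometry!r}")
    intervals = sorted((l.r_in_px, l.r_out_px) for l in layers)
    for (a0, a1), (b0, b1) in zip(intervals, intervals[1:]):
        if b0 < a1:
            raise PhantomSpecError(f"layers overlap: [{a0},{a1}) and [{b0},{b1})")

    labeled = list(layers)
    next_label = 1
    for l in labeled:
        if l.label == 0:
            l.label = next_label
        next_label = max(next_label, l.label) + 1

    rr, cc = np.mgrid[0:ny, 0:nx].astype(float)
    if center is None:
        center = ((ny - 1) / 2.0, (nx - 1) / 2.0)
    cy, cx = center
    if geometry == "annular":
        coord = np.hypot(rr - cy, cc - cx)
    else:
        coord = rr

    axes = np.full((ny, nx, 3), np.nan)
    labels = np.zeros((ny, nx), dtype=np.int32)
    for l in labeled:
        sel = (coord >= l.r_in_px) & (coord < l.r_out_px)
        labels[sel] = l.label
        if l.helix_angle_deg is not None:
            if geometry != "annular":
                raise PhantomSpecError("helical layers require annular geometry")
            psi = np.radians(l.helix_angle_deg)
            h = 1.0 if l.handedness == "right" else -1.0
            # local outward radial and hoop tangent; physical frame is x right,
            # y up (decreasing row), z along the cell axis (beam direction)
            rx = (cc - cx)[sel]
            ry = (cy - rr)[sel]
            norm = np.maximum(np.hypot(rx, ry), 1e-12)
            tx, ty = -ry / norm, rx / norm  # t = ẑ × r̂
            a = np.stack(
                [
                    h * np.sin(psi) * tx,
                    h * np.sin(psi) * ty,
                    np.full(tx.shape, np.cos(psi)),
                ],
                axis=-1,
            )
            flip = a[:, 2] < 0
            a[flip] *= -1.0
            axes[sel] = a
        else:
            axes[sel] = axis_from_angles((l.in_plane_deg, l.out_of_plane_deg))
    return Phantom(axes=axes, labels=labels, step_nm=step_nm, layers=labeled)


def oat_transverse_phantom(
    shape: tuple[int, int] = (256, 256),
    layer_angles: Sequence[tuple[float, float]] | None = None,
    lumen_radius_px: float | None = None,
    layer_thickness_px: float | None = None,
    step_nm: float = 40.0,
) -> Phantom:
    """Seven-layer annular phantom with the oat-husk transverse layer angles.

    Concentric layers of alternating handedness around a central lumen,
    sized to fill the grid.
    """
    from . import datasets

    if layer_angles is None:
        layer_angles = datasets.OAT_TRANSVERSE_LAYERS
    n = len(layer_angles)
    half = min(shape) / 2.0
    if lumen_radius_px is None:
        lumen_radius_px = 0.32 * half
    if layer_thickness_px is None:
        layer_thickness_px = (0.97 * half - lumen_radius_px) / n
    layers = [
        LayerSpec(
            r_in_px=lumen_radius_px + i * layer_thickness_px,
            r_out_px=lumen_radius_px + (i + 1) * layer_thickness_px,
            in_plane_deg=phi,
            out_of_plane_deg=theta,
            label=i + 1,
        )
        for i, (phi, theta) in enumerate(layer_angles)
    ]
    return make_phantom(shape, layers, geometry="annular", step_nm=step_nm)


# --------------------------------------------------------------------------
# Forward model
# --------------------------------------------------------------------------


def forward_azimuth(a_hat: np.ndarray, omega_deg: float) -> np.ndarray:
    """Bragg azimuth φ ∈ [0°, 180°) of an axis observed at tilt ω.

    With â′ = R_y(ω)â, the measured azimuth satisfies
    [cos φ, sin φ, 0] ⊥ â′, i.e. φ = atan2(−â′_x, â′_y) mod 180°.  Axes
    (anti)parallel to the beam at this tilt (â′_x² + â′_y² < 1e-16) have no
    preferred azimuth (the whole ring diffracts) and return NaN.

    Vectorized over leading dimensions of ``a_hat``.
    """
    a = np.asarray(a_hat, dtype=float)
    ap = a @ rotation_y(omega_deg).T
    rho2 = ap[..., 0] ** 2 + ap[..., 1] ** 2
    phi = np.degrees(np.arctan2(-ap[..., 0], ap[..., 1])) % 180.0
    return np.where(rho2 < 1e-16, np.nan, phi)


def _foreshortened_source_cols(nx: int, omega_deg: float) -> np.ndarray:
    """Zero-tilt column index sampled by each tilted-scan column.

    Tilting a flat section about the vertical axis compresses its image
    along x by cos ω, so scan column c of the tilted acquisition probes the
    specimen at zero-tilt column cx + (c − cx)/cos ω.
    """
    cx = (nx - 1) / 2.0
    cols = np.arange(nx, dtype=float)
    return cx + (cols - cx) / np.cos(np.radians(omega_deg))


def _sample_phantom(
    phantom: Phantom, omega_deg: float, foreshorten: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-neighbour sample of (axes, labels) on the tilted scan grid."""
    ny, nx = phantom.shape
    if foreshorten and omega_deg != 0.0:
        src = np.rint(_foreshortened_source_cols(nx, omega_deg)).astype(int)
        in_field = (src >= 0) & (src < nx)
        src_c = np.clip(src, 0, nx - 1)
        axes = phantom.axes[:, src_c, :].copy()
        labels = phantom.labels[:, src_c].copy()
        axes[:, ~in_field, :] = np.nan
        labels[:, ~in_field] = 0
    else:
        axes = phantom.axes.copy()
        labels = phantom.labels.copy()
    return axes, labels


def simulate_azimuth_maps(
    phantom: Phantom,
    tilts_deg: Sequence[float],
    noise: NoiseSpec | None = None,
    foreshorten: bool = True,
) -> list[AzimuthMap]:
    """Per-tilt azimuth maps forward-modelled from a phantom.

    Each tilted map samples the phantom on its foreshortened grid, applies
    the forward azimuth model and adds wrapped-Gaussian noise (period 180°).
    No-signal and degenerate (beam-parallel) pixels are invalid.  Output is
    deterministic for a given ``noise.seed``.
    """
    if noise is None:
        noise = NoiseSpec(azimuth_sigma_deg=0.0)
    if len(set(tilts_deg)) != len(tilts_deg):
        raise ValueError("tilt angles must be distinct")
    rng = noise.rng()
    maps = []
    for omega in tilts_deg:
        axes, labels = _sample_phantom(phantom, omega, foreshorten)
        phi = forward_azimuth(axes, omega)
        valid = (labels > 0) & np.isfinite(phi)
        if noise.azimuth_sigma_deg > 0:
            phi = (phi + rng.normal(0.0, noise.azimuth_sigma_deg, size=phi.shape)) % 180.0
        quality = np.where(valid, 1.0, 0.0)
        maps.append(
            AzimuthMap(
                phi_deg=np.where(valid, phi, np.nan),
                quality=quality,
                valid=valid,
                tilt_deg=float(omega),
            )
        )
    return maps


def signal_maps(maps: Sequence[AzimuthMap]) -> list[ScalarMap]:
    """Companion intensity channels (signal presence) for registration."""
    return [ScalarMap(m.valid.astype(float), units="signal") for m in maps]


# --------------------------------------------------------------------------
# Frame rendering
# --------------------------------------------------------------------------


def _gaussian_patch(shape, row0, col0, amplitude, sigma):
    """Paint a Gaussian into a bounding-box patch; returns (slices, patch)."""
    ky, kx = shape
    r = int(np.ceil(4 * sigma))
    r0, r1 = max(0, int(row0) - r), min(ky, int(row0) + r + 1)
    c0, c1 = max(0, int(col0) - r), min(kx, int(col0) + r + 1)
    if r0 >= r1 or c0 >= c1:
        return None, None
    yy, xx = np.mgrid[r0:r1, c0:c1]
    patch = amplitude * np.exp(
        -((yy - row0) ** 2 + (xx - col0) ** 2) / (2.0 * sigma**2)
    )
    return (slice(r0, r1), slice(c0, c1)), patch


def render_patterns(
    phantom: Phantom,
    omega_deg: float,
    ring: RingConfig,
    detector_shape: tuple[int, int] = (128, 128),
    recip_pixel_inv_A: float = 0.005,
    noise: NoiseSpec | None = None,
    foreshorten: bool = True,
    spot_sigma_px: float = 1.8,
    beam_amplitude: float | None = None,
    dtype=np.uint16,
) -> FrameStack:
    """Render a full 4D diffraction stack for one tilt of a phantom.

    Each frame holds a Poisson background, a central direct beam, and — for
    fibril-bearing pixels — the antipodal (200) Bragg-spot pair at the ring
    radius at azimuths φ and φ+180° (wrapped-Gaussian azimuth noise applied).
    Degenerate pixels (fibril along the beam) render a uniform ring.  Counts
    are Poisson-sampled from the expected pattern; no-signal pixels get
    background (and beam) only.
    """
    if noise is None:
        noise = NoiseSpec()
    rng = noise.rng()
    ky, kx = detector_shape
    cy, cx = (ky - 1) / 2.0, (kx - 1) / 2.0
    r_px = ring.radius_inv_A / recip_pixel_inv_A
    if r_px + ring.detector_box_inv_A / recip_pixel_inv_A / 2 > min(cy, cx):
        raise ValueError("ring does not fit on the requested detector")

    axes, labels = _sample_phantom(phantom, omega_deg, foreshorten)
    phi = forward_azimuth(axes, omega_deg)
    if noise.azimuth_sigma_deg > 0:
        jitter = rng.normal(0.0, noise.azimuth_sigma_deg, size=phi.shape)
        phi = np.where(np.isfinite(phi), (phi + jitter) % 180.0, phi)

    bg = noise.background_level
    amp = noise.peak_snr * max(bg, 1e-6)
    if beam_amplitude is None:
        beam_amplitude = 20.0 * amp
    base = np.full((ky, kx), bg, dtype=float)
    sl, patch = _gaussian_patch((ky, kx), cy, cx, beam_amplitude, 2.0)
    base[sl] += patch
    yy, xx = np.mgrid[0:ky, 0:kx]
    rad = np.hypot(yy - cy, xx - cx)
    ring_band = np.exp(-((rad - r_px) ** 2) / (2.0 * spot_sigma_px**2))
    ring_level = amp * spot_sigma_px / max(r_px, 1.0)

    ny, nx = phantom.shape
    data = np.empty((ny, nx, ky, kx), dtype=dtype)
    expected_row = np.empty((nx, ky, kx), dtype=float)
    for r in range(ny):
        expected_row[:] = base[None, :, :]
        for c in range(nx):
            if labels[r, c] <= 0:
                continue
            f = phi[r, c]
            if not np.isfinite(f):  # beam-parallel fibril: full ring
                expected_row[c] += ring_level * ring_band
                continue
            frad = np.radians(f)
            sx, sy = r_px * np.cos(frad), r_px * np.sin(frad)
            for sgn in (+1.0, -1.0):
                sl, patch = _gaussian_patch(
                    (ky, kx), cy - sgn * sy, cx + sgn * sx, amp, spot_sigma_px
                )
                if sl is not None:
                    expected_row[c][sl] += patch
        data[r] = rng.poisson(expected_row).astype(dtype)

    meta = AcquisitionMeta(
        tilt_deg=float(omega_deg),
        step_nm=phantom.step_nm,
        recip_pixel_inv_A=recip_pixel_inv_A,
        camera_shape=(ky, kx),
    )
    stack = FrameStack(data, meta)
    stack.valid_frames = np.ones(phantom.shape, dtype=bool)
    return stack
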