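"""Data model and I/O for tilt-series 4D scanning electron diffraction stacks.

A scanning electron diffraction (SED) acquisition records a full 2D
diffraction pattern at every beam position of a raster scan, producing a 4D
array ``(scan_y, scan_x, det_ky, det_kx)`` per tilt angle.  This module
defines the in-memory containers for such stacks, an HDF5 layout for storing
a tilt series in a single self-describing file, beam centering, virtual
imaging and electron-dose bookkeeping.

Coordinate conventions (used throughout the package)
----------------------------------------------------
* Scan raster: row-major, x = fast axis (columns), y = slow axis (rows).
  The tilt axis is the vertical image direction (y).  Origin top-left,
  y increasing downward in array indices.
* Detector: azimuth 0 lies along +x (columns increasing), positive azimuth
  counter-clockwise with detector "up" taken as decreasing row index.
* The geometric detector center is ``((n_ky - 1) / 2, (n_kx - 1) / 2)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
import h5py
import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

ELEMENTARY_CHARGE_C = 1.602176634e-19


class FormatError(Exception):
    """An input file does not conform to the declared layout."""


class GeometryError(Exception):
    """A requested detector/scan geometry is impossible."""


class SizeError(Exception):
    """Array sizes are inconsistent with the declared scan shape."""


class OrderingError(Exception):
    """A frame stream cannot be placed into raster order unambiguously."""


# --------------------------------------------------------------------------
# Acquisition metadata
# --------------------------------------------------------------------------

#: HDF5 attribute names considered optional, with their defaults.
_OPTIONAL_META_DEFAULTS = {
    "tilt_deg": 0.0,
    "beam_current_pA": 2.0,
    "dwell_ms": 5.0,
    "beam_diameter_nm": 8.0,
}


@dataclass
class AcquisitionMeta:
    """Acquisition parameters for one tilt of a SED tilt series.

    Parameters
    ----------
    tilt_deg
        Sample tilt about the vertical (y) axis, signed degrees. |tilt| < 90.
    step_nm
        Scan step size in nm (> 0).
    recip_pixel_inv_A
        Reciprocal-space pixel size on the detector, in 1/Å per pixel (> 0).
    beam_current_pA, dwell_ms, beam_diameter_nm
        Beam current (pA), dwell time per position (ms) and beam diameter
        (nm); used only for dose bookkeeping.
    camera_shape
        Detector (rows, cols).
    """

    tilt_deg: float = 0.0
    step_nm: float = 100.0
    recip_pixel_inv_A: float = 0.005
    beam_current_pA: float = 2.0
    dwell_ms: float = 5.0
    beam_diameter_nm: float = 8.0
    camera_shape: tuple[int, int] = (128, 128)

    def __post_init__(self) -> None:
        if not self.step_nm > 0:
            raise ValueError(f"step_nm must be > 0, got {self.step_nm}")
        if not self.recip_pixel_inv_A > 0:
            raise ValueError(
                f"recip_pixel_inv_A must be > 0, got {self.recip_pixel_inv_A}"
            )
        if not abs(self.tilt_deg) < 90:
            raise ValueError(f"|tilt_deg| must be < 90, got {self.tilt_deg}")
        self.camera_shape = tuple(int(v) for v in self.camera_shape)


# --------------------------------------------------------------------------
# Containers
# --------------------------------------------------------------------------


@dataclass
class FrameStack:
    """A 4D diffraction stack ``(scan_y, scan_x, det_ky, det_kx)`` for one tilt.

    Attributes
    ----------
    data
        Non-negative intensities.
    meta
        Acquisition metadata; ``meta.camera_shape`` must match the detector
        dimensions of ``data``.
    center
        Per-frame beam center, detector (row, col); defaults to the geometric
        detector center for every frame.
    valid_frames
        Boolean per-scan-pixel mask; frames flagged False (e.g. all-zero
        frames found during centering) are skipped downstream.
    stream_order
        If the stack was reassembled from a raw stream, the inverse
        permutation mapping raster position -> original stream index.
    """

    data: np.ndarray
    meta: AcquisitionMeta
    center: np.ndarray | None = None
    valid_frames: np.ndarray | None = None
    stream_order: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"data must be 4D, got shape {self.data.shape}")
        if np.any(np.asarray(self.data) < 0):
            raise ValueError("diffraction intensities must be non-negative")
        if tuple(self.data.shape[2:]) != tuple(self.meta.camera_shape):
            raise ValueError(
                f"detector dims {self.data.shape[2:]} do not match "
                f"camera_shape {self.meta.camera_shape}"
            )
        ny, nx = self.scan_shape
        if self.center is None:
            cy, cx = self.detector_center
            self.center = np.broadcast_to(
                np.array([cy, cx]), (ny, nx, 2)
            ).copy()
        self.center = np.asarray(self.center, dtype=float)
        if self.center.shape != (ny, nx, 2):
            raise ValueError("center must have shape (scan_y, scan_x, 2)")
        ky, kx = self.meta.camera_shape
        if (
            np.any(self.center[..., 0] < 0)
            or np.any(self.center[..., 0] > ky - 1)
            or np.any(self.center[..., 1] < 0)
            or np.any(self.center[..., 1] > kx - 1)
        ):
            raise ValueError("beam centers must lie within detector bounds")
        if self.valid_frames is None:
            self.valid_frames = np.ones((ny, nx), dtype=bool)
        self.valid_frames = np.asarray(self.valid_frames, dtype=bool)

    @property
    def scan_shape(self) -> tuple[int, int]:
        return self.data.shape[:2]

    @property
    def detector_center(self) -> tuple[float, float]:
        ky, kx = self.meta.camera_shape
        return ((ky - 1) / 2.0, (kx - 1) / 2.0)


@dataclass
class ScalarMap:
    """A scalar quantity on the scan grid (e.g. a virtual-detector image)."""

    values: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("ScalarMap values must be 2D")

    def to_tiff(self, path: str | Path) -> None:
        import tifffile

        tifffile.imwrite(str(path), self.values.astype(np.float32))

    def to_csv(self, path: str | Path) -> None:
        np.savetxt(str(path), self.values, delimiter=",")


# --------------------------------------------------------------------------
# HDF5 layout
# --------------------------------------------------------------------------
# One group per tilt (any name; conventionally "tilt_<deg>"), holding a 4D
# dataset "data" with dims (scan_y, scan_x, ky, kx) and the attributes
# tilt_deg / step_nm / recip_pixel_inv_A / beam_current_pA / dwell_ms /
# beam_diameter_nm on the group.

_REQUIRED_ATTRS = ("step_nm", "recip_pixel_inv_A")


def tilt_group_name(tilt_deg: float) -> str:
    return f"tilt_{tilt_deg:+.1f}"


def save_framestack(path: str | Path, stack: FrameStack, group: str | None = None) -> None:
    """Write a FrameStack into the tilt-series HDF5 layout (append mode)."""
    name = group or tilt_group_name(stack.meta.tilt_deg)
    with h5py.File(str(path), "a") as f:
        if name in f:
            del f[name]
        g = f.create_group(name)
        g.create_dataset("data", data=stack.data)
        g.create_dataset("center", data=stack.center)
        g.create_dataset("valid_frames", data=stack.valid_frames)
        if stack.stream_order is not None:
            g.create_dataset("stream_order", data=stack.stream_order)
        for key in (
            "tilt_deg",
            "step_nm",
            "recip_pixel_inv_A",
            "beam_current_pA",
            "dwell_ms",
            "beam_diameter_nm",
        ):
            g.attrs[key] = getattr(stack.meta, key)
        g.attrs["camera_shape"] = stack.meta.camera_shape


def load_framestack(path: str | Path, group: str | None = None) -> FrameStack:
    """Load one tilt's stack from the HDF5 layout.

    If ``group`` is None and the file holds exactly one group, that group is
    used.  Missing optional metadata attributes fall back to documented
    defaults (see :data:`_OPTIONAL_META_DEFAULTS`) with a logged warning;
    missing required datasets or attributes raise :class:`FormatError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        f = h5py.File(str(path), "r")
    except OSError as exc:  # truncated / not HDF5
        raise FormatError(f"{path} is not a readable HDF5 file: {exc}") from exc
    try:
        return _read_framestack(f, path, group)
    except (OSError, KeyError) as exc:  # truncated payload
        raise FormatError(f"{path} is corrupt or truncated: {exc}") from exc
    finally:
        f.close()


def _read_framestack(f: h5py.File, path: Path, group: str | None) -> FrameStack:
    if group is None:
        groups = [k for k in f.keys() if isinstance(f[k], h5py.Group)]
        if len(groups) != 1:
            raise FormatError(
                f"{path} holds {len(groups)} groups; specify one of {groups}"
            )
        group = groups[0]
    if group not in f:
        raise FormatError(f"missing group '{group}' in {path}")
    g = f[group]
    if "data" not in g:
        raise FormatError(f"missing required dataset '{group}/data' in {path}")
    data = g["data"][...]
    attrs = dict(g.attrs)
    kwargs: dict = {}
    for key in _REQUIRED_ATTRS:
        if key not in attrs:
            raise FormatError(f"missing required attribute '{group}@{key}' in {path}")
        kwargs[key] = float(attrs[key])
    for key, default in _OPTIONAL_META_DEFAULTS.items():
        if key in attrs:
            kwargs[key] = float(attrs[key])
        else:
            logger.warning(
                "attribute '%s@%s' missing in %s; defaulting to %r",
                group, key, path, default,
            )
            kwargs[key] = default
    meta = AcquisitionMeta(camera_shape=data.shape[2:], **kwargs)
    center = g["center"][...] if "center" in g else None
    valid = g["valid_frames"][...] if "valid_frames" in g else None
    order = g["stream_order"][...] if "stream_order" in g else None
    return FrameStack(data, meta, center=center, valid_frames=valid, stream_order=order)


def list_tilt_groups(path: str | Path) -> list[str]:
    with h5py.File(str(path), "r") as f:
        return [k for k in f.keys() if isinstance(f[k], h5py.Group) and "data" in f[k]]


# --------------------------------------------------------------------------
# Stream reassembly
# --------------------------------------------------------------------------


def reassemble_stream(
    frames: np.ndarray,
    scan_shape: tuple[int, int],
    drift_model: np.ndarray,
    meta: AcquisitionMeta | None = None,
    tie_tol: float = 1e-6,
) -> FrameStack:
    """Arrange a raw frame stream into a raster-ordered 4D stack.

    During scanning a small systematic beam tilt shifts the diffraction
    patterns on the detector in proportion to the beam position; those
    per-frame shift estimates locate each frame within the scan raster.

    Parameters
    ----------
    frames
        ``(n, ky, kx)`` array of patterns in stream order.
    scan_shape
        ``(rows, cols)`` of the scan; ``n`` must equal ``rows * cols``.
    drift_model
        Either ``(n, 2)`` per-frame ``(slow, fast)`` shift coordinates
        (arbitrary units, monotone in scan position), used to sort frames
        into raster order globally; or ``(n,)`` fast-axis shifts with rows
        taken as consecutive chunks of ``cols`` frames, sorted within rows.
    meta
        Metadata for the resulting stack (camera_shape inferred if omitted).

    Returns
    -------
    FrameStack with ``stream_order[r, c]`` = index of the frame (in the
    input stream) placed at raster position (r, c).
    """
    frames = np.asarray(frames)
    rows, cols = (int(v) for v in scan_shape)
    n = frames.shape[0]
    if n != rows * cols:
        raise SizeError(f"{n} frames cannot fill a {rows}x{cols} raster")
    drift = np.asarray(drift_model, dtype=float)
    if drift.ndim == 2 and drift.shape == (n, 2):
        order = np.lexsort((drift[:, 1], drift[:, 0]))
    elif drift.shape == (n,):
        order = np.empty(n, dtype=int)
        for r in range(rows):
            chunk = slice(r * cols, (r + 1) * cols)
            order[chunk] = np.argsort(drift[chunk], kind="stable") + r * cols
        drift = np.column_stack([np.repeat(np.arange(rows), cols), drift])
    else:
        raise ValueError("drift_model must have shape (n,) or (n, 2)")
    fast_sorted = drift[order, 1].reshape(rows, cols)
    # A row whose shifts are all identical (e.g. all zero) is taken as already
    # ordered and passes through in stream order.  Otherwise the sorted shifts
    # must be strictly increasing: duplicate shift values inside a row make
    # the placement of those frames ambiguous.
    for r in range(rows):
        row = fast_sorted[r]
        if np.ptp(row) <= tie_tol:
            continue
        if np.any(np.diff(row) < tie_tol):
            raise OrderingError(
                f"fast-scan shifts are not strictly monotone within row {r} "
                f"(ambiguous ordering within tolerance {tie_tol})"
            )
    data = frames[order].reshape(rows, cols, *frames.shape[1:])
    if meta is None:
        meta = AcquisitionMeta(camera_shape=frames.shape[1:])
    return FrameStack(data, meta, stream_order=order.reshape(rows, cols))


# --------------------------------------------------------------------------
# Beam centering
# --------------------------------------------------------------------------


def center_patterns(stack: FrameStack, window_radius: float | None = None) -> FrameStack:
    """Center each pattern so the beam COM sits at the geometric detector center.

    The center of mass of intensity inside a disk of ``window_radius`` pixels
    around the geometric center is computed per frame and the pattern is
    translated (sub-pixel, linear interpolation) by the opposite offset.
    Frames with zero intensity inside the window are flagged invalid and left
    unshifted.  The recorded ``center`` is updated to the geometric center
    for shifted frames.
    """
    ky, kx = stack.meta.camera_shape
    if window_radius is None:
        window_radius = min(ky, kx) / 4.0
    if not window_radius < min(ky, kx) / 2.0:
        raise ValueError("window_radius must be smaller than half the detector")
    cy, cx = stack.detector_center
    yy, xx = np.mgrid[0:ky, 0:kx]
    window = (yy - cy) ** 2 + (xx - cx) ** 2 <= window_radius**2
    wy = yy[window].astype(float)
    wx = xx[window].astype(float)

    ny, nx = stack.scan_shape
    out = np.array(stack.data, dtype=float)
    center = stack.center.copy()
    valid = stack.valid_frames.copy()
    for r in range(ny):
        for c in range(nx):
            frame = out[r, c]
            w = frame[window]
            total = w.sum()
            if total <= 0:
                valid[r, c] = False
                continue
            com_y = float((w * wy).sum() / total)
            com_x = float((w * wx).sum() / total)
            dy, dx = cy - com_y, cx - com_x
            if abs(dy) > 1e-12 or abs(dx) > 1e-12:
                out[r, c] = ndimage.shift(frame, (dy, dx), order=1, mode="constant")
            center[r, c] = (cy, cx)
    return replace(stack, data=out, center=center, valid_frames=valid)


# --------------------------------------------------------------------------
# Virtual imaging
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class AnnulusSpec:
    """An annular virtual detector, radii in 1/Å about the detector center."""

    r_in_inv_A: float
    r_out_inv_A: float


def _region_mask(stack: FrameStack, region) -> np.ndarray:
    ky, kx = stack.meta.camera_shape
    if isinstance(region, AnnulusSpec):
        rp = stack.meta.recip_pixel_inv_A
        cy, cx = stack.detector_center
        yy, xx = np.mgrid[0:ky, 0:kx]
        r = np.hypot(yy - cy, xx - cx) * rp
        mask = (r >= region.r_in_inv_A) & (r <= region.r_out_inv_A)
    else:
        mask = np.asarray(region, dtype=bool)
        if mask.shape != (ky, kx):
            raise GeometryError(
                f"region mask shape {mask.shape} does not match detector {(ky, kx)}"
            )
    if not mask.any():
        raise ValueError("virtual-detector region is empty")
    return mask


def virtual_image(stack: FrameStack, region) -> ScalarMap:
    """Per-scan-pixel total intensity inside a detector region.

    ``region`` is a boolean detector mask or an :class:`AnnulusSpec`.
    """
    mask = _region_mask(stack, region)
    values = stack.data[..., mask].sum(axis=-1)
    return ScalarMap(values.astype(float), units="counts")


# --------------------------------------------------------------------------
# Dose bookkeeping
# --------------------------------------------------------------------------


def estimate_dose(meta: AcquisitionMeta) -> float:
    """Electron dose in e⁻/Å² delivered per beam position.

    dose = (I * t / e) / (pi (d/2)^2) with the beam modelled as a
    full-diameter disk of diameter ``beam_diameter_nm``.  Note that a
    FWHM-based beam area would give a proportionally higher dose; the
    disk definition is the documented default.
    """
    if not (meta.beam_current_pA > 0 and meta.dwell_ms > 0 and meta.beam_diameter_nm > 0):
        raise ValueError("beam current, dwell time and beam diameter must be > 0")
    electrons = (meta.beam_current_pA * 1e-12) * (meta.dwell_ms * 1e-3) / ELEMENTARY_CHARGE_C
    radius_A = meta.beam_diameter_nm * 10.0 / 2.0
    return electrons / (np.pi * radius_A**2)
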