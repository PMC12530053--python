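"""Registration of per-tilt azimuth maps into the zero-tilt pixel frame.

Tilting a flat section about the vertical axis foreshortens its image along
x by cos ω; the per-tilt maps must be warped into a common (zero-tilt) frame
so every pixel aggregates diffraction from the same specimen position.  The
warp is initialized from the known tilt geometry and optionally refined by
maximizing normalized cross-correlation of companion intensity maps under a
projective transform.  Azimuth maps are warped with nearest-neighbour
interpolation — azimuths are angular labels and must never be blended —
and validity masks are AND-propagated and eroded by one pixel to suppress
resampling artifacts at field edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation
from skimage.transform import ProjectiveTransform, estimate_transform, warp

from .azimuthal import AzimuthMap
from .datamodel import GeometryError, ScalarMap

logger = logging.getLogger(__name__)

DEFAULT_CORRELATION_FLOOR = 0.2


class AlignmentError(Exception):
    """Registration failed; carries the best transform found."""

    def __init__(self, message: str, transform: "PlaneTransform | None" = None,
                 correlation: float = float("nan")):
        super().__init__(message)
        self.transform = transform
        self.correlation = correlation


@dataclass
class PlaneTransform:
    """A 3×3 homogeneous projective map, tilted-map pixels → zero-tilt pixels.

    Points are (x, y) = (col, row).  The matrix is normalized so its
    bottom-right element is 1.
    """

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError("matrix must be 3x3")
        if abs(m[2, 2]) < 1e-12 or not np.isfinite(np.linalg.cond(m)) or np.linalg.cond(m) > 1e12:
            raise ValueError("matrix must be invertible with nonzero scale")
        self.matrix = m / m[2, 2]

    @classmethod
    def identity(cls) -> "PlaneTransform":
        return cls(np.eye(3))

    @classmethod
    def translation(cls, dx: float, dy: float) -> "PlaneTransform":
        m = np.eye(3)
        m[0, 2], m[1, 2] = dx, dy
        return cls(m)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map (N, 2) (x, y) points through the transform."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        h = np.column_stack([pts, np.ones(len(pts))]) @ self.matrix.T
        return h[:, :2] / h[:, 2:3]

    def inverse(self) -> "PlaneTransform":
        return PlaneTransform(np.linalg.inv(self.matrix))

    def compose(self, other: "PlaneTransform") -> "PlaneTransform":
        """self ∘ other (apply ``other`` first)."""
        return PlaneTransform(self.matrix @ other.matrix)

    def is_identity(self, tol: float = 1e-12) -> bool:
        return bool(np.allclose(self.matrix, np.eye(3), atol=tol))


@dataclass
class TiltSeries:
    """Azimuth maps warped into the common zero-tilt frame."""

    maps: list[AzimuthMap]
    transforms: list[PlaneTransform]
    tilts_deg: list[float]

    def __post_init__(self) -> None:
        if not (len(self.maps) == len(self.transforms) == len(self.tilts_deg)):
            raise ValueError("one map, transform and tilt per entry")
        shapes = {m.shape for m in self.maps}
        if len(shapes) != 1:
            raise ValueError("maps must share a shape after warping")
        if len(set(self.tilts_deg)) != len(self.tilts_deg):
            raise ValueError("tilt angles must be distinct")


# --------------------------------------------------------------------------
# Geometric initialization
# --------------------------------------------------------------------------


def foreshorten_transform(omega_deg: float, shape: tuple[int, int]) -> PlaneTransform:
    """Tilt-foreshortening correction about the map center.

    Stretches the axis perpendicular to the (vertical) tilt axis by
    1/cos ω; the tilt axis itself is unchanged.
    """
    if not abs(omega_deg) < 90:
        raise GeometryError(f"|tilt| must be < 90°, got {omega_deg}")
    ny, nx = shape
    cx = (nx - 1) / 2.0
    s = 1.0 / np.cos(np.radians(omega_deg))
    m = np.array([[s, 0.0, cx * (1.0 - s)], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
    return PlaneTransform(m)


# --------------------------------------------------------------------------
# Correlation refinement
# --------------------------------------------------------------------------


def _as_array(m) -> np.ndarray:
    return m.values if isinstance(m, ScalarMap) else np.asarray(m, dtype=float)


def _warp_scalar(values: np.ndarray, t: PlaneTransform, order: int = 1,
                 output_shape=None, cval: float = np.nan) -> np.ndarray:
    """Warp a scalar map into the zero-tilt frame (t: moving → reference)."""
    inv = ProjectiveTransform(matrix=t.inverse().matrix)
    return warp(
        values.astype(float),
        inverse_map=inv,
        order=order,
        cval=cval,
        output_shape=output_shape,
        preserve_range=True,
        mode="constant",
    )


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    mask = np.isfinite(a) & np.isfinite(b)
    if mask.sum() < 16:
        return -1.0
    av = a[mask] - a[mask].mean()
    bv = b[mask] - b[mask].mean()
    denom = np.sqrt((av**2).sum() * (bv**2).sum())
    if denom == 0:
        return -1.0
    return float((av * bv).sum() / denom)


def _patch_correspondence_stage(
    ref: np.ndarray,
    mov: np.ndarray,
    cur: PlaneTransform,
    rounds: int = 6,
    ngrid: int = 5,
    frac: float = 0.4,
    order: int = 3,
) -> PlaneTransform:
    """Iteratively fit affine corrections from patch-wise phase correlation.

    Overlapping patches fully inside the finite overlap contribute one
    (center, center + local shift) correspondence each; an affine transform
    fitted to the correspondences corrects the current estimate.
    """
    ny, nx = ref.shape
    py, px = max(int(ny * frac), 8), max(int(nx * frac), 8)
    cys = np.linspace(0, ny - py, ngrid).astype(int)
    cxs = np.linspace(0, nx - px, ngrid).astype(int)
    for _ in range(rounds):
        w = _warp_scalar(mov, cur, order=order, output_shape=ref.shape)
        src, dst = [], []
        for y0 in cys:
            for x0 in cxs:
                sl = (slice(y0, y0 + py), slice(x0, x0 + px))
                rp, wp = ref[sl], w[sl]
                if not (np.isfinite(rp).all() and np.isfinite(wp).all()):
                    continue
                if rp.std() < 1e-9 or wp.std() < 1e-9:
                    continue
                s = phase_cross_correlation(
                    rp - rp.mean(), wp - wp.mean(),
                    upsample_factor=100, normalization=None,
                )[0]
                if np.abs(s).max() > min(py, px) / 4:
                    continue  # implausible local shift: drop the patch
                cx0, cy0 = x0 + (px - 1) / 2, y0 + (py - 1) / 2
                src.append([cx0, cy0])
                dst.append([cx0 + s[1], cy0 + s[0]])
        if len(src) < 4:
            break
        D = estimate_transform("affine", np.asarray(src), np.asarray(dst))
        step = float(np.abs(D.params - np.eye(3)).max())
        cur = PlaneTransform(D.params @ cur.matrix)
        if step < 1e-4:
            break
    return cur


def _gauss_newton_polish(
    ref: np.ndarray,
    mov: np.ndarray,
    cur: PlaneTransform,
    iters: int = 30,
    order: int = 3,
) -> PlaneTransform:
    """Intensity-based (Lucas–Kanade style) affine polish of the transform."""
    ny, nx = ref.shape
    yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
    for _ in range(iters):
        w = _warp_scalar(mov, cur, order=order, output_shape=ref.shape)
        m = np.isfinite(w) & np.isfinite(ref)
        m = ndimage.binary_erosion(m, iterations=2)
        if m.sum() < 64:
            break
        gy, gx = np.gradient(np.nan_to_num(w))
        r = (np.nan_to_num(ref) - np.nan_to_num(w))[m]
        X, Y, GX, GY = xx[m], yy[m], gx[m], gy[m]
        J = np.stack([GX * X, GX * Y, GX, GY * X, GY * Y, GY], axis=1)
        try:
            dp = np.linalg.solve(J.T @ J, J.T @ r)
        except np.linalg.LinAlgError:
            break
        A = np.array(
            [[1 + dp[0], dp[1], dp[2]], [dp[3], 1 + dp[4], dp[5]], [0.0, 0.0, 1.0]]
        )
        try:
            cur = PlaneTransform(np.linalg.inv(A) @ cur.matrix)
        except ValueError:
            break
        if np.abs(dp).max() < 1e-9:
            break
    return cur


def refine_alignment(
    reference,
    moving,
    init: PlaneTransform | None = None,
    correlation_floor: float = DEFAULT_CORRELATION_FLOOR,
) -> PlaneTransform:
    """Refine a projective transform by maximizing normalized cross-correlation.

    Starting from ``init`` (identity if omitted): a global translation
    bootstrap by phase correlation, then iterative affine corrections fitted
    to patch-wise phase-correlation correspondences, then a Gauss–Newton
    intensity polish.  The transform class is projective (the init, e.g. the
    tilt foreshortening, may carry perspective terms; the data-driven
    corrections are affine).  Requires ≥ 50% field overlap after ``init``.
    Raises :class:`AlignmentError` (carrying the best transform found and its
    correlation) if the final NCC falls below ``correlation_floor`` — e.g.
    for structureless inputs.

    The returned transform has a ``correlation`` attribute with the final NCC.
    """
    ref = _as_array(reference)
    mov = _as_array(moving)
    if init is None:
        init = PlaneTransform.identity()

    mov0 = _warp_scalar(mov, init, order=1, output_shape=ref.shape)
    overlap = np.isfinite(mov0).mean()
    if overlap < 0.5:
        raise AlignmentError(
            f"only {overlap:.0%} of the field overlaps after initialization", init
        )

    current = init
    if np.nanstd(ref) > 1e-12 and np.nanstd(mov0) > 1e-12:
        filled_ref = np.nan_to_num(ref - np.nanmean(ref))
        filled_mov = np.nan_to_num(mov0 - np.nanmean(mov0))
        try:
            shift = phase_cross_correlation(
                filled_ref, filled_mov, upsample_factor=10, normalization=None
            )[0]
            dy, dx = (float(v) for v in shift)
            current = PlaneTransform.translation(dx, dy).compose(init)
        except Exception:  # pragma: no cover - degenerate inputs
            pass
        current = _patch_correspondence_stage(ref, mov, current)
        current = _gauss_newton_polish(ref, mov, current)

    corr = _ncc(ref, _warp_scalar(mov, current, order=1, output_shape=ref.shape))
    if corr < correlation_floor:
        raise AlignmentError(
            f"alignment correlation {corr:.3f} below floor {correlation_floor}",
            current,
            corr,
        )
    current.correlation = corr
    return current


# --------------------------------------------------------------------------
# Series alignment
# --------------------------------------------------------------------------


def _pad_to(shape: tuple[int, int], amap: AzimuthMap) -> AzimuthMap:
    ny, nx = amap.shape
    ty, tx = shape
    if (ny, nx) == (ty, tx):
        return amap
    py0 = (ty - ny) // 2
    px0 = (tx - nx) // 2

    def pad(arr, fill):
        out = np.full(shape, fill, dtype=arr.dtype if arr.dtype != bool else bool)
        out[py0 : py0 + ny, px0 : px0 + nx] = arr
        return out

    return AzimuthMap(
        phi_deg=pad(amap.phi_deg, np.nan),
        quality=pad(amap.quality, 0.0),
        valid=pad(amap.valid, False),
        tilt_deg=amap.tilt_deg,
    )


def warp_azimuth_map(amap: AzimuthMap, t: PlaneTransform,
                     output_shape: tuple[int, int], erode: bool = True) -> AzimuthMap:
    """Warp an azimuth map into the zero-tilt frame.

    Nearest-neighbour interpolation only (angles are never blended), so the
    multiset of azimuth values in the output is a subset of the input's.
    Out-of-field pixels are invalid; the mask is eroded by one pixel to drop
    resampling edge artifacts.  An exact identity transform passes the map
    through untouched.
    """
    if t.is_identity() and amap.shape == tuple(output_shape):
        return amap
    phi = _warp_scalar(amap.phi_deg, t, order=0, output_shape=output_shape, cval=np.nan)
    quality = _warp_scalar(amap.quality, t, order=0, output_shape=output_shape, cval=0.0)
    valid = _warp_scalar(
        amap.valid.astype(float), t, order=0, output_shape=output_shape, cval=0.0
    ) > 0.5
    valid &= np.isfinite(phi)
    if erode:
        valid = ndimage.binary_erosion(valid)
    return AzimuthMap(
        phi_deg=np.where(valid, phi, np.nan),
        quality=quality,
        valid=valid,
        tilt_deg=amap.tilt_deg,
    )


def align_series(
    maps: Sequence[AzimuthMap],
    tilts_deg: Sequence[float] | None = None,
    intensity_maps: Sequence[ScalarMap] | None = None,
    refine: bool = False,
    correlation_floor: float = DEFAULT_CORRELATION_FLOOR,
) -> TiltSeries:
    """Bring per-tilt azimuth maps into the zero-tilt pixel frame.

    The zero-tilt map is the reference (it must be present).  Each tilted map
    gets the geometric foreshortening transform; with ``refine`` and
    companion ``intensity_maps`` the transform is polished by correlation
    (azimuth maps themselves are unsuitable correlation channels).  Maps of
    unequal shape are padded (centered) to the common frame first.
    """
    maps = list(maps)
    if tilts_deg is None:
        tilts_deg = [m.tilt_deg for m in maps]
    tilts_deg = [float(t) for t in tilts_deg]
    if len(maps) < 2 and not (len(maps) == 1 and tilts_deg[0] == 0.0):
        raise ValueError("need maps from at least two tilts")
    if 0.0 not in tilts_deg:
        raise ValueError("a zero-tilt reference map is required")
    common = (
        max(m.shape[0] for m in maps),
        max(m.shape[1] for m in maps),
    )
    maps = [_pad_to(common, m) for m in maps]
    ref_idx = tilts_deg.index(0.0)

    ref_int = None
    if refine and intensity_maps is not None:
        ref_int = _as_array(intensity_maps[ref_idx])

    out_maps: list[AzimuthMap] = []
    transforms: list[PlaneTransform] = []
    for i, (amap, omega) in enumerate(zip(maps, tilts_deg)):
        t = foreshorten_transform(omega, common)
        if i == ref_idx:
            t = PlaneTransform.identity()
        elif ref_int is not None:
            try:
                t = refine_alignment(
                    ref_int,
                    _as_array(intensity_maps[i]),
                    init=t,
                    correlation_floor=correlation_floor,
                )
            except AlignmentError:
                logger.warning(
                    "correlation refinement failed at tilt %s; keeping the "
                    "geometric transform", omega,
                )
        out_maps.append(warp_azimuth_map(amap, t, common))
        transforms.append(t)
    return TiltSeries(maps=out_maps, transforms=transforms, tilts_deg=tilts_deg)


def save_transforms(path, transforms: Sequence[PlaneTransform], tilts_deg) -> None:
    import h5py

    with h5py.File(str(path), "a") as f:
        if "alignment" in f:
            del f["alignment"]
        g = f.create_group("alignment")
        g.create_dataset("matrices", data=np.stack([t.matrix for t in transforms]))
        g.create_dataset("tilts_deg", data=np.asarray(tilts_deg, dtype=float))
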