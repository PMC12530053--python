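"""Angle conventions, handedness, layer statistics and helix geometry.

A reconstructed fibril axis â (unit, a_z ≥ 0) is summarized by two angles:

* in-plane angle φ_ip ∈ [0°, 180°): azimuth of the axis projection in the
  scan plane, measured from +x (the horizontal scan axis);
* out-of-plane angle θ ∈ [−90°, 90°]: |θ| is measured from the +z (beam)
  axis — 0° means the fibril points along the beam, 90° in the scan plane —
  and the sign of θ carries the sign of the axis's y-component, which under
  transverse sectioning encodes the helical handedness of the layer.

In-plane angles are axial quantities with period 180° and are averaged with
circular statistics on the doubled angle; out-of-plane angles are averaged
arithmetically so that the handedness-carrying sign is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .datamodel import GeometryError
from .reconstruct import OrientationField


@dataclass
class OrientationAngles:
    """(in-plane, out-of-plane) angle pair; see module docstring."""

    in_plane_deg: float
    out_of_plane_deg: float
    zero_y: bool = False


@dataclass
class LayerStats:
    """Summary orientation statistics for one labeled region."""

    label: int
    n_pixels: int
    in_plane_mean_deg: float
    out_of_plane_mean_deg: float
    in_plane_std_deg: float
    out_of_plane_std_deg: float
    handedness: str


@dataclass
class HelixDescriptor:
    """Helical-path geometry of a cell-wall layer.

    ``helix_angle_deg`` is the angle between the helical fibril path and the
    cell's extended axis; ``pitch_um`` the axial distance per full turn,
    pitch = circumference / tan(helix angle).
    """

    helix_angle_deg: float
    circumference_um: float
    pitch_um: float


# --------------------------------------------------------------------------
# Circular statistics (axial, period 180°)
# --------------------------------------------------------------------------


def circular_mean_180(angles_deg: np.ndarray) -> float:
    """Mean of axial angles with period 180° (doubled-angle method)."""
    a = np.radians(np.asarray(angles_deg, dtype=float)) * 2.0
    mean = np.arctan2(np.sin(a).mean(), np.cos(a).mean()) / 2.0
    return float(np.degrees(mean) % 180.0)


def circular_std_180(angles_deg: np.ndarray) -> float:
    """Circular standard deviation of axial angles (period 180°), degrees."""
    a = np.radians(np.asarray(angles_deg, dtype=float)) * 2.0
    R = np.hypot(np.sin(a).mean(), np.cos(a).mean())
    R = min(R, 1.0)
    if R <= 0:
        return float("inf")
    return float(np.degrees(np.sqrt(-2.0 * np.log(R)) / 2.0))


# --------------------------------------------------------------------------
# Angle conventions
# --------------------------------------------------------------------------


def angles_from_axis(a_hat: np.ndarray) -> OrientationAngles:
    """Convert a unit axis (a_z ≥ 0) to (in-plane, out-of-plane) angles.

    φ_ip = atan2(a_y, a_x) mod 180°; θ = sign(a_y)·arccos(a_z).  For axes
    with a_y = 0 the sign is undefined; θ is reported non-negative and the
    ``zero_y`` flag is set.
    """
    a = np.asarray(a_hat, dtype=float)
    if a.shape != (3,) or not np.isclose(np.linalg.norm(a), 1.0, atol=1e-6):
        raise ValueError("a_hat must be a unit 3-vector")
    if a[2] < -1e-12:
        raise ValueError("a_hat must lie on the positive-z hemisphere")
    phi = np.degrees(np.arctan2(a[1], a[0])) % 180.0
    theta = np.degrees(np.arccos(np.clip(a[2], -1.0, 1.0)))
    zero_y = bool(np.isclose(a[1], 0.0, atol=1e-12))
    if not zero_y and a[1] < 0:
        theta = -theta
    return OrientationAngles(in_plane_deg=float(phi), out_of_plane_deg=float(theta), zero_y=zero_y)


def axis_from_angles(angles: OrientationAngles | tuple[float, float]) -> np.ndarray:
    """Unit axis (a_z ≥ 0) from an (in-plane, out-of-plane) angle pair.

    s = sign(θ); â = [s·sin|θ|·cos φ_ip, s·sin|θ|·sin φ_ip, cos|θ|].
    """
    if isinstance(angles, OrientationAngles):
        phi, theta = angles.in_plane_deg, angles.out_of_plane_deg
    else:
        phi, theta = angles
    s = 1.0 if theta >= 0 else -1.0
    t = np.radians(abs(theta))
    p = np.radians(phi)
    return np.array([s * np.sin(t) * np.cos(p), s * np.sin(t) * np.sin(p), np.cos(t)])


def angles_field(field: OrientationField) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized (φ_ip, θ) maps for a whole orientation field (NaN invalid)."""
    ax, ay, az = (field.axis[..., i] for i in range(3))
    phi = np.degrees(np.arctan2(ay, ax)) % 180.0
    theta = np.degrees(np.arccos(np.clip(az, -1.0, 1.0)))
    theta = np.where(ay < 0, -theta, theta)
    bad = ~field.well_determined
    phi = np.where(bad, np.nan, phi)
    theta = np.where(bad, np.nan, theta)
    return phi, theta


# --------------------------------------------------------------------------
# Orientation relationships
# --------------------------------------------------------------------------


def orientation_relationship(a1: np.ndarray, a2: np.ndarray) -> float:
    """Angle (degrees, in [0°, 90°]) between two fibril axes.

    Computed as arccos of the absolute dot product, so it is invariant to
    the arbitrary sign of either axis.
    """
    a1 = np.asarray(a1, dtype=float)
    a2 = np.asarray(a2, dtype=float)
    d = abs(float(a1 @ a2)) / (np.linalg.norm(a1) * np.linalg.norm(a2))
    return float(np.degrees(np.arccos(np.clip(d, 0.0, 1.0))))


def mean_consecutive_relationship(
    layer_angles: Sequence[tuple[float, float]],
    pairs: Sequence[tuple[int, int]] | None = None,
) -> float:
    """Mean inter-layer orientation relationship over consecutive layer pairs.

    ``layer_angles`` holds one (in-plane, out-of-plane) pair per layer;
    ``pairs`` gives 0-based layer index pairs (default: all consecutive).
    """
    axes = [axis_from_angles(a) for a in layer_angles]
    if pairs is None:
        pairs = [(i, i + 1) for i in range(len(axes) - 1)]
    return float(np.mean([orientation_relationship(axes[i], axes[j]) for i, j in pairs]))


# --------------------------------------------------------------------------
# Layer statistics
# --------------------------------------------------------------------------


def layer_stats(
    field: OrientationField,
    regions: np.ndarray,
    positive_theta_is: str = "left",
) -> list[LayerStats]:
    """Per-region orientation statistics over well-determined pixels.

    In-plane means/stds use circular statistics (period 180°); out-of-plane
    means/stds are arithmetic on the signed angle.  Empty regions yield an
    entry with ``n_pixels = 0`` and NaN means.  ``positive_theta_is`` names
    the handedness assigned to a positive mean out-of-plane angle — which
    physical handedness that is depends on where the lumen lies relative to
    the mapped wall (here defaulting to the transverse-section convention
    with the lumen toward the lower right).
    """
    regions = np.asarray(regions)
    if regions.shape != field.shape:
        raise ValueError("label map shape must match the field")
    other = "right" if positive_theta_is == "left" else "left"
    phi, theta = angles_field(field)
    usable = field.well_determined & np.isfinite(phi)
    out: list[LayerStats] = []
    for label in np.unique(regions):
        if label == 0:
            continue  # 0 = no-signal background by convention
        sel = (regions == label) & usable
        n = int(sel.sum())
        if n == 0:
            out.append(
                LayerStats(int(label), 0, float("nan"), float("nan"),
                           float("nan"), float("nan"), "indeterminate")
            )
            continue
        p = phi[sel]
        t = theta[sel]
        t_mean = float(np.mean(t))
        hand = positive_theta_is if t_mean > 0 else other if t_mean < 0 else "indeterminate"
        out.append(
            LayerStats(
                label=int(label),
                n_pixels=n,
                in_plane_mean_deg=circular_mean_180(p),
                out_of_plane_mean_deg=t_mean,
                in_plane_std_deg=circular_std_180(p),
                out_of_plane_std_deg=float(np.std(t)),
                handedness=hand,
            )
        )
    return out


def layer_stats_to_csv(stats: Sequence[LayerStats], path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "label": s.label,
                "n": s.n_pixels,
                "phi_mean": s.in_plane_mean_deg,
                "theta_mean": s.out_of_plane_mean_deg,
                "phi_std": s.in_plane_std_deg,
                "theta_std": s.out_of_plane_std_deg,
                "handedness": s.handedness,
            }
            for s in stats
        ]
    ).to_csv(path, index=False, float_format="%.6f")


# --------------------------------------------------------------------------
# Handedness and helix geometry
# --------------------------------------------------------------------------

#: Indeterminacy band for the handedness product, sin(2°).
HANDEDNESS_EPS = float(np.sin(np.radians(2.0)))


def classify_handedness(
    a_hat: np.ndarray,
    cell_axis: np.ndarray,
    radial_out: np.ndarray,
    eps: float = HANDEDNESS_EPS,
) -> str:
    """Classify the winding sense of a fibril axis around the cell.

    With tangent t = cell_axis × radial_out, the product
    s = (â·t)(â·cell_axis) is positive for a right-handed winding and
    negative for a left-handed one; |s| ≤ eps is indeterminate (pure hoop or
    pure axial fibrils).  Invariant under â → −â.
    """
    cell_axis = np.asarray(cell_axis, dtype=float)
    radial_out = np.asarray(radial_out, dtype=float)
    if abs(float(cell_axis @ radial_out)) > np.sin(np.radians(1.0)):
        raise GeometryError("cell_axis and radial_out must be orthogonal within 1°")
    t = np.cross(cell_axis, radial_out)
    a = np.asarray(a_hat, dtype=float)
    s = float((a @ t) * (a @ cell_axis))
    if s > eps:
        return "right"
    if s < -eps:
        return "left"
    return "indeterminate"


def helix_pitch(helix_angle_deg: float, circumference_um: float) -> float:
    """Pitch (axial distance per turn) from helix angle and circumference.

    pitch = circumference / tan(helix angle), helix angle strictly inside
    (0°, 90°): the angle is measured between the helical path and the cell's
    extended axis, so 90° is pure hoop winding (pitch → 0) and 0° degenerates
    (no winding, infinite pitch).
    """
    if not 0.0 < helix_angle_deg < 90.0:
        raise ValueError("helix angle must lie strictly between 0° and 90°")
    if not circumference_um > 0:
        raise ValueError("circumference must be positive")
    return float(circumference_um / np.tan(np.radians(helix_angle_deg)))


def helix_descriptor(helix_angle_deg: float, circumference_um: float) -> HelixDescriptor:
    return HelixDescriptor(
        helix_angle_deg=helix_angle_deg,
        circumference_um=circumference_um,
        pitch_um=helix_pitch(helix_angle_deg, circumference_um),
    )
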