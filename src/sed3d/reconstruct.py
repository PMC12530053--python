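"""Per-pixel 3D fibril-axis reconstruction from tilt-series Bragg azimuths.

Each Bragg azimuth φ measured at tilt ω constrains the fibril axis: the
in-detector diffraction vector q′ = [cos φ, sin φ, 0]ᵀ lies on the circle
orthogonal to the (tilted) fibril axis.  Back-rotating q′ about the vertical
tilt axis, q = R_y(−ω) q′, expresses the constraint in zero-tilt sample
coordinates; the fibril axis â is then the direction best-orthogonal to all
measured q_i.  Two measurements are solved exactly by the normalized cross
product; more are solved by the iterative averaged-projections scheme

    b̂_k = (1/N) Σ_i P_i(â_k),   P_i(â) = â − (â·q_i) q_i,
    â_{k+1} = b̂_k / |b̂_k|,

which is power iteration of I − S with S = (1/N) Σ q_i q_iᵀ, hence converges
to the eigenvector of the smallest eigenvalue of the measurement scatter
matrix S.  Note the projection uses the signed inner product: azimuths are
defined modulo 180°, so the sign of each q_i is arbitrary and the solution
must be (and is) invariant under q_i → −q_i.  A ``verbatim`` mode with
P_i(â) = â − |â·q_i| q_i is retained for comparison; it lacks that
invariance and is not the default.

Axes are sign-ambiguous; they are reported on the positive-z hemisphere.
Axes with zero y-component are degenerate under single-axis tilting (all
tilts measure the same q) and are flagged, not guessed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

#: Relative gap (the scatter matrix has unit trace) between its two smallest
#: eigenvalues below which the axis is considered under-determined.
EIGEN_GAP_TOL = 0.05

DEFAULT_TOL = 1e-10
DEFAULT_MAX_ITER = 1000


@dataclass
class QMeasurement:
    """A back-rotated diffraction direction in zero-tilt sample coordinates."""

    q: np.ndarray
    omega_deg: float
    phi_deg: float

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        if self.q.shape != (3,) or not np.isclose(np.linalg.norm(self.q), 1.0):
            raise ValueError("q must be a unit 3-vector")


@dataclass
class AxisEstimate:
    """A best-fit fibril axis with fit diagnostics.

    ``residual`` is the RMS of |â·q_i| over the measurements (0 for an exact
    solution); ``degenerate`` marks an under-determined axis.
    """

    a_hat: np.ndarray
    residual: float
    n_measurements: int
    degenerate: bool = False
    iterations: int = 0

    def __post_init__(self) -> None:
        self.a_hat = np.asarray(self.a_hat, dtype=float)


@dataclass
class OrientationField:
    """Per-pixel reconstructed fibril axes on the scan grid.

    ``axis`` is (ny, nx, 3) with NaN where invalid; ``valid`` marks pixels
    with signal at ≥ 2 tilts; ``degenerate`` marks under-determined axes
    (e.g. zero y-component under a single vertical tilt axis).
    """

    axis: np.ndarray
    residual: np.ndarray
    valid: np.ndarray
    degenerate: np.ndarray
    n_measurements: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        self.degenerate = np.asarray(self.degenerate, dtype=bool)
        if self.n_measurements is None:
            self.n_measurements = np.where(self.valid, 2, 0)

    @property
    def shape(self) -> tuple[int, int]:
        return self.valid.shape

    @property
    def well_determined(self) -> np.ndarray:
        return self.valid & ~self.degenerate

    def save(self, path: str | Path, group: str = "reconstruction") -> None:
        import h5py

        with h5py.File(str(path), "a") as f:
            if group in f:
                del f[group]
            g = f.create_group(group)
            g.create_dataset("axis", data=self.axis)
            g.create_dataset("residual", data=self.residual)
            g.create_dataset("valid", data=self.valid)
            g.create_dataset("degenerate", data=self.degenerate)
            g.create_dataset("n_measurements", data=self.n_measurements)

    @classmethod
    def load(cls, path: str | Path, group: str = "reconstruction") -> "OrientationField":
        import h5py

        with h5py.File(str(path), "r") as f:
            g = f[group]
            return cls(
                axis=g["axis"][...],
                residual=g["residual"][...],
                valid=g["valid"][...],
                degenerate=g["degenerate"][...],
                n_measurements=g["n_measurements"][...],
            )

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        ny, nx = self.shape
        rr, cc = np.mgrid[0:ny, 0:nx]
        pd.DataFrame(
            {
                "row": rr.ravel(),
                "col": cc.ravel(),
                "ax": self.axis[..., 0].ravel(),
                "ay": self.axis[..., 1].ravel(),
                "az": self.axis[..., 2].ravel(),
                "residual": np.asarray(self.residual).ravel(),
                "valid": self.valid.ravel().astype(int),
                "degenerate": self.degenerate.ravel().astype(int),
            }
        ).to_csv(path, index=False)


# --------------------------------------------------------------------------
# Geometry primitives
# --------------------------------------------------------------------------


def qvec_from_azimuth(phi_deg) -> np.ndarray:
    """Detector-plane diffraction direction q′ = [cos φ, sin φ, 0]ᵀ.

    Vectorized: scalar φ gives a (3,) vector, an array gives (..., 3).
    """
    phi = np.radians(np.asarray(phi_deg, dtype=float))
    out = np.stack([np.cos(phi), np.sin(phi), np.zeros_like(phi)], axis=-1)
    return out


def rotation_y(omega_deg: float) -> np.ndarray:
    """Rotation matrix about the y (tilt) axis by ``omega_deg`` degrees."""
    w = np.radians(omega_deg)
    c, s = np.cos(w), np.sin(w)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def back_rotate(q_prime: np.ndarray, omega_deg: float) -> np.ndarray:
    """Rotate a detector-frame q′ back to zero-tilt coordinates: R_y(−ω) q′."""
    q_prime = np.asarray(q_prime, dtype=float)
    return q_prime @ rotation_y(-omega_deg).T


def hemisphere(a: np.ndarray) -> np.ndarray:
    """Flip axes so a_z ≥ 0 (then a_y ≥ 0, then a_x ≥ 0 on ties)."""
    a = np.asarray(a, dtype=float)
    sign = np.sign(a[..., 2])
    tie_z = a[..., 2] == 0
    sign = np.where(tie_z, np.sign(a[..., 1]), sign)
    tie_zy = tie_z & (a[..., 1] == 0)
    sign = np.where(tie_zy, np.sign(a[..., 0]), sign)
    sign = np.where(sign == 0, 1.0, sign)
    return a * sign[..., None]


# --------------------------------------------------------------------------
# Axis solvers
# --------------------------------------------------------------------------


def axis_from_two(q1: np.ndarray, q2: np.ndarray) -> AxisEstimate:
    """Exact two-measurement solution: â ∝ q1 × q2, on the +z hemisphere."""
    q1 = np.asarray(q1, dtype=float)
    q2 = np.asarray(q2, dtype=float)
    cross = np.cross(q1, q2)
    norm = np.linalg.norm(cross)
    if norm < 1e-8:
        return AxisEstimate(
            a_hat=np.full(3, np.nan), residual=np.nan, n_measurements=2, degenerate=True
        )
    a = hemisphere(cross / norm)
    residual = float(np.sqrt(0.5 * ((a @ q1) ** 2 + (a @ q2) ** 2)))
    return AxisEstimate(a_hat=a, residual=residual, n_measurements=2)


def _scatter_eigen(qs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    S = qs.T @ qs / qs.shape[0]
    w, v = np.linalg.eigh(S)
    return w, v


def _default_init(qs: np.ndarray) -> np.ndarray:
    """Cross product of the two most mutually orthogonal measurements."""
    n = qs.shape[0]
    best, best_norm = None, -1.0
    for i in range(n):
        crosses = np.cross(qs[i], qs[i + 1 :])
        if crosses.size == 0:
            continue
        norms = np.linalg.norm(crosses, axis=1)
        j = int(np.argmax(norms))
        if norms[j] > best_norm:
            best_norm = float(norms[j])
            best = crosses[j]
    if best is None or best_norm < 1e-12:
        return np.array([0.0, 0.0, 1.0])
    return best / best_norm


def averaged_projections(
    qs,
    init: np.ndarray | None = None,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    verbatim: bool = False,
    eigen_gap_tol: float = EIGEN_GAP_TOL,
) -> AxisEstimate:
    """Best-fit axis orthogonal to a set of measurement directions.

    Parameters
    ----------
    qs
        Sequence of unit 3-vectors (or :class:`QMeasurement`); N ≥ 2.
    init
        Starting axis; defaults to the cross product of the two most
        orthogonal measurements (deterministic, no RNG).
    tol, max_iter
        Stop when the iteration step |â_{k+1} − â_k| < tol, or at max_iter.
    verbatim
        Use the absolute-value projection P_i(â) = â − |â·q_i| q_i instead of
        the sign-invariant default (see module docstring).

    Notes
    -----
    If the averaged projection vanishes the iteration restarts once from a
    deterministically perturbed init; a second collapse marks the estimate
    degenerate.  Degeneracy is otherwise decided by the eigen-gap of the
    scatter matrix, matching :func:`reconstruct_field`.
    """
    qlist = [m.q if isinstance(m, QMeasurement) else np.asarray(m, float) for m in qs]
    if len(qlist) < 2:
        raise ValueError("need at least two measurements")
    Q = np.stack(qlist)
    Q = Q / np.linalg.norm(Q, axis=1, keepdims=True)
    n = Q.shape[0]
    a = _default_init(Q) if init is None else np.asarray(init, float)
    a = a / np.linalg.norm(a)

    w, _ = _scatter_eigen(Q)
    degenerate = bool(w[1] - w[0] < eigen_gap_tol)

    restarted = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        dots = Q @ a
        if verbatim:
            dots = np.abs(dots)
        b = a - (dots[:, None] * Q).sum(axis=0) / n
        norm = np.linalg.norm(b)
        if norm < 1e-12:
            if restarted:
                return AxisEstimate(
                    a_hat=np.full(3, np.nan),
                    residual=np.nan,
                    n_measurements=n,
                    degenerate=True,
                    iterations=iterations,
                )
            restarted = True
            a = a + np.array([1e-3, 2e-3, 3e-3])
            a = a / np.linalg.norm(a)
            continue
        a_next = b / norm
        step = np.linalg.norm(a_next - a)
        a = a_next
        if step < tol:
            break
    a = hemisphere(a)
    residual = float(np.sqrt(np.mean((Q @ a) ** 2)))
    return AxisEstimate(
        a_hat=a,
        residual=residual,
        n_measurements=n,
        degenerate=degenerate,
        iterations=iterations,
    )


# --------------------------------------------------------------------------
# Field reconstruction
# --------------------------------------------------------------------------


def reconstruct_field(
    series,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    eigen_gap_tol: float = EIGEN_GAP_TOL,
) -> OrientationField:
    """Reconstruct the per-pixel 3D fibril axis from an aligned tilt series.

    For each scan pixel with valid azimuths at ≥ 2 tilts, the back-rotated
    measurement set {q_i} is solved by averaged projections (vectorized over
    all pixels; exactly the cross-product solution when N = 2).  Degeneracy is
    flagged where the two smallest eigenvalues of the per-pixel scatter matrix
    (unit trace) differ by less than ``eigen_gap_tol``, which captures the
    zero-y ambiguity of single-axis tilting.  Pixels with fewer than two
    valid measurements are invalid.  No failure aborts the map.

    Parameters
    ----------
    series
        A :class:`sed3d.tiltalign.TiltSeries` (or any object with ``maps``
        — aligned :class:`~sed3d.azimuthal.AzimuthMap`s — and ``tilts_deg``).
    """
    maps = series.maps
    tilts = list(series.tilts_deg)
    if len(maps) < 2:
        raise ValueError("need azimuth maps from at least two tilts")
    ny, nx = maps[0].shape
    npx = ny * nx
    T = len(maps)

    qs = np.zeros((T, npx, 3))
    ok = np.zeros((T, npx), dtype=bool)
    for t, (amap, omega) in enumerate(zip(maps, tilts)):
        valid = amap.valid.ravel()
        phi = np.where(valid, amap.phi_deg.ravel(), 0.0)
        qp = qvec_from_azimuth(phi)
        qs[t] = qp @ rotation_y(-omega).T
        ok[t] = valid

    n_meas = ok.sum(axis=0)
    valid_px = n_meas >= 2

    w = ok.astype(float)  # (T, npx)
    denom = np.maximum(n_meas, 1).astype(float)
    # scatter matrices S = (1/N) sum_i q q^T over valid measurements
    S = np.einsum("tp,tpi,tpj->pij", w, qs, qs) / denom[:, None, None]

    # deterministic init: cross product of the most orthogonal valid pair
    init = np.zeros((npx, 3))
    best = np.full(npx, -1.0)
    for i in range(T):
        for j in range(i + 1, T):
            cross = np.cross(qs[i], qs[j])
            norm = np.linalg.norm(cross, axis=1)
            usable = ok[i] & ok[j] & (norm > best)
            init[usable] = cross[usable] / np.maximum(norm[usable], 1e-300)[:, None]
            best = np.where(usable, norm, best)
    fallback = best < 1e-8
    init[fallback] = [0.0, 0.0, 1.0]

    a = init
    active = valid_px.copy()
    iterations = np.zeros(npx, dtype=int)
    for it in range(max_iter):
        if not active.any():
            break
        idx = np.flatnonzero(active)
        ai = a[idx]
        b = ai - np.einsum("pij,pj->pi", S[idx], ai)
        norm = np.linalg.norm(b, axis=1)
        collapsed = norm < 1e-12
        # perturb collapsed iterates once; they will be caught by the
        # eigen-gap degeneracy flag if genuinely under-determined
        if collapsed.any():
            b[collapsed] = ai[collapsed] + np.array([1e-3, 2e-3, 3e-3])
            norm[collapsed] = np.linalg.norm(b[collapsed], axis=1)
        a_next = b / norm[:, None]
        step = np.linalg.norm(a_next - ai, axis=1)
        a[idx] = a_next
        iterations[idx] = it + 1
        converged = step < tol
        active[idx[converged]] = False

    a = hemisphere(a)
    dots = np.einsum("tpi,pi->tp", qs, a) * w
    residual = np.sqrt((dots**2).sum(axis=0) / denom)

    eigvals = np.linalg.eigvalsh(S[valid_px])
    gap = np.zeros(npx)
    gap_valid = eigvals[:, 1] - eigvals[:, 0]
    gap[valid_px] = gap_valid
    degenerate = valid_px & (gap < eigen_gap_tol)

    axis = np.where(valid_px[:, None] & ~degenerate[:, None], a, np.nan)
    return OrientationField(
        axis=axis.reshape(ny, nx, 3),
        residual=residual.reshape(ny, nx),
        valid=valid_px.reshape(ny, nx),
        degenerate=degenerate.reshape(ny, nx),
        n_measurements=n_meas.reshape(ny, nx),
    )
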