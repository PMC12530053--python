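"""Color-wheel orientation maps, signed-component backgrounds and glyph export.

Because the fibril axis is sign-ambiguous, any RGB coding of 3D orientation
has either color collisions or discontinuities; the scheme here (matching the
package's angle conventions) uses

* hue: in-plane angle, period 180°;
* saturation: out-of-plane angle magnitude, 0 (beam-parallel) → 1 (in-plane);
* lightness: two classes distinguishing the sign of the axis y-component
  (the handedness-carrying sign), a mid gray when a_y = 0;
* black: invalid or degenerate pixels.

Its collisions are exactly the inherent ones: axes differing only in the
sign of a_y map to the same hue/saturation but different lightness.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .analysis import angles_field
from .reconstruct import OrientationField


@dataclass(frozen=True)
class ColorMapSpec:
    """Constants of the orientation color wheel (kept in config for
    bit-reproducible figures)."""

    hue_offset_deg: float = 0.0
    lightness_positive_y: float = 0.65
    lightness_negative_y: float = 0.35

    def __post_init__(self) -> None:
        if self.lightness_positive_y == self.lightness_negative_y:
            raise ValueError("the two lightness classes must be distinct")


def _hsl_to_rgb(h: np.ndarray, s: np.ndarray, l: np.ndarray) -> np.ndarray:
    """Vectorized HSL → RGB, all components in [0, 1]."""
    c = (1.0 - np.abs(2.0 * l - 1.0)) * s
    hp = (h % 1.0) * 6.0
    x = c * (1.0 - np.abs(hp % 2.0 - 1.0))
    z = np.zeros_like(c)
    conds = [hp < 1, hp < 2, hp < 3, hp < 4, hp < 5, hp >= 5]
    rgb_cases = [(c, x, z), (x, c, z), (z, c, x), (z, x, c), (x, z, c), (c, z, x)]
    r = np.select(conds, [case[0] for case in rgb_cases])
    g = np.select(conds, [case[1] for case in rgb_cases])
    b = np.select(conds, [case[2] for case in rgb_cases])
    m = l - c / 2.0
    return np.stack([r + m, g + m, b + m], axis=-1)


def colorize(field: OrientationField, spec: ColorMapSpec | None = None) -> np.ndarray:
    """RGB image (ny, nx, 3 floats in [0,1]) of an orientation field."""
    if spec is None:
        spec = ColorMapSpec()
    phi, theta = angles_field(field)
    ok = field.well_determined & np.isfinite(phi)
    h = ((np.where(ok, phi, 0.0) + spec.hue_offset_deg) % 180.0) / 180.0
    s = np.clip(np.abs(np.where(ok, theta, 0.0)) / 90.0, 0.0, 1.0)
    ay = field.axis[..., 1]
    l = np.where(
        np.nan_to_num(ay) > 0,
        spec.lightness_positive_y,
        np.where(
            np.nan_to_num(ay) < 0,
            spec.lightness_negative_y,
            0.5 * (spec.lightness_positive_y + spec.lightness_negative_y),
        ),
    )
    rgb = _hsl_to_rgb(h, s, l)
    rgb[~ok] = 0.0
    return rgb


def save_rgb(rgb: np.ndarray, path: str | Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plt.imsave(str(path), np.clip(rgb, 0, 1))


def component_background(field: OrientationField, component: str = "y") -> np.ndarray:
    """Signed axis-component map for diverging-colormap backgrounds.

    Positive/negative values distinguish the two winding senses; invalid or
    degenerate pixels are 0 (neutral).
    """
    if component not in ("y", "z"):
        raise ValueError("component must be 'y' or 'z'")
    idx = {"y": 1, "z": 2}[component]
    vals = np.nan_to_num(field.axis[..., idx])
    return np.where(field.well_determined, vals, 0.0)


def export_glyphs(
    field: OrientationField,
    stride: int = 1,
    step_nm: float = 100.0,
    preview_path: str | Path | None = None,
):
    """Table of per-pixel 3D orientation glyphs on a strided grid.

    Returns a DataFrame (x_um, y_um, ax, ay, az, residual) over valid,
    well-determined pixels, suitable for external 3D cylinder rendering.
    With ``preview_path`` a 2D quiver preview (in-plane projection, colored
    by out-of-plane angle) is saved as PNG.
    """
    import pandas as pd

    if stride < 1:
        raise ValueError("stride must be >= 1")
    ny, nx = field.shape
    rr, cc = np.mgrid[0:ny:stride, 0:nx:stride]
    sel = field.well_determined[rr, cc]
    rows = rr[sel]
    cols = cc[sel]
    ax = field.axis[rows, cols]
    res = np.asarray(field.residual)[rows, cols]
    df = pd.DataFrame(
        {
            "x_um": cols * step_nm / 1000.0,
            "y_um": rows * step_nm / 1000.0,
            "ax": ax[:, 0],
            "ay": ax[:, 1],
            "az": ax[:, 2],
            "residual": res,
        }
    )
    if preview_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axq = plt.subplots(figsize=(6, 6))
        theta = np.degrees(np.arccos(np.clip(ax[:, 2], -1, 1)))
        q = axq.quiver(
            df["x_um"], -df["y_um"], ax[:, 0], ax[:, 1],
            theta, cmap="viridis", pivot="mid",
            headwidth=1, headlength=0, headaxislength=0,
        )
        fig.colorbar(q, ax=axq, label="out-of-plane angle (deg)")
        axq.set_aspect("equal")
        axq.set_xlabel("x (um)")
        axq.set_ylabel("y (um)")
        fig.savefig(str(preview_path), dpi=120)
        plt.close(fig)
    return df
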