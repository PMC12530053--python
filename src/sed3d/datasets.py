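"""Reference layer-orientation tables for oat husk cell walls.

Measured layer-average fibril orientations (in-plane, out-of-plane; degrees,
under the conventions of :mod:`sed3d.analysis`) for the multilayered cell
wall of oat husk, in two sectioning geometries.  Positive out-of-plane angles
in the transverse table correspond to left-handed layers (lumen toward the
lower right of the mapped region); the alternating sign across layers
reflects the alternating helical handedness of consecutive wall layers.

These tables serve as worked-example inputs: phantom specifications for the
synthetic generator and reference values for the orientation-relationship
computations.
"""

from __future__ import annotations

#: Transversely sectioned oat husk: 7 wall layers, innermost first.
#: (in_plane_deg, out_of_plane_deg); sign of out-of-plane alternates with
#: helical handedness.  Layer 5 is very thin and its values are the least
#: certain.
OAT_TRANSVERSE_LAYERS: list[tuple[float, float]] = [
    (33.0, 56.0),   # layer 1 (left-handed)
    (47.0, -61.0),  # layer 2 (right-handed)
    (27.0, 60.0),   # layer 3 (left-handed)
    (43.0, -62.0),  # layer 4 (right-handed)
    (36.0, 78.0),   # layer 5 (thin; least certain)
    (45.0, -65.0),  # layer 6 (right-handed)
    (27.0, 63.0),   # layer 7 (left-handed)
]

#: Longitudinally sectioned oat husk: 4 wall layers, innermost first.
OAT_LONGITUDINAL_LAYERS: list[tuple[float, float]] = [
    (155.0, -67.0),
    (54.0, -51.0),
    (147.0, -61.0),
    (58.0, -54.0),
]

#: Consecutive opposite-handed layer pairs of the transverse table that do
#: not involve the thin layer 5 (0-based indices).
OAT_TRANSVERSE_PAIRS: list[tuple[int, int]] = [(0, 1), (1, 2), (2, 3), (5, 6)]

#: Consecutive layer pairs of the longitudinal table (0-based indices).
OAT_LONGITUDINAL_PAIRS: list[tuple[int, int]] = [(0, 1), (1, 2), (2, 3)]

#: Indices (0-based) of left-handed / right-handed layers in the transverse
#: table, excluding the thin layer 5.
OAT_TRANSVERSE_LEFT = (0, 2, 6)
OAT_TRANSVERSE_RIGHT = (1, 3, 5)
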