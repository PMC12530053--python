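# sed3d

**3D fibril-orientation reconstruction from tilt-series scanning electron
diffraction (SED / 4D-STEM).**

Plant cell walls, wood and similar biocomposites are built from crystalline
cellulose fibrils wound helically around each cell, often with the winding
sense (handedness) alternating between wall layers. `sed3d` reconstructs the
per-pixel three-dimensional fibril axis of such fiber-textured materials from
low-dose SED data acquired at a few tilt angles, and turns the result into
chirality (handedness) maps and per-layer orientation statistics — at the
sub-100 nm spatial resolution of a scanning nanobeam. It is aimed at electron
microscopists and cell-wall/biomaterials researchers who have 4D-STEM
diffraction stacks and want quantitative 3D texture maps without full
tomography.

## Method

At each beam position the cellulose (200) reflection produces a Bragg spot
pair on a ring at |g₂₀₀|; because the (200) diffraction vector is normal to
the fibril's long axis, the spot azimuth φ (mod 180°) constrains the axis.
For a measurement at tilt ω about the vertical axis,

- q′ = [cos φ, sin φ, 0]ᵀ lies on the circle orthogonal to the tilted axis,
- q = R_y(−ω) q′ expresses that constraint in zero-tilt sample coordinates,

so the fibril axis â is the direction best-orthogonal to all measured qᵢ.
Two tilts are solved exactly by â ∝ q₁ × q₂; more tilts by **averaged
projections**,

    b̂ₖ = (1/N) Σᵢ Pᵢ(âₖ),   Pᵢ(â) = â − (â·qᵢ) qᵢ,   âₖ₊₁ = b̂ₖ/|b̂ₖ|,

which converges to the eigenvector of the smallest eigenvalue of the
measurement scatter matrix (1/N) Σ qᵢqᵢᵀ. Axes are reported on the positive-z
hemisphere as (in-plane angle φ_ip, signed out-of-plane angle θ); the sign of
θ encodes the helical handedness in transverse sections. Axes with zero
y-component are degenerate under a single tilt axis (every tilt measures the
same q) and are flagged rather than guessed.

The pipeline stages, each usable as a library function or CLI subcommand:

| stage | module | what it does |
|---|---|---|
| ingest | `sed3d.datamodel` | HDF5 tilt-series I/O, stream reassembly, COM beam centering, virtual imaging, dose bookkeeping |
| azimuth | `sed3d.azimuthal` | 360 virtual detectors on the (200) ring → folded 180° profile, Fourier quality ratio, peak azimuth |
| align | `sed3d.tiltalign` | foreshortening-initialized projective registration of the per-tilt maps into the zero-tilt frame |
| reconstruct | `sed3d.reconstruct` | per-pixel axis solve with degeneracy masks |
| analyze | `sed3d.analysis` | angle conventions, handedness, layer statistics, helix pitch |
| simulate | `sed3d.synth` | multilayer helical phantoms + diffraction forward model / frame renderer |
| render | `sed3d.viz` | color-wheel maps, signed-component backgrounds, cylinder-glyph export |

## Worked example

Render synthetic diffraction frames for a three-layer transverse cell-wall
phantom with alternating handedness, run the full pipeline, and summarize each
layer (wrapped-Gaussian azimuth noise of 3°, the package default, is applied):

```python
import numpy as np
from scipy import ndimage
from sed3d import (
    NoiseSpec, RingConfig, align_series, azimuth_map, layer_stats,
    oat_transverse_phantom, reconstruct_field, render_patterns,
)

tilts = [0.0, 45.0, -45.0]
ring = RingConfig()
phantom = oat_transverse_phantom(
    (64, 64),
    layer_angles=[(33.0, 56.0), (47.0, -61.0), (27.0, 60.0)],
    lumen_radius_px=10.0, layer_thickness_px=6.0,
)
maps = [
    azimuth_map(render_patterns(phantom, omega, ring, noise=NoiseSpec(seed=1)), ring)
    for omega in tilts
]
field = reconstruct_field(align_series(maps, tilts))

# drop pixels on layer interfaces (the probe there straddles two layers)
interior = np.zeros_like(phantom.labels)
for lab in (1, 2, 3):
    interior[ndimage.binary_erosion(phantom.labels == lab, iterations=2)] = lab

for s in layer_stats(field, interior):
    print(f"layer {s.label}: in-plane {s.in_plane_mean_deg:5.1f} deg, "
          f"out-of-plane {s.out_of_plane_mean_deg:6.1f} deg, "
          f"{s.handedness}-handed (n={s.n_pixels})")
```

Output:

```
layer 1: in-plane  33.0 deg, out-of-plane   55.9 deg, left-handed (n=200)
layer 2: in-plane  46.9 deg, out-of-plane  -61.0 deg, right-handed (n=284)
layer 3: in-plane  27.1 deg, out-of-plane   59.9 deg, left-handed (n=376)
```

The ground-truth layers were (33°, 56°), (47°, −61°) and (27°, 60°): each
mean is recovered to a fraction of a degree, and the alternating sign of the
out-of-plane angle reads out the layer-by-layer reversal of helical
handedness.

The same chain runs from the shell:

```bash
sed3d --output-dir out --seed 1 run        # simulate → … → analyze → render
cat out/layers.csv
```

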