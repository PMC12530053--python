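# Methods

This note documents the model, the numerical choices and the limits of the
synthetic validation in `sed3d`.

## Physical model and assumptions

The material is assumed to be a **fiber texture**: within each probed volume
the crystalline fibrils share one symmetry axis â (the cellulose chain
direction), with rotational symmetry about it. Under this assumption the
azimuth of the (200) Bragg pair on the diffraction ring constrains â to the
plane orthogonal to the measured diffraction direction, and a handful of tilt
angles (three by default: 0°, ±45° about the vertical axis) suffices to fix
the axis in 3D — far less dose than a tomographic tilt series, which is what
makes the method usable on beam-sensitive organic crystals.

Consequences of the single-tilt-axis geometry:

* **Sign ambiguity.** â and −â are indistinguishable; axes are reported on
  the positive-z hemisphere.
* **Degenerate directions.** An axis with zero component along the tilt axis
  (a_y = 0) produces the same measurement (φ = 90°) at every tilt; such
  pixels are flagged `degenerate`, never interpolated. Numerically,
  degeneracy is declared when the two smallest eigenvalues of the per-pixel
  scatter matrix (unit trace) differ by less than `eigen_gap_tol = 0.05`.
* **Projection through thickness.** One axis is reported per scan pixel; the
  method does not resolve depth. Pixels whose probed column contains two
  differently oriented populations (layer interfaces, crossing walls)
  yield an averaged-projection compromise with a large residual.

## Azimuth extraction

Each centered pattern is integrated in 360 square virtual detectors
(0.04 × 0.04 Å⁻¹) on a ring at the (200) radius. The ring radius defaults to
**0.258 Å⁻¹** (d₂₀₀ ≈ 3.88 Å of cellulose Iβ) and is a configuration value —
other semicrystalline polymers need their own ring. Pixels count toward a
detector when their center falls inside its box; at the default geometry the
boxes overlap, which low-pass filters the profile slightly and costs nothing
in peak position. Friedel symmetry lets the two half-circles be folded
(averaged, preserving per-detector intensity units) into a 180-bin curve.

Peak quality is the Fourier ratio |F₁|/|F₀| of the folded curve: 0 for a flat
curve, 0.5 for a pure single-period cosine on a matching baseline. The
default validity threshold is **0.05**, calibrated on the synthetic renderer
so that pure Poisson-background frames at the default background level pass
at far below the 5 % false-valid budget (measured ≈ 0 %, with the noise-only
quality distribution topping out near 0.03) while genuine Bragg-pair frames
score ≳ 0.2. The threshold is configuration, not a constant of nature: real
backgrounds (carbon films, camera artifacts) will shift the null
distribution, and the threshold should be re-examined per instrument.

The peak azimuth is the argmax of the folded curve refined by circular
three-point parabolic interpolation (sub-bin, i.e. sub-degree, precision);
refinement can be disabled. Azimuth zero lies along +x (detector columns),
counter-clockwise positive — one convention fixed globally and shared by the
forward model, so only internal consistency matters.

## Tilt alignment

Tilting a flat section about the vertical axis foreshortens its image by
cos ω along x. Alignment initializes each tilted map with the exact
geometric stretch (1/cos ω about the map center) and, when companion
intensity maps are supplied, refines a projective transform by normalized
cross-correlation: a global phase-correlation translation bootstrap, then
iterated affine corrections fitted to patch-wise phase-correlation
correspondences, then a Gauss–Newton intensity polish. Registration failures
(final NCC below `align.correlation_floor = 0.2`) fall back to the geometric
transform with a logged warning.

Azimuth maps are warped with **nearest-neighbour** interpolation only:
azimuths are angular labels and must never be blended between pixels.
Validity masks are AND-propagated and eroded by one pixel after warping to
suppress resampling edge artifacts.

## Axis solver

`averaged_projections` iterates â ← normalize(â − S â) with
S = (1/N) Σ qᵢqᵢᵀ, which is power iteration of I − S and therefore converges
to the minimum-eigenvector of S; the test suite asserts agreement with a
direct eigendecomposition to 1e-6 rad on random instances, and with the
cross-product closed form for N = 2. Defaults: step-norm tolerance 1e-10,
max 1000 iterations, deterministic initialization from the cross product of
the two most mutually orthogonal measurements (no RNG). A vanishing average
projection triggers one deterministic restart before the pixel is declared
degenerate.

One deliberate deviation from the literal projection formula: the projection
onto the plane orthogonal to qᵢ is Pᵢ(â) = â − (â·qᵢ)qᵢ with the **signed**
inner product. A variant with |â·qᵢ| appears in print, but it is not
invariant to the sign of qᵢ — and that sign is arbitrary, since azimuths are
defined modulo 180°. The signed form is the default; `verbatim=True`
reproduces the absolute-value variant for comparison (a test demonstrates
its sign-dependence).

## Angle conventions and layer statistics

* In-plane angle φ_ip = atan2(a_y, a_x) mod 180°, measured from +x.
* Out-of-plane angle θ: |θ| = arccos(a_z) (0° = fibril along the beam,
  90° = in the section plane), sign = sign(a_y). In transverse sections the
  sign of θ encodes helical handedness; which sign means left-handed depends
  on where the lumen lies, so `layer_stats` exposes `positive_theta_is`
  (default `"left"`, the convention for a lumen toward the lower right).
* In-plane statistics are circular with period 180° (doubled-angle method);
  out-of-plane statistics are arithmetic on the signed angle, so the
  handedness-carrying sign is never wrapped away. At the dispersions seen in
  practice (a few degrees) circular and arithmetic in-plane means agree to
  well under the reporting precision.
* Helix pitch = circumference / tan(helix angle), helix angle strictly
  between 0° and 90°. Note that published per-layer pitch values for oat
  husk are not reproducible from this formula with the layer-average helix
  angle and circumference alone (the worked example 33°, 31 μm gives
  47.7 μm, not the reported 25 μm); the per-layer angles underlying those
  values use a parametrization not fully specified in print. The operation
  implements the stated definition and the discrepancy is left visible in a
  test.

## Synthetic data: what it emulates and what it does not

`sed3d.synth` generates ground-truth phantoms (concentric annular layers for
transverse sections, stacked bands for longitudinal ones; constant per-layer
angles or helical tangent fields; lumen/resin no-signal regions) and two
levels of forward model:

1. **Azimuth-level** (`simulate_azimuth_maps`): exact forward azimuths with
   wrapped-Gaussian noise (period 180°), sampled on the foreshortened tilted
   grids. Default σ = 3°, the scale consistent with the orientation
   dispersion of real cell-wall reconstructions.
2. **Frame-level** (`render_patterns`): full 4D stacks with Poisson
   background (mean 2 counts/pixel), a central direct beam, and the
   antipodal (200) Gaussian spot pair (peak-to-background 20 by default), or
   a uniform ring for beam-parallel fibrils.

Not emulated: multiple diffraction rings (only the (200) pair is rendered,
since only it is analyzed), dynamical scattering, dose-dependent
crystallinity fading, detector point spread, within-pixel fibril
distributions, and registration error sources beyond geometric
foreshortening. Passing the synthetic suite therefore validates the
geometry, the solver and the pipeline plumbing — it does not certify
performance against real backgrounds, beam damage or imperfect alignment.

**Interface pixels.** Nearest-neighbour warping of the tilted maps assigns
each zero-tilt pixel the azimuth of a tilted pixel up to ~0.7 px away, so
pixels within about one scan step of a layer interface can mix measurements
from adjacent layers — exactly as a real probe straddling an interface
would. Per-pixel accuracy statistics and per-layer means are therefore
evaluated on region interiors (labels eroded by 1–2 px, `analysis.label_erosion_px`);
interior recovery of a noiseless phantom is exact to numerical precision.

## Validation summary (computed by the test suite)

* Solver ≡ minimum-eigenvector oracle to 1e-6 rad, 100/100 random instances.
* Noiseless 7-layer 256² phantom at 0°/±45°: ≥ 99 % of interior,
  well-determined pixels recovered within 0.5° (measured: all of them);
  a_y = 0 axes produce φ = 90° at every tilt, exactly, and are flagged.
* σ = 3° azimuth noise over 10⁴ axes with |a_y| > 0.2: RMS axis error
  ≈ 3.2°, i.e. at the noise level.
* Rendered-frame pipeline (128×128 scan, 3 tilts, 128² detector): per-layer
  means within 1° of the phantom; pure-noise frames pass the quality
  threshold ≲ 0 % of the time (budget 5 %).

Problem sizes in the suite (chosen to keep the full run around a minute):
256² grids for azimuth-level round trips, 128² scan × 128² detector for the
rendered-frame chain, 36² for the CLI chain.

## Known limitations

* Real tilt series need reliable intensity contrast for registration; the
  refinement assumes a mostly rigid, flat section (projective model, no
  elastic distortion, no per-row drift correction).
* Electron-dose estimation uses a full-diameter disk beam area; a FWHM-based
  area would report a proportionally higher dose (the 2 pA / 5 ms / 8 nm
  reference condition evaluates to 12.4 e⁻/Å² under the disk definition).
* The quality threshold and ring radius must be revisited per material and
  instrument.
* Degenerate (zero-a_y) directions are inherent to single-axis tilting; a
  second tilt axis, not supported here, would remove them.
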