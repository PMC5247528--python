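# Methods

This note records the model, the numerical choices and their rationale,
what the synthetic-data generator does and does not emulate, and the
known limitations.  It states no empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Forward model

A scan is described declaratively (`ScanSpec`): probe positions `y_j`
in metres, sharing maps `c(j)` and `d(j)` assigning each scan point a
probe and an object entity, a discrete wavelength list with positive
weights normalized to 1, and mode counts `M` (probe) and `N` (object).
`build_pods` realizes it as one *pod* per combination
`(j, λ, m, n)` — the elementary coherent propagation channel — over
five entity containers (probe, object, exit, diffraction, mask).  The
measured intensity is modelled as the incoherent sum over the pods of a
scan point:

    I_j(s) = Σ_{λ,m,n} w(λ) |D_{λ,z}{ p_{c(j),m,λ}(x) o_{d(j),n,λ}(x − y_j) }|²

with a validity mask `M_j(s)` (1 = valid).  Wavelength weights enter
the intensity sum explicitly; the source spectrum can equivalently be
folded into per-λ probe powers.  By default the object's spectral
response is tied to a single layer shared by all wavelengths (adequate
for moderate bandwidth); untied per-λ object layers are available via
`ScanSpec(tie_object_spectrum=False)`.

### Coordinates and the view/storage abstraction

Physical coordinates (metres) refer to pixel centres; a storage's
`origin` is the coordinate of pixel (0, 0); arrays are row-major with
axis 0 vertical, and pixel ranges are half-open.  A view is placed by

    start = round((center − origin)/psize) − shape//2

per axis (round-to-nearest-even via `np.rint`).  Sub-pixel position
remainders are discarded: the model shifts the object by whole-pixel
view placements and defines no sub-pixel interpolation.  Since the
simulator places views with the same rule, simulated data are exactly
consistent with the pixelated model.  Storages grow on demand
(`reformat`) to cover the union of their active views, preserving
existing content at unchanged physical coordinates; newly allocated
object area is filled with 1 (empty space transmits), all other
entities with 0.  Object views are centred at `−y_j`, so the object
shifts under a fixed probe.

### Propagators

Both propagators use orthonormal (unitary) centred FFTs — zero
frequency at index `N//2`, implemented by index shifts, never phase
ramps — so photon counts are directly comparable between planes and
Parseval/energy checks are exact.  Far field: a pure Fourier transform;
quadratic phase prefactors are omitted because only intensities are
measured and they cancel in `|·|²`.  The sampling relation
`v = s/(λz)` gives a real-space pixel of `λz/(N·dpsize)`.  Near field:
the angular-spectrum transfer function
`H(v) = exp(2πiz√(λ⁻² − v²))` on the same grid in both planes;
evanescent components (`|v| > 1/λ`) are hard-zeroed rather than
exponentially attenuated — deterministic, overflow-free for negative
`z`, and documented as a contract.  Per-scan geometry is supported
(each wavelength gets its own propagator); per-scan-point distances
`z(j)` are not.

## Difference-map engine

β = 1, fixed.  One iteration applies the Fourier update to every scan
point in ascending `j`, then `overlap_inner` (default 1) alternations
of object update and probe update.  The probe is frozen for the first
iteration (`probe_update_start = 2`) to keep it from collapsing against
the flat object start; all randomness in initialization flows from one
integer seed.  Starting exit waves are `ψ = p·o`.

Fourier update (per scan point, all coherent channels simultaneously):

    φ = 2 p o − ψ;  Ψ = D{φ};  total = Σ w|Ψ|²
    Υ = 1 − M + M √(I / max(total, ε_floor))
    ψ ← ψ + D̂{Ψ·Υ} − p o

Invalid pixels (M = 0) have Υ = 1 exactly, so masked data can never
influence the reconstruction — perturbing them yields bitwise-identical
runs.  Overlap updates accumulate numerator and denominator through
views into cloned containers and divide elementwise; the restriction of
the sums to the scan points sharing an entity is implicit in which
storage each pod's view targets.

**Regularization.**  Denominators are clamped from below at
`eps` × their mean (default `eps = 1e-10`) instead of adding a constant.
An additive term biases *every* pixel by `eps·mean/denominator`, which
is large exactly at dark pixels and measurably perturbs a consistent
reconstruction (the ground-truth fixed point drifted at the 1e-9
level); the floor is exactly neutral wherever the denominator exceeds
it while giving the same protection against division by zero.  Object
and probe pixels with zero coverage keep their previous values.

**Error metric.**  The per-iteration `fourier_error` is the masked,
normalized mismatch of the *model* intensity:
`Σ M (Σw|D{p·o}|² − I)² / Σ M I²`, averaged over scan points.  The
intensity of the feedback field `φ` is deliberately not used: at
difference-map fixed points `φ` retains a structural residual (the DM
iterate `ψ` converges to the solution plus a component that the two
projections cancel between them), so a `φ`-based mismatch saturates at
a finite value even when the reconstruction is exact; the model-based
mismatch vanishes precisely when the reconstruction explains the data.
`exit_change` is the relative squared change of the exit-wave buffer
per iteration.  Note the difference map is not a descent method: the
error trace oscillates at the few-tens-of-percent scale per iteration
around a strongly decreasing trend, which is expected behaviour, not a
convergence failure.

**Mode orthogonalization.**  Mixed-state probes are defined only up to
a unitary mixing of their layers, so recovered modes are rotated into
the eigenbasis of the Hermitian Gram matrix `G_ab = Σ conj(p_a) p_b`;
eigenvalues over the trace give power fractions, sorted descending.
This is a standard choice (the mixing within the recovered span is not
observable); total power is conserved by unitarity.

**Gauge fixing.**  The model is invariant under `p → a·p, o → o/a`,
under a global phase, and under a linear phase ramp
`p → p·e^{2πiv·x}, o → o·e^{−2πiv·x}` (each frame only gains a constant
phase `e^{−2πiv·y_j}`).  `fix_ambiguities` removes all three: the probe
power is set to the largest valid-pixel frame total (so probe and data
share one photon scale), the probe's mean transverse frequency is set
to zero, and the mean object phase over the well-covered region
(coverage ≥ 50% of maximum) is set to zero.  The ramp is estimated by
the power-weighted circular mean of the probe's phase gradient
(`angle Σ p(x+e)conj(p(x))`), which is exact for a pure ramp and, unlike
a windowed far-field centroid, is not biased by truncating the
slowly decaying tails of the probe spectrum.  The operation is
idempotent and leaves all model intensities unchanged.

## Synthetic data

The simulator runs the identical forward model the engine inverts, so
simulate → reconstruct → compare-to-truth is a closed loop.

- **Probe**: mode 0 is a flat circular aperture of the configured
  diameter (optionally near-field propagated to the sample plane, or
  given a converging quadratic phase for the "focused" kind); higher
  modes are smoothed random-phase perturbations Gram-Schmidt
  orthogonalized against earlier modes.  Modes are scaled to the
  configured power fractions; total power is 1 before photon scaling.
- **Object**: "bars" (binary resolution-target stripes of decreasing
  pitch), "random_phase" (unit modulus, smooth random phase — the
  default test object, chosen because it has no amplitude contrast to
  help the algorithm), or "lens_like" (circular zone structure).
  `|o| ≤ 1` always.
- **Positions**: raster grid with uniform per-point jitter (default
  0.1 of the step), emulating acquisition on a non-periodic grid, which
  also breaks the raster-grid pathology.  A warning is raised if the
  step reaches the probe diameter (no overlap).
- **Photon budget**: defined as total counts per frame for a
  transparent object; with unit transforms each unit-modulus-object
  frame integrates exactly to `photons`.  Default 1e6 per frame.
- **Noise and masks**: optional per-pixel Poisson sampling; dead pixels
  drawn i.i.d. once per dataset (the file format also accepts per-frame
  masks); optional central beamstop disc.  Frames carry 0 at masked
  pixels.
- **Seeding**: one dataset seed fans out to named sub-seeds (probe,
  object, jitter, noise, mask) via a SHA-256 derivation, so toggling
  one stochastic element does not shift the others' streams.

What the generator does *not* emulate: detector point-spread, readout
noise, position errors unknown to the reconstruction, continuous source
spectra, sample vibration.  Passing recovery tests therefore
demonstrate correctness of the algebra and the solver on data that
exactly follow the pixelated model — not robustness to the systematic
errors of real instruments.

## Default study conditions and problem sizes

Unit and acceptance tests run on a visible-light far-field geometry
(λ = 650 nm, z = 145 mm, 72 µm detector pixels).  The standard recovery
problem is a 7×7 jittered raster of 64×64 frames; the probe disc spans
a quarter of the frame and the step is 0.4 of the probe diameter (60%
linear overlap), 1e6 photons per frame, no noise, 300 DM iterations —
sizes at which the full stack (simulation + reconstruction) completes
in seconds while leaving the recovery far from trivially
overdetermined.  Fixed-point and neutrality checks use 5×5 and 3×3
scans.  The Fraunhofer-consistency check compares the two regimes on
matched grids at `z = N·dpsize²/λ` with a small Gaussian source
(N = 128), where the residual quadratic-phase error is below 1% RMS.

## Known limitations

- Single process only; `reduce_sum` is a defined extension point, not a
  parallelization.
- Difference map only — no maximum-likelihood refinement, ePIE or RAAR;
  no position refinement; no Fourier relaxation thresholds.
- No sub-pixel scan positions; no per-scan-point geometry; no Fresnel
  scaled propagator with unequal input/output pixel sizes; no
  tilted-plane or Bragg geometries.
- The HDF5 scan tree is this package's own minimal layout (documented
  in the README), not byte-compatible with any other tool's format.
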