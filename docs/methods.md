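# Methods

This note documents the models implemented in `emgsim`, the defaults and
their provenance, the synthetic phantom's scope, and the numerical choices
that a user extending or auditing the package needs to know.

## Action-potential source model

The intracellular action potential is the Rosenfalck cubic-exponential
`v_m(l) = 96 (alpha l)^3 e^{-alpha l} - 90` (mV), with `l` the distance in
mm behind the depolarization front and `alpha` (1/mm) a spatial scaling
factor.  The production default `alpha = 0.5` gives a waveform peaking
6 mm behind the front.  The transmembrane current per unit length is
`i_m = sigma_ic pi r^2 v_m''`, with intracellular conductivity
`sigma_ic = 1 S/m` and fiber radii of 12.4–20.3 um (half the 24.8–40.6 um
diameter population).  `v_m` is stated in mV over mm; the single unit
conversion (1 mV/mm^2 = 1e3 V/m^2) happens in
`transmembrane_current_per_length`, which returns SI A/m.  Derivatives are
analytic closed forms; finite differences appear only in tests.

**Charge balance.**  Two action potentials emerge at the innervation point
at t = 0 and travel toward the fiber ends at constant conduction velocity
(3.2–5.0 m/s across the pool).  The travelling profile is sharply windowed
to the traversed fiber region (the excitation wave grows out of the
innervation zone and collapses at the tendon), and stationary compensatory
point sources at the innervation point (generation) and the terminating
fiber end (extinction) carry the missing charge.  Rather than sampling
`i_m` pointwise, each 0.1 mm cell of the discretized fiber carries the
exact integral of `i_m` over the cell, obtained from the analytic first
derivative `v_m'`.  The per-instant sum of all currents then telescopes to
zero at machine precision instead of to quadrature error, and the
compensatory amplitudes are exactly the emerged/absorbed charge deficits.
The window is a sharp spatial truncation; a smooth window would be a
straightforward extension but nothing in the implemented checks requires
one.

## Volume conductor and lead fields

The static conduction problem `div(sigma grad phi) = 0` is solved with a
uniform current density on the active electrode contact (Neumann), a
ground `phi = 0` on the domain-truncation face — the analogue of currents
leaving toward the body — and insulated skin–air surfaces.  Tissue
conductivities are the 150 Hz values: skin 4.88e-4, fat 4.07e-2,
cancellous bone 7.56e-2, cortical bone 2.00e-2, muscle 0.28 (isotropic) or
0.40/0.09 S/m longitudinal/transverse along the local fiber direction.

The finite-element solver is implemented in-package on scipy sparse:
Lagrange P1 or P2 tetrahedra (P2 is the production default, P1 the fast
test option), a 4-point degree-2 quadrature rule, Jacobi-preconditioned
conjugate gradients at 1e-9 relative residual (deterministic for a fixed
mesh).  Electrode contacts are represented as boundary patches carrying a
uniform current density; on meshes coarser than the 0.5 mm physical
contact the patch degenerates to the nearest boundary triangle, which is
adequate for the desk-scale meshes used here (the recorded potential is
the area-weighted patch mean).  Interior point sources enter through
shape-function weights; queries outside the mesh raise instead of
extrapolating.

**Reciprocity.**  One solve with unit current at an electrode yields the
weighting function h everywhere, so lead fields for any number of fibers
cost exactly one solve per electrode.  Because the discrete stiffness
matrix is symmetric, reciprocal and forward formulations agree to solver
tolerance, which the tests verify against per-source forward solves.

**Verification against closed forms.**  The solver is validated on a bar
resistor (exact for affine potentials), against the infinite-medium
anisotropic point-source potential `I / (4 pi sqrt(det Sigma d'Sigma^-1 d))`,
and against the half-space solution `I/(2 pi sigma r)` with the analytic
values imposed on the truncation boundary so the comparison isolates
discretization error (within 5% for r in 3–10 mm at the reference
refinement).

## Tractography

Deterministic streamline tracking seeds at every ROI voxel center and
integrates the principal diffusion eigenvector with fixed 0.4 mm Euler
steps and nearest-neighbor tensor lookup, enforcing eigenvector sign
continuity by dot-product alignment.  Termination: FA < 0.15, per-step
turning > 15 deg, or ROI exit.  Tracks are retained when their endpoints
reach the two end-region masks (dilated by 3 voxels, 6-connected); the
retention filter can be disabled when quantifying tracking error under
noise.  Retained tracks are refit coordinate-wise as cubics in normalized
arc length, and of any pair of tracks whose symmetric mean closest-point
distance falls below one voxel edge the later-indexed one is discarded.
Fractional anisotropy uses the standard eigenvalue form with FA of the
zero tensor defined as 0; axial diffusivity is the largest eigenvalue and
radial the mean of the two smaller.

## Muscle architecture

Fiber crossing points are scrambled-Sobol samples rejected into the
reference cross-section polygon at 350 fibers/mm^2.  Innervation numbers
follow `y_i = y1 exp((ln R / n) i)` with n = 120, y1 = 21, R = 84 (half-up
rounding; the first 90 units then total exactly 15,493 fibers).  Territory
centers are drawn from the crossing-point set; each radius is solved by
bisection so the circle-section intersection area equals innervation
number over a per-unit fiber density drawn uniformly from 25–45
fibers/mm^2 — territories clipped by the muscle border therefore grow to
compensate.  Points are attributed to the nearest unit with unfilled
quota, resolved in rounds with random tie-breaking inside overfull
regions, so the covered point set stays spatially uniform.

Fibers grow bidirectionally from their crossing points in 0.1 mm steps
along the direction field, stopping at the muscle boundary or at a
15-degree-per-step turn; innervation points are truncated-normal draws
centred on the fiber midpoint with SD 10% of fiber length, truncated to
the fiber extent.  The direction field interpolates track tangents with
normalized inverse-distance weighting over the 8 nearest samples
(sign-aligned per query); it reproduces the tangents exactly at the track
points.  True natural-neighbor interpolation in 3-D was judged not worth
its cost for the smooth phantom fields; the interpolator is a documented
seam where users can plug an alternative.

Per-unit fiber diameter and conduction velocity increase linearly with
recruitment index across their population ranges (size principle).  The
ranges are data; the monotone mapping is this package's choice.

## Motor pool

A Fuglevand-style pool: recruitment thresholds are exponential in unit
index with a 30-fold range across the pool, rescaled so threshold 90 of
120 equals the 25 %MVC plateau exactly; the drive is a
ramp–plateau–ramp trapezoid (5 %MVC/s, 25 s).  Firing rate is linear in
excess drive (gain 2 Hz per %MVC) between a minimum of 8 Hz and a
per-unit peak; the default "onion-skin" scheme lowers the peak with
recruitment index, an after-hyperpolarization variant raises it.
Inter-spike intervals carry Gaussian jitter (CV 0.15) and a 20 ms
refractory floor.  Pool size, the 90-unit recruitment at 25 %MVC and the
trapezoid protocol are pinned constraints; the rate parameters are free
modelling defaults, not data.

## EMG engine

Fiber potentials evaluate the zero-sum source train against h interpolated
linearly in arc length — equivalent to the discrete convolution
`i0(t) * h(x, t)` and verified against a direct brute-force summation
oracle.  MUAPs superpose a unit's fibers on a common 20 kHz time base
sized to the slowest fiber's transit plus a 5 ms guard.  The recorded
montage takes each corner contact of the 5 x 5 mm array against the center
contact (the recording system's "double differential" nomenclature); a
true second-difference montage is available as an option.  Interference
EMG convolves spike trains with MUAPs (FFT convolution), adds white
Gaussian noise, and band-passes 20–2000 Hz with a zero-phase 4th-order
Butterworth.  The stated noise level "107.5 dBW (1 ohm)" is dimensionally
ambiguous; it is interpreted as noise *power* -107.5 dBW into 1 ohm,
i.e. sigma = 10^(-107.5/20) V ~ 4.217 uV, and is configurable.

Signal features: RMS over the analysis window (plateau-only by default
when a window is given; the record's full extent otherwise), median
frequency from a Welch spectrum (1 s Hann segments, 50% overlap),
skewness, and non-excess kurtosis (Gaussian = 3).  Spike-triggered
averaging means windowed record segments aligned on a unit's firing times
and requires at least 10 usable spikes.

The electrical profile map evaluates the mean of the five electrode lead
fields on a grid over the reference cross-section — zero additional
solves — normalized by the maximum across the compared states; the pick-up
radius is the maximal distance from the array's surface projection at
which the normalized profile still reaches the stated level (0.30 by
default).

## The phantom: what it emulates and what it does not

The phantom is a 40 x 28 x 24 mm layered box: 1 mm skin and 2 mm fat over
muscle, with a two-shell bone cylinder buried below the muscle belly, a
five-contact electrode array (0.5 mm contacts at the corners and center of
a 5 x 5 mm square) on the skin above the belly, and ground on one end
face.  The muscle belly is an elliptic tube (semi-axes 9 x 6 mm, about
170 mm^2 cross-section).  The fiber-direction field is bipennate-like: two
families tilt toward the central aponeurosis plane with a pennation angle
that tapers linearly to zero at the plane, so streamlines converge
smoothly.  State semantics: *rest* tilts in the skin-parallel plane
(15 deg at the belly edge); *abduction* fans the families wider (25 deg)
and adds a constant 20 deg dip toward depth, emulating fibers projecting
from dorsum toward palm; *flexion* aligns the families (5 deg) parallel to
the surface.  Diffusion tensors are built directly from the analytic
field with eigenvalues (1.85, 1.09, 1.09) x 1e-3 mm^2/s (FA = 0.3156) on
a 2 mm voxel grid; background voxels are isotropic and therefore excluded
by the FA gate.  Tensor noise is additive Gaussian on the six components,
calibrated to a mean Frobenius-norm SNR — raw diffusion-weighted signals
and Rician noise are out of scope, as is any real anatomy.

Consequences for interpretation: passing tests demonstrate the numerics
and the qualitative physics (reciprocity, charge balance, the
volume-conductor model ladder, anisotropy-driven pick-up changes) on a
clean, convex, desk-scale geometry.  They do not certify subject-specific
amplitudes: the reference study's headline values (0.21/0.10 mV RMS,
6.3/5.4 mm pick-up radii, in-vivo FA 0.33) depend on a real hand geometry
and a ~9-million-DoF mesh that are deliberately out of scope.

**Model ladder conditions.**  The five-model comparison (I analytic
infinite isotropic; II homogeneous FE; III inhomogeneous FE; IV anisotropic
muscle, ratio 4.4; V ratio 10 — implemented as 0.90/0.09 S/m, keeping the
transverse value) is evaluated on a representative mid-belly motor unit at
the 1 mm mesh.  Units hugging the muscle–fat interface (< ~3 mm below it)
sit in a regime where the local potential build-up under the resistive cap
outweighs the anisotropic smoothing and the amplitude effect of anisotropy
can invert; mid-belly units, which dominate the population, show the
expected ordering (II > I > none, III > II, IV < III, V < IV, and a
median-frequency drop from III to IV).

## Problem sizes and determinism

Defaults are desk-scale by design: 2 mm test meshes (about 20k tetrahedra)
and 1 mm meshes (about 161k) for the finer FEM comparisons; 5 simulated
units of the 120-unit pool in the demonstration pipeline; 11–12 s records
for spectral features.  All randomness funnels through seeds recorded in
the run manifest; identical config and seed reproduce outputs exactly
(conjugate gradients is deterministic for a fixed mesh and ordering).

## Known limitations

* The electrode patch collapses to one boundary triangle on meshes coarser
  than the physical contact; inter-electrode distances are honored but the
  contact area is mesh-dependent.
* Nearest-neighbor tensor lookup quantizes streamline curvature at the
  voxel scale (trilinear component interpolation is the natural upgrade).
* The motor pool's rate parameters are plausible defaults, not fits; only
  the recruitment constraint is data-anchored.
* Conduction velocity is constant along each fiber, and the membrane model
  is the analytic waveform — no conductance-based dynamics.
* Capacitive, inductive and frequency-dependent tissue effects are
  neglected (fixed 150 Hz conductivities).
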