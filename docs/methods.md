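# Methods

`helimorph` models the helical polymorphism of tubular 2D protein crystals
— concretely, the baculovirus nucleocapsid, whose wall is a 2D crystal of
VP39 dimers rolled into a tube — and implements the complete
model-and-classify loop: derive helical symmetry for any wrapping of the
lattice, build (optionally flattened) pseudo-atomic tube models, render
band-limited projections, and assign noisy segment images to the
polymorph/flattening hypothesis that explains them best.

## Wrapping geometry

The tube wall is described by a planar lattice with basis vectors
**a**, **b** given in a frame whose x axis is the equator of a reference
wrapping and whose y axis is the helix axis.  For the VP39 lattice these
are **a** = [27.91, −43.86] Å and **b** = [72.31, 43.86] Å, with the
reference wrapping (n₁, n₂) = (14, 14).

A wrapping index (n₁, n₂) defines the wrapping vector **w** = n₁**a** +
n₂**b**; the tube has circumference C = |**w**| and radius r = C/2π.  Each
basis vector decomposes into an arc component xᵢ (along **ŵ**) and an
axial component yᵢ, giving per-basis twists 360°·xᵢ/C.  The rotational
order is gcd(|n₁|, |n₂|): a Cₙ rotation maps the rolled lattice onto
itself exactly when n divides both indices, so the gcd is the general
condition (the "integer multiples" picture is its special case).

The canonical one-start screw operator is constructed, not assumed: axial
rises of lattice translations form the arithmetic set (|det(a,b)|/C)·g·ℤ
with g the rotational order, so the minimal positive rise is g·|det|/C.  A
lattice point achieving it is found with the extended gcd and its twist is
reduced modulo 360°/g to the representative of smallest magnitude.  The
operator is reported with positive rise; the twist sign then carries the
handedness.  For (14, 14) this yields rise 43.86 Å and twist −7.16°,
matching the refined reconstruction parameters, with no free choices left.

Candidate polymorphs are enumerated over a circumference window
(1140–1660 Å for the observed tubes, i.e. diameters ≈360–530 Å).  The
sector of lattice points considered is a predicate the caller can inject;
the default keeps pitch angles |atan2(w_axial, w_arc)| ≤ 20° and
canonicalizes signs with n₁+n₂ > 0.  The exact sector used to pick a
reference set is a presentation choice, not physics, which is why it is
injectable rather than hard-coded.

## Tube building

The asymmetric unit (a rigid dimer, or the synthetic stand-in below) is
radialized — translated so its center of mass sits at (r, 0, 0) with its
outward direction along +x — and then symmetry-expanded.  Each lattice
point (u₁, u₂) with arc coordinate in [0, C) and z in the requested window
produces one placement:

    x ↦ R_z(azimuth) · R_spin · x + (0, 0, z)

where the spin rotation about the radial axis accounts for the in-plane
rotation of the 2D lattice between the reference wrapping and the current
one (signed angle from **ŵ**_ref to **ŵ**).  Positive spin appears
counterclockwise viewed from outside the tube; internally it is a rotation
by −spin about +x.  The sign convention is pinned by a test: with the
wrong sign, inter-subunit atomic contacts in a strongly tilted wrapping
such as (6, 13) change by >100 %, while the correct sign leaves only the
curvature-induced drift (≤ ~16 % at the smallest radii; center-of-mass
packing is exactly invariant by construction).

Keeping one representative per congruence class modulo (n₁, n₂) makes the
rolled lattice seamless by construction.  Models are written as mmCIF
(chains named by lattice coordinates; unlimited subunits) or PDB
(single-character chains, 62-subunit limit with an explicit error or
opt-in recycling).

## Perimeter-preserving flattening

Tubes compressed in thin ice deform toward an elliptical cross-section
while the crystalline wall conserves its arc length.  For a flattening
scale k ∈ [1.00, 1.09] (0–9 %), the semi-major axis is a = k·r and the
semi-minor axis b is solved by bracketed root finding (Brent, bracket
[0.4 r, r]) so that the elliptical perimeter equals C to ≤10⁻⁸ relative.
Perimeters and partial arc lengths use the complete/incomplete elliptic
integrals of the second kind, so accuracy is limited only by machine
precision; arc-length inversion is again Brent's method on the strictly
monotone arc-length function.

Each subunit keeps its axial position and its arc-length coordinate
s = r·azimuth, mapped to the ellipse point at arc length s from
(+a, 0) counterclockwise; the subunit is rotated about the vertical axis
through its center of gravity so its outward reference aligns with the
exact ellipse normal.  The registration between azimuth 0 and the major
axis is an arbitrary phase (configurable, default 0): any fixed choice is
absorbed by the azimuth search during classification.  Flattening composes
from the round model only; re-flattening a flattened tube is rejected
rather than silently compounded.

## Rendering and spectra

Densities are sums of isotropic Gaussian blobs, one per atom, amplitude
proportional to a scattering weight (≈ atomic number, generic carbon for
pseudo-atoms).  Projections perpendicular to the tube axis are generated
by two independent paths:

* **analytic splat** (default): the projection of a 3D Gaussian is a 2D
  Gaussian of the same σ, so atoms are splatted directly with the view
  rotation φ, in-plane rotation ψ and shifts applied to coordinates —
  no interpolation at all;
* **volume path**: trilinear-deposited, Gaussian-filtered 3D volume,
  line-integrated along the view, with ψ/shifts applied by spline
  interpolation (cubic by default); the two paths must agree within 2 %
  RMS on small test objects, which the suite verifies.

The fast `binned` splat (bilinear deposit + Gaussian filter, with the
deposit kernel's 1/6 px² variance compensated in the filter width) is
accurate to ~2 % at the 12 Å band for σ ≥ 1.5 px and is kept for bulk
volume work; the default pipeline uses the exact splat throughout so
references and segments share one rendering contract.

Band limiting is a hard radial low-pass in Fourier space; 12 Å is the
working resolution of the whole classification, matching what the
alignment is meant to resolve.  Blob σ defaults to 4 Å so the 12 Å band
retains contrast (attenuation ≈0.11 at the band edge).  Noise is white
Gaussian with variance var(signal)/SNR measured inside the projected tube
support (pixels above 5 % of the peak); the seed fully determines the
field.  Power spectra are |FFT|²/N, zero-frequency centered, so their sum
equals the image energy.  A C14 tube's projection shows its strongest
off-equator meridional layer line at 1/43.86 Å⁻¹, which the tests locate
to the nearest discrete bin.  MRC2014 I/O (mode 2 float32, ISPG
distinguishing volumes from stacks) is implemented directly on the header
specification and round-trips bit-identically.

## Supervised classification

The reference bank holds band-limited projections for every
(n₁, n₂, scale) hypothesis, sampled over one rotational period of φ
(360°/order for round tubes; flattening reduces the usable symmetry to
gcd(order, 2)).  Rotating a flattened tube in φ also rotates its
flattening axis relative to the view, so no separate axis-orientation
search is needed.

The score is masked normalized cross-correlation in [−1, 1]: references
are zero-meaned and unit-normalized under a circular mask (default radius
= largest tube radius + 3σ + 15 Å, capped just inside the box); the
segment's local mean and variance under every shift of the mask come from
two FFT correlations, and each reference projection then costs a single
FFT product per ψ.  Correlations are circular; the shift search is capped
at ±¼ box so wrap-around touches only background.  A brute-force
nested-loop implementation of the identical score is kept in the tests
and must agree with the FFT path at every grid point.

The search is two-stage: a coarse grid (φ step 6°, ψ ±12° step 4°, all
integer-pixel shifts) scores every entry, then the top-4 entries are
re-scored on a local grid subdivided 3× in φ and ψ around each entry's
coarse optimum.  Fine-φ projections are rendered lazily from the stored
tube models and cached on the bank entry, so their cost amortizes across a
stack.  The ψ range assumes segments are extracted with the tube axis
vertical to within ~10°, as helical pickers provide.  Assignment is the
arg-max over entries with deterministic ties to the lowest key; the margin
to the runner-up is recorded so downstream users can impose their own
confidence cutoffs — none is imposed here, because supervised
classification of near-degenerate polymorphs can produce confident-looking
wrong assignments and the margin is the honest summary of that risk.

Grid defaults were chosen to resolve the 12 Å band at r ≈ 220–260 Å within
a single-CPU desk-scale budget; they are all configurable in
`SearchGrid`, and the refinement stage is what keeps the effective pose
resolution finer than the coarse steps suggest.

## Synthetic data

`make_pseudo_unit` draws a chiral cluster of Gaussian blobs (default 24)
uniformly in a (tangential 100 Å × axial 50 Å × radial 45 Å) box, echoing
the footprint of the real dimeric repeat unit; a generic random cluster
has no internal mirror symmetry, so handedness is testable (projections
mirrored across the equator decorrelate below 0.95 even at their best
axial shift).  `generate_dataset` builds each requested class once, then
projects at seeded random poses (φ uniform on [0, 360), ψ uniform within
±10°, shifts uniform within ±50 Å), band-limits to 12 Å, and adds noise at
the requested SNR.  Three named PRNG streams (unit, poses, noise) derive
from one master seed so stages can be varied independently; the whole
pipeline is bit-reproducible from the spec.

The standard validation suite is 6 wrappings {(13,13), (14,14), (15,15),
(13,14), (14,15), (6,13)} × 3 flattening scales {1.00, 1.02, 1.05} × 20
segments, 128² px at 5 Å/px, SNR 0.3, seed 20240104.  The wrappings cover
the dominant polymorph, its single-subunit insertion/deletion neighbors
(the hardest confusions: diameters differ by only ~9–30 Å), and one
strongly tilted lattice point.  On this suite the classifier recovers the
true (n₁, n₂) for ≥90 % of segments and confuses flattening only between
adjacent scales within the (14,14) class.

What the generator does *not* emulate: CTF (classification operates on
12 Å band-limited data, where a CTF envelope mostly rescales contrast; an
optional multiplier could be added but is deliberately out of the default
path), ice gradients, support film, dose damage, out-of-plane tilt, or
model mismatch between the reference subunit and the imaged one —
references and segments share the same pseudo-unit, which makes the
recovery criterion a test of the geometry/search machinery, not a claim
about attainable accuracy on micrographs.  Real-data fractions (which
polymorphs occur at which rates) therefore cannot be reproduced here; a
synthetic mixture drawn at comparable proportions (40 % (14,14), a small
non-flattened minority) is recovered within binomial sampling error as a
qualitative echo.

## Numerical choices and edge cases

* Angles are degrees, lengths Å, everywhere in the API.
* Degenerate lattices (|det| ≈ 0), zero wrapping index, non-positive
  radii/axes/SNR, sub-Nyquist band limits and oversized masks raise
  `ValueError` rather than propagating garbage.
* Flattening scales above ~1.57 have no perimeter-preserving minor axis
  and are rejected by the bracket check.
* Arc-length inversion guards the s ≈ 0 / s ≈ P endpoints against
  floating-point rounding of the modulo reduction.
* Scoring runs in single precision (the FFT backend's float32 path); the
  brute-force oracle agrees to ~10⁻⁴, well below any decision margin the
  classifier acts on.
* Half-open z windows [z_min, z_max) make stacked windows partition-exact;
  an empty window warns and returns an empty model instead of raising.

## Problem sizes

Desk-scale defaults (128 px boxes, 5 Å/px, 18-entry bank, 360-segment
suite) were chosen so the full pipeline — generation, bank, coarse +
refined classification — completes in a few minutes on one CPU.  The
paper-scale regime (912-px boxes at sub-Å pixels, hundreds of references)
is supported by the same code paths but is not exercised by the tests.
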