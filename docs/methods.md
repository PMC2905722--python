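# Methods

This note documents the physical model, the numerical choices, and the
limits of what the bundled tests demonstrate.

## Tissue transport

Photon packages follow the standard weighted-walk scheme for turbid
media. The per-event rules are:

* **Step.** `d = −ln ζ / μt`, `μt = μa + μs`. When `μt = 0` (free
  space) the step is infinite and no random number is consumed, so a
  ballistic ray-cast and the full loop consume identical streams — this
  is what makes the free-space degeneracy check bit-exact.
* **Absorption.** Deposit `w · μa/μt` at the site. A pure absorber
  (μs = 0) therefore kills a package at its first interior interaction,
  which reproduces Beer–Lambert attenuation for the *exiting fraction*
  exactly.
* **Scattering.** Henyey–Greenstein deflection cosine; the closed-form
  inverse handles any g in [−1, 1], with g = 0 reducing to `2ξ−1` and
  |g| = 1 to a delta at ±1. Azimuth uniform. The rotation uses the usual
  local-frame formula with the |uz| > 0.99999 polar branch and a final
  renormalization; 10⁴ consecutive spins drift the norm by < 1e−6.
* **Boundary.** Unpolarized Fresnel reflectance decides specular
  reflection vs Snell refraction. The random draw is *skipped* when the
  reflectance is exactly 0 (matched indices) or 1 (beyond the critical
  angle); besides saving a draw, this keeps stream consumption identical
  between media with and without an index step in the degenerate cases
  the tests rely on. A transmitted package carries its full residual
  weight out; there is no partial transmission splitting.
* **Roulette.** Below `10⁻⁴` of the launch weight a package survives
  with probability 0.1 (weight ×10) or dies with its weight booked to a
  signed roulette channel. Both parameters are configurable; the
  defaults are the values in common use for weighted-packet codes.
* **Step across a boundary.** The package is advanced to the boundary
  and, after a reflection, a fresh full step is sampled. For
  exponential steps this resampling is distributionally equivalent to
  carrying the residual (memorylessness) and considerably simpler.

The ledger identity `launched = absorbed + exited + roulette_net` is
exact bookkeeping, not a statistical statement. Kernels accumulate
per-package sums locally and combine them with Kahan compensation, so
the residual stays near machine epsilon even for 10⁹-event runs (the
tests require 1e−9 relative; observed ~1e−16).

The reference per-package operations in `tissue.py` mirror the compiled
kernel *bit for bit* (same draw order, same left-to-right arithmetic;
note that numpy's 3-vector dot product rounds differently from a scalar
left-to-right sum, so the reference path spells dots out explicitly).
One test asserts this equivalence on a few hundred packages.

## Geometry

The phantom is a finite cylinder in canonical pose (axis +z, base at
z = 0, mm units); the source region is an embedded cylinder treated
optically as phantom material — emission is volumetric, uniform and
isotropic, and there is no index step at the hole wall. Degenerate
source dimensions (radius or height 0) give disc, line and point
emitters; a pencil emission mode replaces the isotropic direction draws
for collimated test beams. Ray–cylinder intersection is analytic;
candidates below 1e−9 mm are discarded to prevent self-intersection
after boundary events, and a point exactly on the surface counts as
inside. The general-pose API transforms through the region's local
frame, making intersections rigid-motion equivariant; the transport
kernel itself runs in the canonical frame.

## Camera model

The lens is an ideal thin lens. `u` and `v` are *axial* distances; the
factor `(u + v)/cos α` converts axial separation to path length along
the chief ray, which is how an off-axis point is carried to its image.
The detector mapping uses `v′ = v_ccd` — the chief-ray intersection with
the physical CCD plane — i.e. a perspective projection through the lens
center. For a point whose ideal image distance equals `v_ccd` this *is*
the exact image point; for other points it is where the focused image
would be projected, consistent with the assumption that the whole
surface lies within the depth of field. By default `v_ccd` is chosen to
focus the phantom's nearest surface point.

The field visibility factor is operationalized as "a real image exists
(u > f) and its projection lies on the CCD active area"; the system
factor tests the ray against the aperture disc in the lens plane. The
phantom is convex, so a ray leaving the surface in the outward
hemisphere can never re-enter it — no separate occlusion test is needed
for these scenes.

The energy-loss coefficient τ is a pluggable model (constant T₀ = 1 by
default, optional `cos⁴α` vignetting). Because τ of a real optical
train must be measured, simulated images are qualitative in absolute
scale; relative structure (facula position, view-to-view ratios) is the
meaningful output. Each accepted package deposits its full weight into
the single pixel containing its projection (nearest-pixel binning) —
the simplest unbiased estimator of the detected-flux integral.

Perspectives rotate the camera, not the phantom: the lens sits at a
configurable standoff (default 200 mm) from the phantom axis at
mid-height, at azimuth 0/90/180/270° (front/left/back/right), with its
axis pointing from the scene toward the CCD. The raw image keeps the
optically inverted orientation; a `flip` flag marks presentation output
(TIFF) to be mirrored upright, and the plain-text matrix stays raw.

## Random numbers and parallelism

A single multiplicative congruential generator drives everything;
output is `x · (1/m)`, strictly inside (0,1), so `ln ζ` is always
finite. The default constants are the Lehmer minimal-standard pair
(a = 16807, m = 2³¹−1), chosen as a well-studied full-period generator
of the stated class; alternates (e.g. a = 48271) are configurable, with
the constraint `a · m < 2⁶³` for exact 64-bit arithmetic.

Dividing-cycle partitioning assigns worker `i` the master-sequence block
`[iL, (i+1)L)`; block starts are located by modular exponentiation
rather than by iterating the master sequence — mathematically identical,
without O(N_c·L) master work. `L` is `draw_budget × ceil(N/N_c)` with a
default budget of 10⁴ draws per package (the phantom scene consumes
~2.7×10³ on average, leaving ample headroom); a worker that exhausts its
block raises a stream-overrun error rather than silently reusing a
neighbour's draws. Partitions whose total reaches the generator period
are rejected outright.

A single-worker run uses the master stream directly with no block bound:
with one stream there is nothing to overlap. Long serial runs can
exceed the generator period (the 10⁶-package phantom scene consumes
~2.7×10⁹ draws against a period of ~2.1×10⁹); the stream then reuses the
cycle with shifted phase. This is an inherent limitation of the
generator class at this scale and is acceptable for the qualitative
imaging results here, but quantitative work at 10⁸ packages should
prefer partitioned parallel runs and larger-period constants.

Workers are same-host processes exchanging pickled tasks and partial
results (the message-passing topology kept as a swappable boundary);
merging is fixed in worker-index order, so outputs are byte-for-byte
reproducible. Wall-clock timings are reported per worker in run
diagnostics but are deliberately not a validated quantity — they are
hardware-bound.

## Scene presets and what the tests show

`bench_phantom` encodes the bench scene the model targets: cylinder
⌀30 × 30 mm, source hole ⌀2 mm × 16 mm deep at 8 mm offset,
μa = 0.0138 /mm, μs′ = 0.91 /mm, 55 mm f/8 lens. Published values end
there; g = 0.9 (hence μs = 9.1 /mm), n = 1.4 for nylon, 200 mm standoff,
and a 256×256 / 0.11 mm detector are this package's defaults, all
config-exposed. The default package count is 10⁶ — a deliberate
reduction from the 10⁸ a production-quality image would use; the CCD
image is correspondingly sparse (~10² accepted packages), which is why
the image-level checks assert centroid positions and brightness
ratios, not pixel-level distributions.

The synthetic scenes emulate geometry, optics and transport physics
exactly, but not detector noise, CCD calibration, lens aberrations or
ambient light; passing tests therefore validate the transport and
imaging mathematics, not agreement with any particular measured image.

Verification oracles used by the suite: exact bookkeeping identities;
Beer–Lambert closed form (3 binomial σ at 10⁵ packages); bit-equality
between the transport loop and a ballistic ray-cast in the degenerate
free-space medium; the Henyey–Greenstein first moment (3σ at 10⁶);
closed-form thin-lens magnification (1e−9 mm); the aperture solid-angle
fraction `(1 − D/√(D²+a²))/2` (3σ at 10⁵); brute-force iteration of a
tiny full-period MCG (a = 3, m = 7) for the stream partition, checked
exhaustively; and sequential replay of worker tasks for parallel runs.

## Known limitations

* Single homogeneous region; no voxelized media, meshes, internal index
  interfaces, fluorescence, polarization or time resolution.
* Thin-lens optics only: no thick-lens ray tracing, diffraction, or
  depth-of-field blur (all surface points are assumed in focus).
* Absolute radiometric scale depends on the unmeasured τ; outputs are
  qualitative in scale.
* The minimal-standard MCG's period bounds the number of independent
  draws; see above.
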