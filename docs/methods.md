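# Methods

## Model overview

`photonmc` simulates light transport in turbid (absorbing + scattering)
media with the weighted photon-packet Monte Carlo scheme, on anatomy
described by nested closed triangular surface meshes, followed by a
free-space thin-lens model that maps the surface flux onto CCD detector
images.  The radiative picture is the standard one for biomedical optical
imaging: within a tissue region the medium is homogeneous and isotropic
with absorption coefficient `mu_a` (mm⁻¹), scattering coefficient `mu_s`
(mm⁻¹), Henyey–Greenstein anisotropy `g` and refractive index `n`;
refraction and reflection happen only at region boundaries.

A packet carries a continuous statistical weight rather than a single
quantum.  Its life cycle:

1. **Launch.** Initial weight `w0 = total_power / n_photons`.  Internal
   (bioluminescent) sources place packets uniformly over the source
   volume by rejection sampling with truly isotropic directions
   (`cos θ` uniform on [−1, 1]).  External beams start at the entry point
   along the beam direction; the normal-incidence specular fraction
   `((n_ambient − n_tissue)/(n_ambient + n_tissue))²` is removed from the
   weight at entry and tracked as its own ledger channel.
2. **Hop.** Free path `s = −ln ξ / (mu_a + mu_s)`.  If a boundary lies
   closer than the sampled path, the packet moves to the boundary and the
   *dimensionless* remainder of the step is carried across the interface
   and rescaled by the next region's `mu_a + mu_s` (the MCML convention).
3. **Drop.** At an interaction site the fraction `mu_a / (mu_a + mu_s)`
   of the current weight is deposited into the absorption voxel grid
   (continuous absorption; packets are not terminated by an absorption
   draw).
4. **Spin.** The deflection cosine is drawn from the Henyey–Greenstein
   inverse CDF (`cos θ = 2ξ − 1` when `g = 0`), the azimuth uniformly on
   [0, 2π), and the direction is rotated in the local frame (degenerate
   formula within 1e−5 of ±z).
5. **Boundary.** The unpolarized Fresnel reflectance `R(θᵢ)` is compared
   with one uniform draw: the packet reflects *or* transmits as a whole
   (no packet splitting), with Snell refraction on transmission and total
   internal reflection beyond the critical angle `asin(n_t/n_i)`.
   Transmission through the outermost boundary terminates the packet and
   records its residual weight on the exit recorders.
6. **Roulette.** Below the weight threshold the packet survives with
   probability `1/m` at weight `m·w`, else dies — unbiased by
   construction.  Both the killed and the injected weight are tracked, so
   the exact ledger `launched + injected = specular + deposited + exited
   + killed (+ cap/lost)` balances to rounding (≈1e−12 relative) in every
   run; with roulette disabled the physical identity
   `launched = deposited + exited` holds outright.

### Time and frequency domains

Every hop advances the elapsed time by `path · n / c` with
`c = 0.299792458 mm/ps`.  In TD mode each deposit/exit event is binned
into uniform gates `[start, stop)`; events outside the span land in a
dedicated overflow gate so conservation is never broken by the gate
window.  Frequency-domain data are *derived* from a TD record by the
discrete Fourier sum `Σ h_k exp(−i 2π f t_k)` over gate centers
(amplitude/phase); `f = 0` reproduces the CW total.  No native FD phase
tracking is attempted.

### Fluorescence

A fluorophore is a scene region plus a quantum efficiency `η ∈ [0, 1]`.
Once per interaction site inside that region — after the deposit, before
the scatter — an excitation-band packet converts with probability `η`:
the excitation packet terminates and an emission packet continues from
the same position and elapsed time with an isotropic direction, the
packet's current weight, and the emission-band optical property table.
Emission packets never re-convert (no re-absorption cascade), so the
conversion count equals the number of band-switched packets exactly.

## Geometry

Regions form a containment tree rooted in the ambient medium; each
boundary mesh must be closed, consistently wound and outward-oriented
(positive signed volume), with no degenerate triangles — all validated at
scene build, not per query (trimesh backs the watertightness and winding
checks; phantoms come from built-in generators or STL/PLY/OFF files).
Child meshes must lie strictly inside their parents; siblings must not
interpenetrate (vertex-level checks).

Ray–triangle intersection is an inclusive-edge Möller–Trumbore test.
Ties between coincident triangles at the same distance resolve to the
smallest triangle id, so replays are deterministic.  The production query
culls whole regions with an axis-aligned bounding-box slab test before a
flat scan of that region's triangles; a plain all-triangle scan is kept
as the independent oracle and the two are tested identical over 10⁴
random rays.  A full bounding-volume *hierarchy* was considered and
rejected: the scenes this package targets stay in the low thousands of
triangles, where the flat compiled scan wins on both simplicity and
speed, and per-region culling already skips most triangles in nested
scenes.

**Epsilon policy.**  After any boundary event the packet origin is nudged
1e−7 mm along its new direction, and intersections closer than 1e−7 mm
are discarded.  This prevents self-intersection with the surface just
left; the scale is far below any feature size of interest (µm-scale) and
far above double-precision noise at phantom coordinates.

Point-in-region queries use crossing parity along a fixed
irrational-slope probe direction (so axis-aligned mesh edges are never
hit exactly); the innermost (deepest) odd-parity region wins.

**Face recording chart.**  For an axis-aligned box outer boundary, exits
can be accumulated on per-face `rows × cols` grids.  Each face is charted
by its two in-plane axes ordered by axis index (lower axis → rows),
origin at the minimal corner, `bin = floor(local/Δ)` clamped to the last
bin on the maximal edge.  Per-triangle exit records are always available
and are the general-geometry recorder.

## Free-space imaging

Surface elements (face-grid cells or triangles) are Lambertian emitters
with flux density `J = exited weight / area`.  A thin-lens camera
(`1/u + 1/v = 1/f`, enforced to 1e−9 at construction) maps an element to
a pixel by central projection through the lens center onto the detector
plane at distance `v` behind the lens (magnification `v/depth`,
inverted, nearest-pixel assignment — no anti-aliasing, so images are
bit-reproducible).  The energy assigned there is the Lambert-cosine
kernel

    ΔE = J · cos θs · cos θd · ξ(r, r_d) · dS / (π |r − r_d|²)

evaluated with the receiving point `r_d` on the **virtual detector
plane** and copied to the conjugate pixel unchanged (equal flux density
at conjugate points).  The virtual plane is realized as the detector
plane mirrored through the lens center — at distance `v` *in front* of
the lens — rather than at the detector's conjugate plane at distance
`u`: the mirrored plane keeps the receiver facing the incoming light and
makes `|r − r_d|` the physical propagation distance, whereas the
`u`-plane generally cuts through the scene and is singular for elements
near it.  The position mapping is identical either way.  Consequence:
cameras should be demagnifying (`u > 2f`, hence `v < u`), which is the
realistic small-animal CCD geometry; elements closer to the lens than
the virtual plane are culled by the receiver cosine clamp.  Visibility
`ξ` is an exact 0/1 segment–mesh test; back-facing emitters are culled
by clamping `cos θs` at zero.  The `π` in the denominator is the
Lambertian radiosity normalization.  No finite apertures, depth of
field, spectral response or noise models.

## Randomness and determinism

Each packet owns a splitmix64 stream keyed by (run seed, packet index),
generated inside the compiled (numba) kernel; uniforms are mapped to the
open interval (0, 1) so `−ln ξ` is always finite.  Results are therefore
independent of execution order and bit-identical across repeated runs
with the same seed and configuration — serialized HDF5 results are
byte-identical (`track_times=False`).  Python-level sampling APIs use
numpy Generators; the compiled kernel and the vectorized numpy
primitives implement the same formulas and are pinned against each other
in the test suite.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `roulette_threshold` | 1e−4 × initial weight | start roulette below this weight; 0 disables |
| `roulette_m` | 10 | survival multiplier (survive with prob. 1/m) |
| `max_steps` | 1e6 | per-packet step cap; capped weight goes to a diagnostics channel with a warning |
| `EPS_NUDGE` | 1e−7 mm | boundary nudge / minimum hit distance |
| TD gates | 0–100 ps, Δ10 ps | uniform gate span for time-resolved runs |
| face grid | 300 × 300 | per-face exit binning on box phantoms |
| absorption voxels | 0.5 mm | deposit grid resolution in the DOT/FMT examples |

## Packaged study conditions

* `blt_cube`: 10 mm cube, `mu_a = 0.0002`, `mu_s = 11.7`, `g = 0.95`,
  `n = 1.37`; isotropic source sphere (radius 0.5 mm) centred at
  (0, 0, 2) — 3 mm below the +z face; four cameras at 90° spacing
  (radius 150 mm, f = 50 mm → v = 75 mm, 120×120 pixels at 0.1 mm).
* `dot_mouse`: ellipsoidal body (semi-axes 20×10×8 mm) containing five
  ellipsoidal organs plus an optional tumor
  (`mu_a = 0.55`, `mu_s = 29.5`), heterogeneous properties at 670 nm,
  perpendicular external beam on the back, 0.5 mm absorption voxels.
* `fmt_td`: the same synthetic body with two-band (620/690 nm)
  properties, fluorophore `η = 0.6` in the kidney, excitation beam on
  the back, gates 0–100 ps at 10 ps.

The configured photon budget is 10⁷, a typical production operating
point for phantom studies of this size; demos, tests and the examples
override it downward (`--photons` / `n_photons=`), which changes only
the Monte Carlo noise floor.  The
multi-organ phantom is **synthetic**: it reproduces the computational
content of a digital-mouse study (nested heterogeneous regions, external
illumination, tumor contrast, two-band fluorescence) on generated
ellipsoids, not the atlas geometry.  Consequently its absolute
transmittance values and gate histograms are not comparable to
real-mouse data — e.g. the synthetic body is large enough that most
emission light arrives after 100 ps and lands in the overflow gate.

## What the tests do and do not show

The suite verifies the simulator against independent oracles and closed
forms: HG moment recovery (`E[cos θ] = g` within 3 SE at 10⁶ draws),
quantum-efficiency recovery, Fresnel vs s/p-polarization averages to
1e−12, Beer–Lambert ballistic transmission, exponential point-source
decay, time-of-flight gate placement, exact energy conservation
(≤1e−9 relative without roulette; in expectation over 30 seeds with it),
face/CCD symmetry of a centred source within counting error, and
intersection-oracle equivalence.  Statistical tests use fixed seeds and
3σ bands.  None of this validates against a physical CCD measurement;
comparing to a lab experiment additionally requires camera calibration
and spectral effects that are out of scope here.  Typical problem sizes
in the suite: 10⁵ packets for the cube studies, 10³–10⁴ for the
multi-organ phantom, 10⁶ draws for the sampling-recovery checks — sizes
chosen so the whole suite runs comfortably on one core while keeping
counting errors well below the tested tolerances.

## Known limitations

* No polarization, no refractive-index gradients, no voxel/layered media
  modes; media are piecewise homogeneous between mesh boundaries.
* All-or-nothing boundary draws (as specified) increase variance
  relative to deterministic packet splitting.
* FD data come from TD histograms, so their frequency resolution is
  limited by the gate width.
* The thin-lens model is an ideal pinhole with conjugate scaling —
  no aperture integration, so absolute image irradiance follows the
  1/r² kernel rather than an f-number.
* Fluorescence ignores re-absorption/re-emission cascades and treats
  `η` as wavelength-independent within the band pair.
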