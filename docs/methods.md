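# Methods

This note records the modelling assumptions, the numerical choices and the
limits of validity behind `snapsole`. Everything quantitative stated here
is computed by the test suite or by `scripts/acceptance.py`.

## Shallow-arch model

The offloading element is a fixed–fixed arch whose stress-free mid-line is
the raised cosine `y0(x) = (h/2)(1 − cos 2πx/L)`. The theory is
Euler–Bernoulli bending plus mid-line stretching between immovable clamped
ends — the standard shallow-arch/bistable-beam setting. Its assumptions:

* slender cross-section (no shear deformation, no rotary inertia);
* shallowness: strain from the slope enters only through the averaged
  stretching term. Geometries with `h/L > 0.2` are rejected outright and a
  `ShallownessWarning` is issued above `h/L = 0.1`; the guard values are
  conventional rather than derived, because the expansion is asymptotic
  and has no sharp validity edge;
* linear elastic material, no damping. TPU is viscoelastic; see
  *Limitations*.

Deflection from the as-fabricated shape is expanded in the buckling
eigenfunctions of the straight clamped–clamped beam. The cosine shape *is*
the first symmetric mode, so the stretching integral couples the modes
only through one scalar, `s = Σ c_j a_j² − Q c₁ a₁`, and the reduced
equations depend on the geometry only through `Q = h/w` once displacements
are scaled by `w`, forces by `EIw/L³` and time by `L²√(ρA/EI)`. Exact
constants: `N₁ = 2π`, `c₁ = 2π²`, `m₁ = 3/2`; mode 2 has
`tan(N₂/2) = N₂/2`, `N₂ ≈ 8.98682`. The normalization of the
antisymmetric shape is immaterial because only `c₂a₂²` is physical.

## Switching force: the minimum-energy criterion

Under a step load the system starts at rest with total energy zero. The
asymmetric (second-mode) snap route opens when the saddle on the
bifurcated branch (`s = s* = −N₂²/6`) descends to energy zero. Combining
the three conditions (branch condition, `a₁`-equilibrium, zero energy)
gives a quadratic in `a₁`; each root carries a force and a second-mode
weight `A₂ = ±√((s* − c₁a₁² + Qc₁a₁)/c₂)`, real for one pair and imaginary
for the other. The real-A₂ pair's force is the switching force; if both
pairs were real the smaller positive force would be chosen (first
instability on loading). For this basis the quadratic's middle coefficient
cancels identically, so `f̄_s(Q)` is linear in Q above the bifurcation
threshold `Q ≈ 1.6517` (located numerically by bisection on the
existence of a real-A₂, positive-force pair, and cached).

This is an *infinite-time* (minimum possible critical load) criterion: for
a conservative system, below it escape through the saddle is energetically
impossible, while above it the trajectory eventually finds the saddle. The
transient oracle confirms the approach direction: its finite-window
threshold exceeds the closed form by ~5% at 30 natural periods and by
0.5–1.6% at 300 periods over the design band. The oracle's default window
is therefore 300 first-mode periods — a convergence choice, not a fit.

The quasi-static equilibrium path is computed under displacement control
(no arc-length continuation needed): for prescribed mid-span displacement,
the free path follows the symmetric cubic until the stretching scalar
reaches `s*`, then the linear negative-stiffness branch. The dynamic
switching force is below the static limit point (ratio ≈ 0.80 across the
band), as the energy argument requires. Note that force ordering between
the mode-2-suppressed and free paths holds only on the loading stroke (up
to the straight configuration); past it the branch force exceeds the
cubic, since constrained-vs-free ordering applies to energies, not their
derivatives.

## Switchback time: quartic and elliptic integral

Physical definition: the time from the extreme inverted configuration
(zero velocity) to the first return of the mid-point to the as-fabricated
height. Load removal is modelled as instantaneous.

The release state is taken from the post-snap motion under the sustained
switching load: with total energy zero, the maximum inversion is the
largest root of `V₁(a) = 2 f̄_s a`, where `V₁` is the unloaded single-mode
potential. Free motion then conserves `E₀ = V₁(a_start)`, and the turning
condition `E₀ − V₁(a) = 0` is a quartic with leading coefficient
`−(3/2)c₁²`. In the design band it has exactly two real roots straddling
zero (reported with the inverted side negative) and one complex pair
`p ± iq`; four real roots mean the energy does not clear the inter-well
barrier and the arch is **not self-returning** — an error, not a number.

With roots in hand, the time integral reduces by the Byrd–Friedman 260.00
substitution to `τ̄ = √(m₁/2)/√(c₄AB) · [2K(k) − F(φ₀, k)]` with
`A² = (a_hi−p)² + q²`, `B² = (a_lo−p)² + q²`,
`k² = ((a_hi−a_lo)² − (A−B)²)/(4AB)`, and `φ₀` marking the zero crossing;
`F` is the incomplete elliptic integral of the first kind (`F(π,k) = 2K`
recovers the full half-period between turning points). The complete-K
half-period alone is *not* the switchback time, because the quartic
potential is strongly asymmetric; the incomplete form was locked against
the release simulation, which it matches to integrator accuracy.
Evaluation uses `scipy.special.ellipk/ellipkinc` (parameter `m = k²`),
which are uniformly accurate down to `k = 0`; `k² ≥ 1 − 1e−9` raises a
separatrix diagnostic instead of returning a diverging number. Agreement
with adaptive quadrature of the same integral (turning-point singularity
removed by `a = a_hi − s²`) is at machine precision, tested at 1e−8.

## Design band

Three Q ranges matter for this arch family:

* `Q < 1.65` — no asymmetric snap route (no offloading);
* `Q ≳ 4.1` — the released single-mode energy falls below the inter-well
  barrier: not self-returning (and beyond ≈5.65 the two-mode model is
  statically bistable);
* inside, the single-mode switchback reduction carries a multimode error
  that is *not* monotone: ~5% around `Q ≈ 2.1–2.3` (inertial coupling to
  the higher symmetric modes through the non-diagonal mass matrix) and
  growing again past `Q ≈ 3.3` as unstable modes amplify parametrically
  during the return (the mode-2 instability condition `6|s| > N_j²` is met
  transiently by several modes).

The **design band is `Q ∈ [2.4, 3.2]`**, where the 6-mode release agrees
with the closed form to ≲3.7% and the force oracle to ≲1.6%. The designer
bounds, the contour maps' recommended range and the validation grid all
use it. The reference arch (`L=30, w=1, b=10, h=3 mm`, TPU at 26 MPa) sits
at its centre, `Q = 3`.

## Transient integrator (the oracle)

`M ä = −∇V(a; f)` for `n_modes` modes (default 6), velocity Verlet,
`dt = T_min/40` with `T_min` the shortest linearized modal period —
symplectic and undamped, with total-energy drift monitored and runs
aborted above 1% of the peak mechanical energy (measured drift is far
below the 0.1% test bound). A `1e−8·w` second-mode seed is injected at
`t = 0` so the asymmetric bifurcation can express itself; everything else
is deterministic. Snap criterion: mid-point displacement beyond the
straight configuration (`> h`) together with `|a₂| > 1e−6` — an
unambiguous, discretization-independent event.

The critical-force bisection brackets inside `[0, 10 × k_lin × h]`
(`k_lin` the linearized mid-span stiffness) and narrows to `rel_tol`
(default 0.1%). Near the threshold the snap/no-snap boundary is weakly
chaotic, so the finite-window threshold carries an intrinsic jitter of a
few tenths of a percent under dt or mode-count changes (measured: 0.23%
for dt halving at the default window, 0.3% for 6→12 modes); this is
modal-content physics, not integrator error, and is why the oracle
comparison tolerance is 3%.

`release_time` starts all mode counts from the same idealized inverted
extreme (the single-mode `a_start`, zero velocity, seeded mode 2), so the
1-mode run isolates numerics (<0.01% from the elliptic form) and the
6-mode run isolates mode-truncation error (the recorded multimode
fraction). Starting instead from a snapped multimode trajectory state
conflates initial-condition differences with truncation error and also
requires simulating at loads where finite-window snap is not guaranteed;
`simulate_step_load` still records the post-snap maximum-inversion state
for such diagnostics.

The inner loop is JIT-compiled with numba when importable; the pure-NumPy
fallback is semantically identical (validation grids then take a few
minutes instead of seconds).

## Pedobarography

Sensor grid: square cells of 0.7 cm side (~2 sensors/cm², the resolution
of clinical capacitive platforms); `sensor_area` returns both the exact
0.49 cm² and the 0.5 cm² one-decimal nominal used in reporting. The single
unit conversion kPa·cm² → N (×0.1) lives in `force_from_pressure`.

Ten regions — heel, midfoot, MTH1–5, hallux, second toe, toes 3–5 — are
assigned by length fractions of the footprint (heel 0–31%, midfoot
31–55%, metatarsal band 55–73% split into five medial–lateral strips,
toes 73–100% split 30/15/55% across the width). The fractional scheme is
a reproducible, configurable stand-in for the clinical template, whose
exact boundaries are not published in machine-readable form.

Image decoding: each sensor cell is a pixel block (default 8×8); the
block's majority colour absorbs anti-aliased boundary pixels and is
matched to the nearest legend colour within an RGB tolerance; unmatched
cells become background and a >5% unmatched fraction is a decode error.
The arch index is the middle-third contact area of the toeless print over
its total, with boundary rows weighted fractionally so a uniform
rectangle gives exactly 1/3; categories use the published cuts (<0.21
high, 0.21–0.28 normal, >0.28 low), as do the BMI bands (18.5/25/28).

### Synthetic pedoscan generator

The generator is the package's study condition, not a fixture hack. It
emulates: a foot-shaped contact patch sized from the Indian shoe size
(length ≈ 19 + 0.85·size cm, width 40% of length, midfoot contact
narrowed or removed by arch type), smooth per-region pressure bumps
following the heel-strike → toe-off progression with per-region peak
pressures (defaults scale linearly from a 55 kg reference: heel 240 kPa,
MTH1 220 kPa, …), five phase durations (defaults 120/150/220/160/120 ms),
±5% seeded per-region amplitude jitter, and calibration of the mid-stance
frame to total vertical force = body weight before quantization to the
16-level colour legend (stated tolerance 8% after quantization; measured
≤3%). Explicitly requested region peaks are applied as absolute pressures
after calibration so threshold-exceedance scenarios are exact. The
quantized grids *are* the ground truth: rendering is palette-exact and
decoding recovers them bit for bit.

What the generator does not emulate: sensor noise and hysteresis, partial
cell coverage at the foot boundary, inter-step variability, pathological
pressure patterns (ulcer scars, deformities), or the 25 Hz frame stream
of a real platform (it produces one representative frame per phase).
Passing tests therefore demonstrate the correctness of the *pipeline*
arithmetic and the design logic, not clinical accuracy on real feet.

## Designer

Per region, with `F_max` the maximum force over the gait phases and
`A_contact` its contact area, the design load is
`F_design = min(F_max, P_thr·A_contact)` with `P_thr = 200 kPa`: up to the
threshold force the array must carry the load; beyond it, snapping *is*
the intended function, so requiring the array to withstand more would
contradict offloading. Feasibility of a candidate geometry requires

1. `n·f_s ≥ F_design` with `n = max(1, ceil(F_design/f_s))` (at least one
   arch per region so every capping plate is supported);
2. `n·f_s ≤ P_thr·A_contact` (the array snaps before the region exceeds
   the threshold — the transmitted-pressure cap);
3. switchback time ≤ the shortest gait-phase duration;
4. row packing `n·(b+1 mm)·(L+1 mm)` within the region area.

Candidates come from a fixed catalog (L ∈ 15–35 mm, w ∈ 1–3 mm,
b ∈ 8–15 mm, Q ∈ 2.4–3.2, filtered by the shallowness guard), cached per
material. Among feasible candidates the largest switchback-time margin
wins, tie-broken by smallest packed footprint and then by a fixed
geometry ordering, making the search deterministic. Because the margin
depends only on geometry, regions tend to share a geometry and differ in
count. The midfoot is designed last under a part-coherence cap: when the
heel's (or forefoot's) maximum force is at least the midfoot's, its part
must not end up with fewer arches — the operational form of placing more
support under the clinically loaded heel and forefoot. Infeasible regions
produce a structured report naming the violated constraints of the
best-scoring candidate instead of aborting the layout.

The default material is printed shore-95A TPU at `E = 80 MPa`,
`ρ = 1210 kg/m³` (printed-TPU moduli span ~25–90 MPa; the stiff end is
what lets heel-strike loads pack into the heel area within the
shallowness bound). A 100-subject seeded cohort (45–90 kg, sizes 5–10,
phase durations 90–260 ms, all arch types) designs fully feasibly, and a
post-hoc audit that recomputes every constraint from the stored
geometries by direct calls reports zero violations.

## Problem sizes and determinism

Validation uses a 10-point Q grid on [2.4, 3.2]; oracle bisections run 6
modes, 300 first-mode periods, 0.2% brackets; release checks run 1, 6 and
12 modes; image checks use 50 frames (10 subjects × 5 phases); the design
audit uses 100 subjects. All randomness flows from explicit seeds
(`numpy.random.default_rng`); the transient oracle is fully
deterministic. The full test suite and the acceptance script each run in
well under a minute with numba, minutes without.

## Known limitations

* The closed forms are leading-order shallow-arch results; at the
  `h/L = 0.2` guard the theory is stretched and the designer deliberately
  uses geometries near it (they warn when rebuilt by hand).
* No damping: real TPU dissipates, so physical switchback is slower than
  the conservative estimate and physical switching thresholds sit between
  the finite-time and infinite-time values.
* The two-mode switching criterion is exact only asymptotically in time;
  transient overshoot under fast-rising loads is not modelled.
* Arch-to-arch contact, capping-plate compliance and fatigue of printed
  TPU are outside scope; so is any claim about in-shoe clinical
  offloading percentages, which require a human subject.
* The region template and the size→length mapping are parameterized
  stand-ins for clinical conventions and should be recalibrated against a
  clinic's own templates before real use.
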