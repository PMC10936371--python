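# snapsole

Design tools for **dynamically self-offloading therapeutic footwear** built
from arrays of snap-through arches.

In diabetic peripheral neuropathy, plantar pressures above roughly 200 kPa
promote ulceration, and statically carved offloading insoles lose their
effect as the pressure map drifts. A purely mechanical alternative replaces
the foam by arrays of shallow, fixed–fixed arches under rigid capping
plates: each array carries load up to a bespoke threshold, then snaps
through a negative-stiffness regime to an inverted shape, momentarily
dropping contact with the foot and redistributing the load; when the load
moves on, the monostable arches spring back unaided. The arches act as
sensor and actuator at once, powered by the wearer's own body weight.

`snapsole` implements the complete design chain for such insoles:

* **Arch mechanics** (`arch_core`, `statics`, `dynamics`) — closed-form
  dynamic switching force and switchback time of a shallow fixed–fixed
  cosine arch, from a two-mode Galerkin reduction.
* **Transient oracle** (`transient`) — direct multimode time integration
  (energy-conserving velocity Verlet) used to validate both closed forms by
  brute force: bisection on the step-load amplitude, and free-release
  timing.
* **Pedobarography** (`pedomap`) — decoding colour-coded plantar-pressure
  frames against a colour-bar legend, per-region forces over the five
  stance phases for the ten standard anatomical regions, arch-index and BMI
  classification, and a synthetic pedoscan generator with exact ground
  truth.
* **Customization** (`designer`) — the constraint search that picks, for
  every foot region, an arch geometry and count satisfying the load,
  200 kPa offloading-threshold, switchback-time and packing constraints,
  grouped into a three-part (forefoot / midfoot / heel) insole with a model
  code such as `W5060S68`.
* **CLI** (`cli`) — the `snapsole` command ties everything into a
  reproducible pipeline.

## The model

The arch is stress-free in the raised-cosine shape
`y0(x) = (h/2)(1 − cos 2πx/L)` with span `L`, in-plane width `w`,
out-of-plane breadth `b` and rise `h`; section properties `A = b w`,
`I = b w³/12`. With displacements scaled by `w`, point forces by
`E I w / L³` and time by `L² √(ρA/EI)`, the reduced dynamics depends only
on the shape parameter **Q = h/w**.

Expanding the deflection in clamped–clamped buckling modes (the cosine is
exactly mode 1; mode 2 is the first antisymmetric shape with wavenumber
`N₂ ≈ 8.987` from `tan(N/2) = N/2`), the potential is

```
V(a₁,a₂; f̄) = ½N₁²c₁a₁² + ½N₂²c₂a₂² + (3/2)s² − 2f̄a₁,
s = c₁a₁² + c₂a₂² − Qc₁a₁
```

* **Switching force.** A step load starts the arch from rest at energy
  zero. Snap-through via the asymmetric route first becomes possible when
  the bifurcated saddle (`s = −N₂²/6`) reaches energy zero; eliminating
  `a₂` and `f̄` reduces this to a *quadratic polynomial* whose two root
  pairs carry (force, second-mode weight A₂) — one pair real-valued, one
  complex — and the dynamic switching force `f̄_s(Q)` is the force of the
  real-A₂ pair. Dimensionally `f_s = f̄_s(Q) · E I w / L³`.
* **Switchback time.** After load removal the inverted arch returns
  through the straight configuration. Single-mode energy conservation
  turns the free motion into a quartic `E₀ − V₁(a)`: two real turning
  points straddling the as-fabricated state plus a complex pair. The time
  from the inverted extreme to the first zero crossing reduces to an
  incomplete elliptic integral of the first kind with modulus assembled
  from the quartic roots; `t_sb = τ̄(Q) · L² √(ρA/EI)`.

Both closed forms are checked against the transient integrator: the
bisection threshold converges to `f̄_s` from above as the window grows
(within ~1.6% at 300 natural periods across the design band Q ∈ [2.4, 3.2]),
and release simulations agree with the elliptic time to <0.01% (single
mode) and ≲4% (six modes).

## Worked example

A printed-TPU reference arch (`L=30 mm, w=1 mm, b=10 mm, h=3 mm`, so
`Q = 3`; `E = 26 MPa`, `ρ = 1210 kg/m³`):

```console
$ snapsole arch --L 30 --w 1 --b 10 --hmid 3 --E 26 --rho 1210
f_s = 0.692429 N
$ snapsole switchback --L 30 --w 1 --b 10 --hmid 3 --E 26 --rho 1210
t_sb = 1.30396 ms
```

Each such arch snaps at 0.69 N and returns to its as-fabricated shape
1.3 ms after the load disappears — far faster than any gait phase, so the
region it supports is ready again before the next step lands on it.

A full design for a 55 kg, size-6 subject, from synthetic pedoscan frames:

```console
$ snapsole synth  --weight 55 --size 6 --seed 42 --out scan
$ snapsole extract --frames scan --legend scan/legend.json --out forces.csv
$ snapsole design --forces forces.csv --weight 55 --size 6 --phase-ms 120 --out layout.json
model W5060S68: 51 arches; wrote layout.json
```

The extracted force table shows the heel-strike → toe-off progression
(heel peaks at 437 N at heel strike, MTH1 at 74 N at heel off), and the
layout places e.g. 26 stiff-TPU arches of 15 × 1 × 3 mm under the heel
(per-arch switching force 17.0 N, array threshold 443 N just above the
heel's design load and below the 200 kPa cap for its contact area) and 2–4
arches under each toe and metatarsal region, all with switchback times
under 0.2 ms against the 120 ms minimum phase. `snapsole pipeline
--config cfg.yaml` runs the same chain end to end and byte-identically on
repetition.

## Layout

```
src/snapsole/
  arch_core.py   geometry, material, nondimensionalization, config I/O
  _modal.py      clamped-clamped modal basis and Galerkin constants
  statics.py     equilibrium path, switching quadratic, f_s
  dynamics.py    switchback quartic, elliptic time, design contour grids
  transient.py   multimode step-load / release integrator (the oracle)
  pedomap.py     pressure-image decoding, region forces, synthetic gait
  designer.py    per-region constraint search and insole layout
  cli.py         the `snapsole` command
docs/methods.md  modelling assumptions, parameter choices, limitations
```
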