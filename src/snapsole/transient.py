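"""Direct transient integration of the multimode shallow-arch equations.

This module is the brute-force counterpart of the closed forms in
:mod:`snapsole.statics` and :mod:`snapsole.dynamics`: it integrates

    M addot = -grad V(a; f)

for ``n_modes`` clamped-clamped modes with the undamped, energy-conserving
velocity-Verlet scheme, and derives from the trajectories

* the dynamic critical step force (bisection on the step amplitude), and
* the switchback (release) time from the inverted extreme.

Because the system is conservative, the finite-window snap threshold
converges from above to the closed form's minimum-energy value as the
window grows; the default window of 300 first-mode periods brings the two
within ~1%.

A 1e-8 (in units of w) second-mode perturbation is injected at t = 0 so the
asymmetric bifurcation can express itself numerically; everything else is
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._modal import C1, N1, ModalBasis, modal_basis
from .arch_core import ArchGeometry, ArchState, Material, NondimArch, nondimensionalize
from .errors import IntegrationError, NoSnapError, NotSelfReturningError
from .statics import solve_switching_quadratic

__all__ = [
    "ModalArch",
    "Trajectory",
    "simulate_step_load",
    "oracle_critical_force",
    "release_time",
    "DEFAULT_N_MODES",
    "DEFAULT_WINDOW_PERIODS",
]

DEFAULT_N_MODES = 6
#: default integration window for the critical-force bisection, in periods
#: of the first linearized mode (long, because the conservative threshold is
#: approached from above as the window grows)
DEFAULT_WINDOW_PERIODS = 300.0
#: time step = (shortest retained modal period) / this
_STEPS_PER_MIN_PERIOD = 40
#: second-mode seed, units of w
_MODE2_SEED = 1e-8

# optional numba acceleration of the inner Verlet loop; the pure-numpy
# fallback is semantically identical
try:  # pragma: no cover - environment dependent
    import numba as _numba
except ImportError:  # pragma: no cover
    _numba = None


def _grad(a, f, Q, c, n2c, mid):
    s = float(c @ (a * a)) - Q * c[0] * a[0]
    g = n2c * a + 6.0 * s * c * a - f * mid
    g[0] -= 3.0 * s * Q * c[0]
    return g


def _verlet_numpy(a, v, Minv, c, n2c, mid, Q, f, dt, n_steps, record_every):
    n_rec = n_steps // record_every + 1
    rec_a = np.empty((n_rec, a.size))
    rec_v = np.empty((n_rec, a.size))
    rec_a[0] = a
    rec_v[0] = v
    acc = Minv @ (-_grad(a, f, Q, c, n2c, mid))
    k = 1
    for i in range(1, n_steps + 1):
        v = v + 0.5 * dt * acc
        a = a + dt * v
        acc = Minv @ (-_grad(a, f, Q, c, n2c, mid))
        v = v + 0.5 * dt * acc
        if i % record_every == 0:
            rec_a[k] = a
            rec_v[k] = v
            k += 1
    return rec_a[:k], rec_v[:k]


if _numba is not None:

    @_numba.njit(cache=False)
    def _verlet_numba(a, v, Minv, c, n2c, mid, Q, f, dt, n_steps, record_every):  # pragma: no cover
        n = a.size
        n_rec = n_steps // record_every + 1
        rec_a = np.empty((n_rec, n))
        rec_v = np.empty((n_rec, n))
        rec_a[0] = a
        rec_v[0] = v
        g = np.empty(n)
        s = 0.0
        for j in range(n):
            s += c[j] * a[j] * a[j]
        s -= Q * c[0] * a[0]
        for j in range(n):
            g[j] = n2c[j] * a[j] + 6.0 * s * c[j] * a[j] - f * mid[j]
        g[0] -= 3.0 * s * Q * c[0]
        acc = -(Minv @ g)
        k = 1
        for i in range(1, n_steps + 1):
            for j in range(n):
                v[j] += 0.5 * dt * acc[j]
                a[j] += dt * v[j]
            s = 0.0
            for j in range(n):
                s += c[j] * a[j] * a[j]
            s -= Q * c[0] * a[0]
            for j in range(n):
                g[j] = n2c[j] * a[j] + 6.0 * s * c[j] * a[j] - f * mid[j]
            g[0] -= 3.0 * s * Q * c[0]
            acc = -(Minv @ g)
            for j in range(n):
                v[j] += 0.5 * dt * acc[j]
            if i % record_every == 0:
                rec_a[k] = a.copy()
                rec_v[k] = v.copy()
                k += 1
        return rec_a[:k], rec_v[:k]


def _run_verlet(a0, v0, sys_, f, dt, n_steps, record_every=1):
    args = (
        a0.copy(),
        v0.copy(),
        sys_.basis.mass_inv,
        sys_.basis.c,
        sys_.n2c,
        sys_.basis.psi_mid,
        sys_.Q,
        f,
        dt,
        int(n_steps),
        int(record_every),
    )
    if _numba is not None:
        return _verlet_numba(*args)
    return _verlet_numpy(*args)


class ModalArch:
    """Galerkin reduction of one arch to ``n_modes`` clamped-clamped modes.

    Everything inside works in normalized units (see :mod:`snapsole._modal`);
    the stored :class:`~snapsole.arch_core.NondimArch` converts to SI.
    """

    def __init__(self, geom: ArchGeometry, mat: Material, n_modes: int = DEFAULT_N_MODES):
        if n_modes < 2:
            raise ValueError("n_modes must be >= 2 (the snap route is mode 2)")
        self.geom = geom
        self.mat = mat
        self.nd: NondimArch = nondimensionalize(geom, mat)
        self.Q = self.nd.Q
        self.basis: ModalBasis = modal_basis(n_modes)
        self.n_modes = n_modes
        self.n2c = self.basis.wavenumbers**2 * self.basis.c

    # -- reduced energies ---------------------------------------------------
    def potential(self, a, f: float = 0.0) -> float:
        """Normalized potential energy including the load potential."""
        a = np.asarray(a, dtype=float)
        s = float(self.basis.c @ (a * a)) - self.Q * self.basis.c[0] * a[0]
        v = 0.5 * float(self.n2c @ (a * a)) + 1.5 * s * s
        return v - f * float(self.basis.psi_mid @ a)

    def kinetic(self, v) -> float:
        v = np.asarray(v, dtype=float)
        return 0.5 * float(v @ (self.basis.mass @ v))

    def midpoint(self, a) -> float:
        """Normalized mid-span deflection (units of w, toward the load)."""
        return float(self.basis.psi_mid @ np.asarray(a, dtype=float))

    # -- linearized frequencies --------------------------------------------
    def frequencies(self) -> np.ndarray:
        """Normalized natural frequencies about the as-fabricated state."""
        K = np.diag(self.n2c)
        K[0, 0] += 3.0 * self.Q**2 * self.basis.c[0] ** 2
        w2 = np.linalg.eigvals(self.basis.mass_inv @ K)
        return np.sqrt(np.sort(w2.real))

    def default_dt(self) -> float:
        """Time step resolving the highest retained mode: T_min / 40."""
        return 2.0 * np.pi / self.frequencies()[-1] / _STEPS_PER_MIN_PERIOD

    def state(self, weights) -> ArchState:
        return ArchState(
            weights=np.asarray(weights, dtype=float),
            psi_mid=self.basis.psi_mid,
            length_scale=self.nd.length_scale,
        )


@dataclass
class Trajectory:
    """Sampled transient history of one arch (SI units).

    ``weights`` are the modal amplitudes (normalized, units of w) per sample;
    energies are reported in joules using the arch scales.  ``snapped`` is
    set when the mid-point passed beyond the straight configuration with a
    nonzero second-mode weight (the snap criterion), at time ``t_snap``.
    ``max_inversion_state`` records the post-snap maximum-inversion weights
    for diagnostics.
    """

    t: np.ndarray  # s
    weights: np.ndarray  # (n_samples, n_modes)
    midpoint: np.ndarray  # m, toward the load
    force: np.ndarray  # N, applied history (step)
    energy: np.ndarray  # J, kinetic + elastic (no load potential)
    total_energy: np.ndarray  # J, including load potential (conserved)
    snapped: bool
    t_snap: float | None
    max_inversion_state: np.ndarray | None
    arch: ModalArch

    def states(self) -> list[ArchState]:
        return [self.arch.state(w) for w in self.weights]


def _energy_scale(nd: NondimArch) -> float:
    return nd.force_scale * nd.length_scale


def simulate_step_load(
    geom: ArchGeometry,
    mat: Material,
    f: float,
    n_modes: int = DEFAULT_N_MODES,
    t_end: float | None = None,
    dt: float | None = None,
    record_every: int = 4,
) -> Trajectory:
    """Integrate the arch from rest under a mid-span step load of ``f`` N.

    The run starts from the as-fabricated rest state (with the 1e-8 w
    second-mode seed) and records whether and when the snap criterion -
    mid-point displacement beyond the straight configuration (> h_mid) with
    |a2| > 1e-6 - was met.

    Raises
    ------
    IntegrationError
        If the undamped energy drifts by more than 1% of the peak kinetic
        energy (suggests a smaller dt).
    """
    sys_ = ModalArch(geom, mat, n_modes)
    nd = sys_.nd
    w1 = sys_.frequencies()[0]
    T1 = 2.0 * np.pi / w1
    dt_nd = dt / nd.time_scale if dt is not None else sys_.default_dt()
    t_end_nd = t_end / nd.time_scale if t_end is not None else 20.0 * T1
    min_period = 2.0 * np.pi / sys_.frequencies()[-1]
    if dt_nd > min_period / 20.0:
        raise IntegrationError(
            f"dt={dt_nd * nd.time_scale:.3e}s does not resolve the highest "
            f"retained mode",
            suggested_dt=sys_.default_dt() * nd.time_scale,
        )

    f_nd = nd.force_nd(f)
    a0 = np.zeros(n_modes)
    a0[1] = _MODE2_SEED
    v0 = np.zeros(n_modes)
    n_steps = max(1, int(np.ceil(t_end_nd / dt_nd)))
    rec_a, rec_v = _run_verlet(a0, v0, sys_, f_nd, dt_nd, n_steps, record_every)

    t_nd = np.arange(rec_a.shape[0]) * (dt_nd * record_every)
    umid = rec_a @ sys_.basis.psi_mid
    elastic = np.array([sys_.potential(a, 0.0) for a in rec_a])
    kin = np.array([sys_.kinetic(v) for v in rec_v])
    load_pot = -f_nd * umid
    total = kin + elastic + load_pot

    # undamped energy conservation check, scaled by the peak kinetic energy
    scale = max(kin.max(), 1e-30)
    drift = (total.max() - total.min()) / scale
    if kin.max() > 1e-20 and drift > 0.01:
        raise IntegrationError(
            f"energy drift {drift:.2%} exceeds 1% on an undamped run",
            suggested_dt=0.5 * dt_nd * nd.time_scale,
        )

    snap_mask = (umid > sys_.Q) & (np.abs(rec_a[:, 1]) > 1e-6)
    snapped = bool(snap_mask.any())
    t_snap = None
    max_inv = None
    if snapped:
        i0 = int(np.argmax(snap_mask))
        t_snap = float(t_nd[i0] * nd.time_scale)
        max_inv = rec_a[i0 + int(np.argmax(umid[i0:]))].copy()

    e_scale = _energy_scale(nd)
    return Trajectory(
        t=t_nd * nd.time_scale,
        weights=rec_a,
        midpoint=umid * nd.length_scale,
        force=np.full(t_nd.shape, float(f)),
        energy=(kin + elastic) * e_scale,
        total_energy=total * e_scale,
        snapped=snapped,
        t_snap=t_snap,
        max_inversion_state=max_inv,
        arch=sys_,
    )


def _snaps(sys_: ModalArch, f_nd: float, t_end_nd: float, dt_nd: float) -> bool:
    """Fast snap test used by the bisection (no recording overhead)."""
    a0 = np.zeros(sys_.n_modes)
    a0[1] = _MODE2_SEED
    v0 = np.zeros(sys_.n_modes)
    n_steps = max(1, int(np.ceil(t_end_nd / dt_nd)))
    rec_a, _ = _run_verlet(a0, v0, sys_, f_nd, dt_nd, n_steps, record_every=4)
    umid = rec_a @ sys_.basis.psi_mid
    return bool(((umid > sys_.Q) & (np.abs(rec_a[:, 1]) > 1e-6)).any())


def oracle_critical_force(
    geom: ArchGeometry,
    mat: Material,
    rel_tol: float = 1e-3,
    n_modes: int = DEFAULT_N_MODES,
    window_periods: float = DEFAULT_WINDOW_PERIODS,
    dt: float | None = None,
) -> float:
    """Dynamic critical step force (N) located by bisection on the amplitude.

    A (no-snap, snap) bracket is first found by geometric stepping inside
    [0, 10 x linear-stiffness x h_mid]; bisection then narrows it until its
    width is below ``rel_tol`` times its midpoint.  Deterministic for fixed
    dt, n_modes and window.

    Raises
    ------
    NoSnapError
        If no snapping amplitude exists below the search ceiling.
    """
    sys_ = ModalArch(geom, mat, n_modes)
    nd = sys_.nd
    T1 = 2.0 * np.pi / sys_.frequencies()[0]
    dt_nd = dt / nd.time_scale if dt is not None else sys_.default_dt()
    t_end_nd = window_periods * T1

    # linear mid-span stiffness (normalized): df/d(umid) at the origin
    k_lin = 0.25 * C1 * (N1**2 + 3.0 * C1 * sys_.Q**2)
    f_ceiling = 10.0 * k_lin * sys_.Q  # 10 x linear-stiffness x h_mid

    f_lo, f_hi = 0.0, None
    f = max(f_ceiling * 1e-3, 1e-6)
    while f <= f_ceiling:
        if _snaps(sys_, f, t_end_nd, dt_nd):
            f_hi = f
            break
        f_lo = f
        f *= 2.0
    if f_hi is None:
        raise NoSnapError(sys_.Q, float("nan"))

    while (f_hi - f_lo) > rel_tol * 0.5 * (f_hi + f_lo):
        f_mid = 0.5 * (f_lo + f_hi)
        if _snaps(sys_, f_mid, t_end_nd, dt_nd):
            f_hi = f_mid
        else:
            f_lo = f_mid
    return 0.5 * (f_lo + f_hi) * nd.force_scale


def release_time(
    geom: ArchGeometry,
    mat: Material,
    n_modes: int = DEFAULT_N_MODES,
    dt: float | None = None,
) -> float:
    """Switchback time (s) from a free-release simulation.

    The arch is initialized at the inverted extreme of the post-snap motion
    (first-mode weight at the largest root of V1(a) = 2 fbar_s a, zero
    velocity, 1e-8 second-mode seed) and integrated unloaded; the returned
    time is the first crossing of zero mid-point displacement, located by
    linear interpolation between samples.

    With ``n_modes=1`` semantics (the smallest allowed is 2, with the second
    mode present only through its seed) this reproduces the closed form of
    :func:`snapsole.dynamics.switchback_time`; larger ``n_modes`` quantify
    the multimode error of the single-mode reduction.

    Raises
    ------
    NotSelfReturningError
        If the mid-point does not cross zero within 50 first-mode periods.
    """
    from .dynamics import inverted_extreme_1mode  # local import, no cycle at module load

    # single-mode release: integrate the reduced scalar equation directly
    if n_modes == 1:
        return _release_time_1mode(geom, mat, dt)

    sys_ = ModalArch(geom, mat, n_modes)
    nd = sys_.nd
    fbar_s = solve_switching_quadratic(nd).fbar_s
    a_start = inverted_extreme_1mode(sys_.Q, fbar_s)

    T1 = 2.0 * np.pi / sys_.frequencies()[0]
    dt_nd = dt / nd.time_scale if dt is not None else sys_.default_dt()
    a0 = np.zeros(n_modes)
    a0[0] = a_start
    a0[1] = _MODE2_SEED
    v0 = np.zeros(n_modes)
    n_steps = int(np.ceil(50.0 * T1 / dt_nd))
    rec_a, _ = _run_verlet(a0, v0, sys_, 0.0, dt_nd, n_steps, record_every=1)
    umid = rec_a @ sys_.basis.psi_mid
    below = np.flatnonzero(umid <= 0.0)
    if below.size == 0:
        raise NotSelfReturningError(
            f"mid-point did not return to the as-fabricated shape within 50 "
            f"periods at Q={sys_.Q:.4g}"
        )
    i = int(below[0])
    u_prev, u_next = umid[i - 1], umid[i]
    frac = u_prev / (u_prev - u_next)
    return ((i - 1) + frac) * dt_nd * nd.time_scale


def _release_time_1mode(geom: ArchGeometry, mat: Material, dt: float | None) -> float:
    """Single-mode release integrated with velocity Verlet on the scalar
    reduced equation m1 addot = -V1'(a)."""
    from ._modal import M1
    from .dynamics import inverted_extreme_1mode

    nd = nondimensionalize(geom, mat)
    Q = nd.Q
    fbar_s = solve_switching_quadratic(nd).fbar_s
    a = inverted_extreme_1mode(Q, fbar_s)

    w1 = np.sqrt((N1**2 * C1 + 3.0 * Q**2 * C1**2) / M1)
    T1 = 2.0 * np.pi / w1
    dt_nd = dt / nd.time_scale if dt is not None else T1 / 2000.0

    def grad(a_):
        s = C1 * (a_ * a_ - Q * a_)
        return N1**2 * C1 * a_ + 3.0 * s * C1 * (2.0 * a_ - Q)

    v = 0.0
    acc = -grad(a) / M1
    t = 0.0
    n_max = int(np.ceil(50.0 * T1 / dt_nd))
    for _ in range(n_max):
        u_prev = 2.0 * a
        v += 0.5 * dt_nd * acc
        a += dt_nd * v
        acc = -grad(a) / M1
        v += 0.5 * dt_nd * acc
        t += dt_nd
        u = 2.0 * a
        if u <= 0.0:
            frac = u_prev / (u_prev - u)
            return (t - dt_nd + frac * dt_nd) * nd.time_scale
    raise NotSelfReturningError(
        f"single-mode release did not cross zero within 50 periods at Q={Q:.4g}"
    )
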