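"""Closed-form switchback time of a released snap-through arch.

After the load disappears, the inverted arch swings back through the
straight configuration.  In the single-mode reduction the free motion of the
first-mode weight a conserves

    1/2 m1 adot^2 + V1(a) = E0,     V1(a) = 1/2 N1^2 c1 a^2 + 3/2 s(a)^2,

with E0 set by the inverted extreme of the post-snap motion.  The turning
points are roots of the quartic E0 - V1(a): two real roots on either side of
the as-fabricated state (a = 0) and one complex-conjugate pair whenever the
energy clears the inter-well barrier; four real roots mean the released arch
stays inverted (not self-returning).

The switchback time - from the inverted extreme to the first crossing of
zero mid-point displacement - reduces to an (incomplete) elliptic integral
of the first kind with modulus assembled from the quartic roots
(Byrd & Friedman 260.00):

    tau = sqrt(m1/2) / sqrt(c4 A B) * [2 K(k) - F(phi0, k)]

where c4 = 3/2 c1^2 is the quartic's leading coefficient,
A^2 = (a_hi - p)^2 + q^2, B^2 = (a_lo - p)^2 + q^2,
k^2 = ((a_hi - a_lo)^2 - (A - B)^2) / (4 A B) and phi0 marks the zero
crossing.  Multimode corrections are quantified against
:func:`snapsole.transient.release_time`.

Sign convention for reported roots: the inverted side is negative, so
``a_start < 0 < a_far``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ellipk, ellipkinc

from ._modal import C1, M1, N1
from .arch_core import ArchGeometry, Material, NondimArch, nondimensionalize
from .errors import NotSelfReturningError, SnapsoleError
from .statics import reduced_potential_1mode, solve_switching_quadratic

__all__ = [
    "SwitchbackSolution",
    "ContourGrids",
    "switchback_quartic_roots",
    "switchback_solution",
    "switchback_time_nd",
    "switchback_time",
    "inverted_extreme_1mode",
    "contour_grids",
]

#: leading coefficient of the switchback quartic (normalized units)
_C4 = 1.5 * C1**2

#: moduli above this are treated as a separatrix approach, not a number
_K2_MAX = 1.0 - 1e-9


@dataclass(frozen=True)
class SwitchbackSolution:
    """Quartic roots, elliptic modulus and switchback time of one arch.

    Roots are reported with the inverted side negative: ``a_start`` is the
    mid-point weight at release (inverted extreme), ``a_far`` the overshoot
    past the as-fabricated shape, and ``p +- i q`` the complex pair.
    """

    tau_nd: float  # normalized switchback time
    t_s: float | None  # dimensional time (s); None if scales unknown
    a_start: float
    a_far: float
    p: float
    q: float
    modulus_k: float  # elliptic modulus k in [0, 1)
    energy: float  # E0, normalized
    quartic_coefficients: tuple  # in the reported (inverted-negative) variable
    Q: float


def inverted_extreme_1mode(Q: float, fbar_s: float) -> float:
    """First-mode weight at the maximum inversion of the post-snap motion.

    Under the sustained step load fbar_s the snapped arch oscillates in the
    inverted pocket with total energy zero; the extreme is the largest root
    of V1(a) = 2 fbar_s a (internal convention: inversion positive).
    """
    # V1(a) - 2 f a as polynomial coefficients (descending powers)
    coeffs = [
        _C4,
        -3.0 * C1**2 * Q,
        1.5 * C1**2 * Q**2 + 0.5 * N1**2 * C1,
        -2.0 * fbar_s,
        0.0,
    ]
    roots = np.roots(coeffs)
    real = roots.real[np.abs(roots.imag) < 1e-9 * np.maximum(1.0, np.abs(roots))]
    if real.size == 0:  # pragma: no cover - cannot happen for fbar_s > 0
        raise SnapsoleError("no inverted extreme found")
    return float(np.max(real))


def _quartic(nd: NondimArch):
    """Roots and energy of the free-oscillation quartic (internal sign)."""
    Q = nd.Q
    fbar_s = solve_switching_quadratic(nd).fbar_s
    a_hi = inverted_extreme_1mode(Q, fbar_s)
    E0 = reduced_potential_1mode(a_hi, Q)
    # P(a) = E0 - V1(a), descending coefficients
    coeffs = np.array(
        [
            -_C4,
            3.0 * C1**2 * Q,
            -(1.5 * C1**2 * Q**2 + 0.5 * N1**2 * C1),
            0.0,
            E0,
        ]
    )
    roots = np.roots(coeffs)
    tol = 1e-7 * np.maximum(1.0, np.abs(roots))
    real = np.sort(roots.real[np.abs(roots.imag) < tol])
    cplx = roots[np.abs(roots.imag) >= tol]
    if real.size != 2:
        raise NotSelfReturningError(
            f"released arch is not self-returning at Q={Q:.4g}: the free "
            f"oscillation energy does not clear the inter-well barrier "
            f"({real.size} real turning points)"
        )
    a_lo, a_hi2 = float(real[0]), float(real[1])
    p = float(cplx[0].real)
    q = float(abs(cplx[0].imag))
    if not (a_lo < 0.0 < a_hi2):
        raise NotSelfReturningError(
            f"turning points {a_lo:.4g}, {a_hi2:.4g} do not straddle the "
            f"as-fabricated state at Q={Q:.4g}"
        )
    return a_lo, a_hi2, p, q, E0, coeffs


def switchback_quartic_roots(nd: NondimArch):
    """Roots (a_start, a_far, p, q) of the switchback quartic.

    Reported with the inverted side negative, so ``a_start < 0 < a_far``.

    Raises
    ------
    NotSelfReturningError
        If the quartic has four real roots (the unloaded arch would remain
        inverted).
    """
    a_lo, a_hi, p, q, _, _ = _quartic(nd)
    return -a_hi, -a_lo, -p, q


def switchback_solution(nd: NondimArch) -> SwitchbackSolution:
    """Full switchback solution: roots, modulus and elliptic-form time."""
    a_lo, a_hi, p, q, E0, coeffs = _quartic(nd)

    A = float(np.hypot(a_hi - p, q))
    B = float(np.hypot(a_lo - p, q))
    k2 = ((a_hi - a_lo) ** 2 - (A - B) ** 2) / (4.0 * A * B)
    if not 0.0 <= k2 < _K2_MAX:
        raise NotSelfReturningError(
            f"elliptic modulus k^2={k2:.12g} at Q={nd.Q:.4g}: separatrix "
            "approach, switchback time diverges"
        )
    # time from the inverted extreme a_hi down to the zero crossing a = 0
    y = 0.0
    cosphi = ((a_hi - y) * B - (y - a_lo) * A) / ((a_hi - y) * B + (y - a_lo) * A)
    phi0 = float(np.arccos(np.clip(cosphi, -1.0, 1.0)))
    # scipy's parameter is m = k^2; near k = 0 ellipkinc reduces smoothly to
    # its small-modulus series, no special-casing needed
    tau = (
        np.sqrt(M1 / 2.0)
        / np.sqrt(_C4 * A * B)
        * (2.0 * ellipk(k2) - ellipkinc(phi0, k2))
    )
    if not (np.isfinite(tau) and tau > 0.0):  # pragma: no cover
        raise SnapsoleError(f"switchback time evaluation failed (tau={tau!r})")

    # coefficients in the reported variable (inverted negative): flip odd powers
    flip = coeffs * np.array([1.0, -1.0, 1.0, -1.0, 1.0])
    return SwitchbackSolution(
        tau_nd=float(tau),
        t_s=None,
        a_start=-a_hi,
        a_far=-a_lo,
        p=-p,
        q=q,
        modulus_k=float(np.sqrt(k2)),
        energy=E0,
        quartic_coefficients=tuple(flip),
        Q=nd.Q,
    )


def switchback_time_nd(nd: NondimArch) -> float:
    """Normalized switchback time (depends on Q only)."""
    return switchback_solution(nd).tau_nd


def switchback_time(geom: ArchGeometry, mat: Material) -> float:
    """Dimensional switchback time (s) of a single arch."""
    nd = nondimensionalize(geom, mat)
    return switchback_time_nd(nd) * nd.time_scale


# ---------------------------------------------------------------------------
# design contours
# ---------------------------------------------------------------------------

@dataclass
class ContourGrids:
    """Normalized switching-force and switchback-time maps for design.

    Axes are the shape parameter Q (rows) and the slenderness L/w (columns).
    ``force`` holds f_s / (E b L) = fbar_s(Q) / (12 (L/w)^4) and ``time``
    holds t_sb sqrt(E/rho) / L = 2 sqrt(3) tau(Q) (L/w); cells outside the
    snap-through / self-returning range are masked, not errors.
    """

    Q_axis: np.ndarray
    slenderness_axis: np.ndarray
    force: np.ma.MaskedArray
    time: np.ma.MaskedArray


def contour_grids(Q_range, slenderness_range=(10.0, 40.0), grid_density: int = 50) -> ContourGrids:
    """Tabulate the two normalized design maps over a (Q, L/w) grid."""
    Q_lo, Q_hi = float(Q_range[0]), float(Q_range[1])
    s_lo, s_hi = float(slenderness_range[0]), float(slenderness_range[1])
    if not (Q_hi > Q_lo and s_hi > s_lo and grid_density >= 2):
        raise ValueError("empty or degenerate contour ranges")
    Q_axis = np.linspace(Q_lo, Q_hi, grid_density)
    s_axis = np.linspace(s_lo, s_hi, grid_density)

    fbar = np.full(grid_density, np.nan)
    tau = np.full(grid_density, np.nan)
    for i, Q in enumerate(Q_axis):
        nd = NondimArch(Q=Q, force_scale=1.0, time_scale=1.0, length_scale=1.0)
        try:
            fbar[i] = solve_switching_quadratic(nd).fbar_s
        except SnapsoleError:
            continue
        try:
            tau[i] = switchback_time_nd(nd)
        except SnapsoleError:
            pass
    # the force map is masked exactly on the no-snap Q set; the time map
    # additionally masks Q where the released arch is not self-returning
    lam = s_axis[None, :]
    force = fbar[:, None] / (12.0 * lam**4)
    time = 2.0 * np.sqrt(3.0) * tau[:, None] * lam
    force_mask = np.broadcast_to(~np.isfinite(fbar)[:, None], force.shape).copy()
    time_mask = np.broadcast_to(~np.isfinite(tau)[:, None], time.shape).copy()
    return ContourGrids(
        Q_axis=Q_axis,
        slenderness_axis=s_axis,
        force=np.ma.MaskedArray(force, mask=force_mask),
        time=np.ma.MaskedArray(time, mask=time_mask),
    )
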