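"""Quasi-static equilibrium path and the dynamic switching force.

Two-mode Galerkin reduction of the shallow fixed-fixed cosine arch loaded by
a mid-span point force.  With deflection from the as-fabricated shape
expanded as u = a1 psi1 + a2 psi2 (psi1 the raised cosine, psi2 the first
antisymmetric mode) and the normalization of :mod:`snapsole.arch_core`, the
reduced potential is

    V(a1, a2; f) = 1/2 N1^2 c1 a1^2 + 1/2 N2^2 c2 a2^2 + 3/2 s^2 - 2 f a1
    s = c1 a1^2 + c2 a2^2 - Q c1 a1            (mid-line stretching scalar)

The asymmetric (second-mode) bifurcation requires s = s* = -N2^2/6.

Dynamic switching force (step load).  A step load of normalized magnitude f
starts the arch from rest with total energy zero.  Snap-through through the
asymmetric route first becomes energetically possible when the saddle of V
on the bifurcated branch reaches energy zero; eliminating a2 (via s = s*)
and f (via equilibrium in a1) turns that condition into a quadratic
polynomial in a1.  Each quadratic root carries a force magnitude and a
second-mode weight A2; one pair has real A2 and the other complex A2, and
the switching force is the force of the real-A2 pair.  This is the minimum
step load at which the inverted state is dynamically reachable; the
transient integrator of :mod:`snapsole.transient` converges to it from
above as its time window grows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from ._modal import C1, N1, N2, S_STAR, modal_basis
from .arch_core import ArchGeometry, Material, NondimArch, nondimensionalize
from .errors import NoSnapError, SnapsoleError

__all__ = [
    "EquilibriumPath",
    "SwitchingSolution",
    "equilibrium_path",
    "solve_switching_quadratic",
    "critical_dynamic_force",
    "snap_threshold_Q",
    "reduced_potential_1mode",
    "reduced_force_1mode",
]

# c2 for the first antisymmetric mode (normalization-dependent; only the
# product c2 * a2^2 is physical)
_C2 = float(modal_basis(2).c[1])


# ---------------------------------------------------------------------------
# single-mode reduced potential (shared with dynamics/transient)
# ---------------------------------------------------------------------------

def reduced_potential_1mode(a, Q: float):
    """Unloaded single-mode potential V1(a) (normalized units).

    ``a`` is the first-mode weight; the mid-span deflection is 2 a.
    """
    a = np.asarray(a, dtype=float)
    s = C1 * (a**2 - Q * a)
    v = 0.5 * N1**2 * C1 * a**2 + 1.5 * s**2
    return v if v.ndim else float(v)


def _potential_1mode_grad(a, Q: float):
    s = C1 * (a**2 - Q * a)
    return N1**2 * C1 * a + 3.0 * s * C1 * (2.0 * a - Q)


def reduced_force_1mode(a1, Q: float):
    """Equilibrium mid-span force with the second mode suppressed (a2 = 0).

    Displacement control: for prescribed a1 the force follows from
    dV/da1 = 2 f, a cubic in a1.
    """
    return 0.5 * _potential_1mode_grad(np.asarray(a1, dtype=float), Q)


def _branch_force(a1, Q: float):
    """Equilibrium force on the bifurcated (a2 != 0) branch, where s = s*.

    Linear in a1 with negative slope (since N1^2 + 6 s* < 0): this is the
    negative-stiffness segment that produces the offloading behaviour.
    """
    return 0.5 * C1 * (N1**2 * np.asarray(a1, dtype=float) + 3.0 * S_STAR * (2.0 * np.asarray(a1, dtype=float) - Q))


# ---------------------------------------------------------------------------
# equilibrium path
# ---------------------------------------------------------------------------

@dataclass
class EquilibriumPath:
    """Sampled force-displacement equilibrium path under displacement control.

    Displacements are mid-span deflections toward the load.  Both the
    normalized samples and their dimensional counterparts (via the arch
    scales) are kept.  ``branch`` is "stable" where the local slope is
    positive and "unstable" where it is negative.
    """

    displacement_nd: np.ndarray  # mid-span deflection / w
    force_nd: np.ndarray
    displacement: np.ndarray  # m
    force: np.ndarray  # N
    slope_sign: np.ndarray  # +1 / -1 / 0 per sample
    branch: list = field(default_factory=list)  # "stable" / "unstable"
    static_limit_force_nd: float = 0.0
    static_limit_force: float = 0.0  # N
    has_negative_stiffness: bool = False


def equilibrium_path(
    nd: NondimArch,
    displacement_grid,
    suppress_mode2: bool = False,
) -> EquilibriumPath:
    """Equilibrium force at prescribed mid-span displacements.

    Parameters
    ----------
    nd : NondimArch
    displacement_grid : array-like
        Monotone increasing normalized mid-span deflections starting at 0.
    suppress_mode2 : bool
        If True the antisymmetric mode is held at zero (the path then follows
        the symmetric cubic everywhere and bounds the free path from above).

    Notes
    -----
    Under displacement control the negative-stiffness branch is traversed
    directly, with no arc-length continuation needed: for each prescribed
    a1 = displacement/2, the energy-minimizing a2 is either 0 or the value
    that pins the stretching scalar at s*.
    """
    grid = np.asarray(displacement_grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2:
        raise ValueError("displacement_grid must be a 1-D array with >= 2 samples")
    if np.any(np.diff(grid) <= 0.0):
        raise ValueError("displacement_grid must be strictly increasing")
    if abs(grid[0]) > 1e-12:
        raise ValueError("displacement_grid must start at 0")

    Q = nd.Q
    a1 = grid / 2.0  # psi1(1/2) = 2
    force = reduced_force_1mode(a1, Q)
    if not suppress_mode2:
        s = C1 * (a1**2 - Q * a1)
        on_branch = s <= S_STAR
        force = np.where(on_branch, _branch_force(a1, Q), force)

    slope = np.gradient(force, grid)
    slope_sign = np.sign(np.round(slope, 12))
    branch = ["stable" if s > 0 else "unstable" for s in slope_sign]

    # static limit = first local maximum of the primary (rising) branch;
    # falls back to the global maximum for monotone paths
    neg = np.flatnonzero(slope_sign < 0)
    if neg.size:
        limit_nd = float(np.max(force[: neg[0] + 1]))
    else:
        limit_nd = float(np.max(force))

    return EquilibriumPath(
        displacement_nd=grid,
        force_nd=force,
        displacement=grid * nd.length_scale,
        force=force * nd.force_scale,
        slope_sign=slope_sign,
        branch=branch,
        static_limit_force_nd=limit_nd,
        static_limit_force=limit_nd * nd.force_scale,
        has_negative_stiffness=bool(neg.size),
    )


# ---------------------------------------------------------------------------
# switching quadratic
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SwitchingSolution:
    """Both root pairs of the switching quadratic and the selected force.

    ``fbar_s`` is the normalized dynamic switching force; ``A2`` the (real)
    second-mode weight of the selected pair at the bifurcation saddle.  The
    rejected pair is kept with its complex A2, together with the quadratic's
    coefficients and discriminant for diagnostics.
    """

    fbar_s: float
    A2: float
    a1: float
    rejected_force: float
    rejected_A2: complex
    quadratic_coeffs: tuple
    discriminant: float
    Q: float


def _quadratic_coeffs(Q: float) -> tuple[float, float, float]:
    """Coefficients (alpha, beta, gamma) of the switching quadratic in a1.

    Obtained by substituting the branch conditions s = s* and the a1
    equilibrium into the zero-energy condition V = 0.  For the clamped-
    clamped basis the middle coefficient cancels identically (beta = 0);
    it is kept in symbolic form so a different basis would flow through.
    """
    alpha = C1 * (-0.5 * N1**2 - 0.5 * N2**2 - 6.0 * S_STAR)
    beta = Q * C1 * (0.5 * N2**2 + 3.0 * S_STAR)
    gamma = S_STAR * (0.5 * N2**2 + 1.5 * S_STAR)
    return alpha, beta, gamma


def solve_switching_quadratic(nd: NondimArch) -> SwitchingSolution:
    """Solve the switching quadratic and select the real-A2 root pair.

    Raises
    ------
    NoSnapError
        If neither root pair has a real second-mode weight together with a
        positive force, i.e. Q is below the asymmetric-bifurcation threshold.
    """
    Q = nd.Q
    alpha, beta, gamma = _quadratic_coeffs(Q)
    disc = beta**2 - 4.0 * alpha * gamma
    if disc < 0.0:
        raise NoSnapError(Q, snap_threshold_Q())
    roots = np.roots([alpha, beta, gamma])

    pairs = []
    for r in np.sort(roots.real):
        f = float(_branch_force(r, Q))
        a2_sq = (S_STAR - C1 * r**2 + Q * C1 * r) / _C2  # = A2^2
        if a2_sq >= 0.0:
            A2 = complex(np.sqrt(a2_sq), 0.0)
        else:
            A2 = complex(0.0, np.sqrt(-a2_sq))
        pairs.append((f, A2, float(r)))

    admissible = [p for p in pairs if p[1].imag == 0.0 and p[0] > 0.0]
    if not admissible:
        raise NoSnapError(Q, snap_threshold_Q())
    # tie-break when both pairs are real: first instability on loading
    f_s, A2, a1 = min(admissible, key=lambda p: p[0])
    rejected = max(pairs, key=lambda p: abs(p[1].imag)) if len(pairs) > 1 else pairs[0]

    return SwitchingSolution(
        fbar_s=f_s,
        A2=A2.real,
        a1=a1,
        rejected_force=rejected[0],
        rejected_A2=rejected[1],
        quadratic_coeffs=(alpha, beta, gamma),
        discriminant=disc,
        Q=Q,
    )


def critical_dynamic_force(geom: ArchGeometry, mat: Material) -> float:
    """Dimensional dynamic switching force f_s (N) of a single arch."""
    nd = nondimensionalize(geom, mat)
    sol = solve_switching_quadratic(nd)
    f = sol.fbar_s * nd.force_scale
    if not f > 0.0:
        raise SnapsoleError("switching force must be positive")
    return f


@lru_cache(maxsize=1)
def snap_threshold_Q(tol: float = 1e-10) -> float:
    """Smallest Q with a real-A2 switching solution, located by bisection.

    Below this threshold the stretching scalar cannot reach s* and no
    asymmetric snap-through exists.
    """

    def has_snap(Q: float) -> bool:
        alpha, beta, gamma = _quadratic_coeffs(Q)
        disc = beta**2 - 4.0 * alpha * gamma
        if disc < 0.0:
            return False
        for r in np.roots([alpha, beta, gamma]).real:
            a2_sq = S_STAR - C1 * r**2 + Q * C1 * r
            if a2_sq >= 0.0 and _branch_force(r, Q) > 0.0:
                return True
        return False

    lo, hi = 0.5, 5.0
    if has_snap(lo) or not has_snap(hi):  # pragma: no cover - sanity guard
        raise SnapsoleError("snap threshold bracketing failed")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if has_snap(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)
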