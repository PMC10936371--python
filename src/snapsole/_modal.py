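"""Clamped-clamped modal basis for the shallow-arch Galerkin reduction.

The arch mid-line is expanded in the buckling eigenfunctions of a straight
clamped-clamped beam, written on the normalized axial coordinate X = x/L:

* symmetric modes      psi(X) = 1 - cos(N X),              N = 2*pi, 4*pi, ...
* antisymmetric modes  psi(X) = 1 - 2X - cos(N X) + 2 sin(N X)/N,
  with N a root of tan(N/2) = N/2  (N ~ 2.86*pi, 4.92*pi, ...).

The as-fabricated raised-cosine shape is exactly (Q/2) times the first
symmetric mode, which is what makes the closed-form switching analysis
tractable: the stretching integral couples modes only through the single
scalar s = sum_j c_j a_j^2 - Q c_1 a_1.

All quantities here are dimensionless.  Displacements are measured in units
of the in-plane width w, the axial coordinate in units of the span L, time in
units of L^2 sqrt(rho A / (E I)) and the mid-span point force in units of
E I w / L^3; with that convention every coefficient below depends only on the
mode shapes, and the reduced equations depend on the geometry only through Q.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

__all__ = [
    "N1",
    "N2",
    "C1",
    "M1",
    "S_STAR",
    "ModalBasis",
    "modal_basis",
    "antisymmetric_wavenumbers",
]

#: wavenumber of the first symmetric clamped-clamped buckling mode
N1 = 2.0 * np.pi
#: c_1 = integral of psi_1'^2 = 2 pi^2 (analytic)
C1 = 2.0 * np.pi**2
#: m_1 = integral of psi_1^2 = 3/2 (analytic)
M1 = 1.5


def antisymmetric_wavenumbers(count: int) -> list[float]:
    """First `count` roots of tan(N/2) = N/2 with N > 2*pi.

    These are the wavenumbers of the antisymmetric clamped-clamped buckling
    modes; the smallest (~8.9868) governs the asymmetric snap-through
    bifurcation.
    """
    roots = []
    k = 1
    while len(roots) < count:
        lo = 2 * k * np.pi + 1e-9
        hi = (2 * k + 1) * np.pi - 1e-9
        roots.append(brentq(lambda N: np.tan(N / 2) - N / 2, lo, hi, xtol=1e-14))
        k += 1
    return roots


#: wavenumber of the first antisymmetric mode (governs the bifurcation)
N2 = antisymmetric_wavenumbers(1)[0]

#: critical stretching scalar at which the first antisymmetric mode goes
#: unstable: d2V/da2^2 = c_2 (N2^2 + 6 s) = 0  =>  s* = -N2^2/6
S_STAR = -(N2**2) / 6.0


@dataclass(frozen=True)
class ModalBasis:
    """Numerical Galerkin data for the first `n_modes` clamped-clamped modes,
    ordered by increasing wavenumber (so mode 1 is the raised cosine and mode
    2 the first antisymmetric shape)."""

    n_modes: int
    wavenumbers: np.ndarray  # N_j
    symmetric: np.ndarray  # bool per mode
    c: np.ndarray  # integral psi_j'^2
    mass: np.ndarray  # integral psi_i psi_j (non-diagonal between symmetric modes)
    mass_inv: np.ndarray
    psi_mid: np.ndarray  # psi_j(1/2); zero for antisymmetric modes

    def shape_functions(self):
        """Return list of (psi, psi') callables on X in [0, 1]."""
        funcs = []
        for N, sym in zip(self.wavenumbers, self.symmetric):
            if sym:
                funcs.append(
                    (
                        lambda X, N=N: 1.0 - np.cos(N * X),
                        lambda X, N=N: N * np.sin(N * X),
                    )
                )
            else:
                funcs.append(
                    (
                        lambda X, N=N: 1.0 - 2.0 * X - np.cos(N * X) + 2.0 * np.sin(N * X) / N,
                        lambda X, N=N: -2.0 + N * np.sin(N * X) + 2.0 * np.cos(N * X),
                    )
                )
        return funcs


@lru_cache(maxsize=8)
def modal_basis(n_modes: int) -> ModalBasis:
    """Build (and cache) the Galerkin integrals for `n_modes` modes."""
    if n_modes < 1:
        raise ValueError("n_modes must be >= 1")
    n_each = n_modes // 2 + 1
    sym = [(2.0 * np.pi * (k + 1), True) for k in range(n_each)]
    anti = [(N, False) for N in antisymmetric_wavenumbers(n_each)]
    modes = sorted(sym + anti)[:n_modes]
    wavenumbers = np.array([N for N, _ in modes])
    symmetric = np.array([s for _, s in modes])

    basis = ModalBasis(
        n_modes=n_modes,
        wavenumbers=wavenumbers,
        symmetric=symmetric,
        c=np.empty(0),
        mass=np.empty(0),
        mass_inv=np.empty(0),
        psi_mid=np.empty(0),
    )
    funcs = basis.shape_functions()

    c = np.array(
        [quad(lambda X, fp=fp: fp(X) ** 2, 0.0, 1.0, limit=400, epsabs=1e-13)[0] for _, fp in funcs]
    )
    mass = np.zeros((n_modes, n_modes))
    for i in range(n_modes):
        for j in range(i + 1):
            if symmetric[i] != symmetric[j]:
                continue  # symmetric x antisymmetric integrates to zero
            val = quad(
                lambda X, fi=funcs[i][0], fj=funcs[j][0]: fi(X) * fj(X),
                0.0,
                1.0,
                limit=400,
                epsabs=1e-13,
            )[0]
            mass[i, j] = mass[j, i] = val
    psi_mid = np.array([f(0.5) for f, _ in funcs])
    # antisymmetric shapes vanish at mid-span exactly; clean up quadrature dust
    psi_mid[~symmetric] = 0.0

    return ModalBasis(
        n_modes=n_modes,
        wavenumbers=wavenumbers,
        symmetric=symmetric,
        c=c,
        mass=mass,
        mass_inv=np.linalg.inv(mass),
        psi_mid=psi_mid,
    )
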