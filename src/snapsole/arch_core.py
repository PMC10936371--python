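"""Arch geometry, material and nondimensionalization.

A self-offloading insole element is a shallow fixed-fixed arch whose
stress-free (as-fabricated) mid-line is the raised cosine

    y0(x) = (h_mid / 2) * (1 - cos(2 pi x / L)),   0 <= x <= L,

with span ``L``, in-plane width (thickness) ``w``, out-of-plane breadth ``b``
and mid-span rise ``h_mid``.  Shallow-arch theory further assumes
``h_mid / L`` small; geometries above 0.2 are rejected and a warning is
issued above 0.1.

The switching and switchback closed forms depend on the geometry only through
the shape parameter ``Q = h_mid / w`` once forces, times and displacements are
expressed in the scales

    force_scale  = E I w / L^3
    time_scale   = L^2 sqrt(rho A / (E I))
    length_scale = w                      (transverse displacements)

with ``A = b w`` and ``I = b w^3 / 12``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigError, GeometryError

__all__ = [
    "ArchGeometry",
    "Material",
    "NondimArch",
    "ArchState",
    "as_fabricated_shape",
    "nondimensionalize",
    "load_config",
    "SHALLOWNESS_LIMIT",
    "SHALLOWNESS_WARN",
]

#: hard validity bound on h_mid / L for shallow-arch theory
SHALLOWNESS_LIMIT = 0.2
#: above this rise-to-span ratio a warning is issued
SHALLOWNESS_WARN = 0.1


class ShallownessWarning(UserWarning):
    """The arch rise-to-span ratio is large enough that the shallow-arch
    asymptotics start to degrade."""


@dataclass(frozen=True)
class ArchGeometry:
    """Fixed-fixed cosine arch geometry, SI units (metres).

    Parameters
    ----------
    L : float
        Span between the clamped ends.
    w : float
        In-plane width (the bending thickness).
    b : float
        Out-of-plane breadth.
    h_mid : float
        Mid-span rise of the as-fabricated shape.
    """

    L: float
    w: float
    b: float
    h_mid: float

    def __post_init__(self):
        for name in ("L", "w", "b", "h_mid"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0.0:
                raise GeometryError(f"{name} must be strictly positive, got {v!r}")
        ratio = self.h_mid / self.L
        if ratio > SHALLOWNESS_LIMIT:
            raise GeometryError(
                f"h_mid/L = {ratio:.3g} exceeds the shallow-arch bound {SHALLOWNESS_LIMIT}"
            )
        if ratio > SHALLOWNESS_WARN + 1e-12:
            warnings.warn(
                f"h_mid/L = {ratio:.3g} > {SHALLOWNESS_WARN}: shallow-arch theory "
                "is asymptotic and accuracy degrades for deep arches",
                ShallownessWarning,
                stacklevel=2,
            )

    @property
    def area(self) -> float:
        """Cross-section area A = b w (m^2)."""
        return self.b * self.w

    @property
    def second_moment(self) -> float:
        """Second moment of area I = b w^3 / 12 (m^4)."""
        return self.b * self.w**3 / 12.0

    @property
    def Q(self) -> float:
        """Shape parameter Q = h_mid / w (rise over in-plane thickness)."""
        return self.h_mid / self.w


@dataclass(frozen=True)
class Material:
    """Linear elastic material, SI units."""

    youngs_modulus: float  # Pa
    density: float  # kg/m^3

    def __post_init__(self):
        if not np.isfinite(self.youngs_modulus) or self.youngs_modulus <= 0:
            raise GeometryError("youngs_modulus must be strictly positive")
        if not np.isfinite(self.density) or self.density <= 0:
            raise GeometryError("density must be strictly positive")


@dataclass(frozen=True)
class NondimArch:
    """Normalized arch description.

    ``Q`` is the shape parameter h_mid/w; the three scales convert normalized
    forces, times and transverse displacements back to SI.  All reduced
    equations (equilibrium path, switching quadratic, switchback quartic)
    are functions of Q alone.
    """

    Q: float
    force_scale: float  # N per unit normalized force, = E I w / L^3
    time_scale: float  # s per unit normalized time, = L^2 sqrt(rho A / (E I))
    length_scale: float  # m per unit normalized displacement, = w

    def __post_init__(self):
        for name in ("Q", "force_scale", "time_scale", "length_scale"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise GeometryError(f"{name} must be strictly positive, got {v!r}")

    # -- round-trip helpers -------------------------------------------------
    def force(self, fbar) -> float:
        """Dimensional force (N) from normalized force."""
        return fbar * self.force_scale

    def force_nd(self, f) -> float:
        """Normalized force from dimensional force (N)."""
        return f / self.force_scale

    def time(self, tau) -> float:
        """Dimensional time (s) from normalized time."""
        return tau * self.time_scale

    def time_nd(self, t) -> float:
        return t / self.time_scale

    def displacement(self, u) -> float:
        """Dimensional transverse displacement (m) from normalized."""
        return u * self.length_scale

    def displacement_nd(self, y) -> float:
        return y / self.length_scale


@dataclass
class ArchState:
    """Instantaneous configuration as modal weights.

    ``weights[j]`` multiplies the j-th clamped-clamped mode of the deflection
    measured from the as-fabricated shape, positive toward the load (i.e.
    flattening).  ``psi_mid`` are the mode values at mid-span and
    ``length_scale`` converts normalized displacement to metres.
    """

    weights: np.ndarray
    psi_mid: np.ndarray
    length_scale: float

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.psi_mid = np.asarray(self.psi_mid, dtype=float)
        if self.weights.size < 2:
            raise GeometryError("ArchState needs at least two modal weights")
        if self.weights.shape != self.psi_mid.shape:
            raise GeometryError("weights and psi_mid must have matching shapes")

    @property
    def midpoint_displacement(self) -> float:
        """Mid-span deflection from the as-fabricated shape (m, toward load)."""
        return float(self.weights @ self.psi_mid) * self.length_scale


def as_fabricated_shape(geom: ArchGeometry, x):
    """Height of the stress-free cosine profile at axial position ``x`` (m).

    Raises
    ------
    GeometryError
        If any ``x`` lies outside [0, L].
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0.0) or np.any(x > geom.L):
        raise GeometryError(f"x must lie in [0, {geom.L}]")
    y = 0.5 * geom.h_mid * (1.0 - np.cos(2.0 * np.pi * x / geom.L))
    return y if y.ndim else float(y)


def nondimensionalize(geom: ArchGeometry, mat: Material) -> NondimArch:
    """Reduce geometry and material to ``(Q, force_scale, time_scale)``.

    The convention (displacements by w, forces by E I w / L^3, time by
    L^2 sqrt(rho A / (E I))) makes the reduced mechanics a function of Q
    alone; changing the convention is a one-line change here.
    """
    E, rho = mat.youngs_modulus, mat.density
    I = geom.second_moment
    A = geom.area
    return NondimArch(
        Q=geom.Q,
        force_scale=E * I * geom.w / geom.L**3,
        time_scale=geom.L**2 * np.sqrt(rho * A / (E * I)),
        length_scale=geom.w,
    )


# ---------------------------------------------------------------------------
# configuration I/O: flat key-value file, lengths in mm, SI internally
# ---------------------------------------------------------------------------

_ARCH_KEYS = {"L_mm", "w_mm", "b_mm", "h_mid_mm", "E_MPa", "rho_kg_m3"}


def load_config(path) -> tuple[ArchGeometry, Material]:
    """Read an arch + material description from a flat YAML key-value file.

    Expected keys: ``L_mm, w_mm, b_mm, h_mid_mm, E_MPa, rho_kg_m3``.
    Lengths are millimetres and the modulus megapascals at the interface;
    everything is converted to SI on load.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: expected a flat key-value mapping")
    missing = _ARCH_KEYS - raw.keys()
    if missing:
        raise ConfigError(f"{path}: missing keys {sorted(missing)}")
    unknown = raw.keys() - _ARCH_KEYS
    if unknown:
        raise ConfigError(f"{path}: unknown keys {sorted(unknown)}")
    try:
        vals = {k: float(raw[k]) for k in _ARCH_KEYS}
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: non-numeric value ({exc})") from exc
    geom = ArchGeometry(
        L=vals["L_mm"] * 1e-3,
        w=vals["w_mm"] * 1e-3,
        b=vals["b_mm"] * 1e-3,
        h_mid=vals["h_mid_mm"] * 1e-3,
    )
    mat = Material(youngs_modulus=vals["E_MPa"] * 1e6, density=vals["rho_kg_m3"])
    return geom, mat
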