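"""Customization of the arch-array insole from a region force table.

Given per-region maximum forces over the gait cycle, the available region
areas and the shortest gait-phase duration, the designer picks for every
anatomical region an arch geometry and a count ``n`` such that

* the array withstands the design load:       n * f_s >= F_design,
* the array snaps before the region exceeds the offloading threshold
  (default 200 kPa):                          n * f_s <= P_thr * A_contact,
* the snapped arches return before the next phase:  t_sb <= min phase time,
* ``n`` arches fit in the region:   n * (b + s) * (L + s) <= A_available,

with ``F_design = min(F_max, P_thr * A_contact)``: beyond the threshold
force the array is meant to snap (that is the offloading function), so the
design load is capped there.  Candidates come from a grid over the search
bounds; among the feasible ones the design with the largest switchback-time
margin wins, tie-broken by the smallest packed footprint (robustness to
gait-speed variation first, compactness second).

The ten regional designs are grouped into the three replaceable insole
parts (forefoot, midfoot, heel) and stamped with a model code such as
``W5060S68`` (weight band 50-60 kg, size band 6-8).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict

import pandas as pd

from .arch_core import ArchGeometry, Material
from .dynamics import switchback_time
from .errors import GeometryError, InfeasibleDesignError, SnapsoleError
from .pedomap import REGION_NAMES, RegionForceTable
from .statics import critical_dynamic_force

__all__ = [
    "SearchBounds",
    "DesignSpec",
    "RegionDesign",
    "InsoleLayout",
    "arch_count",
    "packing_check",
    "design_region",
    "design_insole",
    "model_code",
    "audit_layout",
    "PART_OF_REGION",
]

#: insole part of each anatomical region
PART_OF_REGION = {
    "heel": "heel",
    "midfoot": "midfoot",
    **{name: "forefoot" for name in ("MTH1", "MTH2", "MTH3", "MTH4", "MTH5", "hallux", "toe2", "toes3_5")},
}

#: default material for FDM-printed shore-95A TPU arches.  The elastic
#: modulus of printed TPU spans roughly 25-90 MPa depending on filament and
#: infill; the default uses the stiff end, which a load-bearing insole needs
#: to carry heel-strike forces within the shallow-arch geometry bounds.
DEFAULT_MATERIAL = Material(youngs_modulus=80e6, density=1210.0)


@dataclass(frozen=True)
class SearchBounds:
    """Candidate grids (mm / dimensionless) for the geometry search.

    ``Q`` values stay inside the monostable snap-through band where both
    closed forms are valid (roughly 1.7 < Q < 4 for this arch family; the
    defaults use the well-conditioned core 2.4-3.2).
    """

    L_mm: tuple = (15.0, 20.0, 25.0, 30.0, 35.0)
    w_mm: tuple = (1.0, 1.5, 2.0, 2.5, 3.0)
    b_mm: tuple = (8.0, 10.0, 12.0, 15.0)
    Q: tuple = (2.4, 2.6, 3.0, 3.2)


@dataclass
class DesignSpec:
    """Inputs to the insole customization.

    ``region_max_force`` and areas are indexed by the ten region names;
    ``region_area_mm2`` is the space available for packing arches and
    ``region_contact_area_mm2`` the loaded contact area used for the
    pressure-threshold cap (defaults to the packing area when omitted).
    """

    region_max_force: pd.Series  # N
    region_area_mm2: pd.Series
    min_phase_ms: float
    threshold_kpa: float = 200.0
    region_contact_area_mm2: pd.Series | None = None
    material: Material = DEFAULT_MATERIAL
    bounds: SearchBounds = SearchBounds()
    spacing_mm: float = 1.0
    weight_band: tuple = (50, 60)
    size_band: tuple = (6, 8)

    def __post_init__(self):
        if self.threshold_kpa <= 0:
            raise SnapsoleError("threshold pressure must be positive")
        if self.min_phase_ms <= 0:
            raise SnapsoleError("minimum phase duration must be positive")
        if (self.region_area_mm2 <= 0).any():
            raise SnapsoleError("region areas must be positive")
        if (self.region_max_force < 0).any():
            raise SnapsoleError("region forces must be nonnegative")
        if self.region_contact_area_mm2 is None:
            self.region_contact_area_mm2 = self.region_area_mm2.copy()

    def force_cap(self, region: str) -> float:
        """Threshold force (N) above which the region must offload:
        P_thr (kPa) x contact area (converted to cm^2) x 0.1."""
        area_cm2 = float(self.region_contact_area_mm2[region]) / 100.0
        return self.threshold_kpa * area_cm2 * 0.1


def arch_count(F_region: float, f_s: float) -> int:
    """Number of arches so the array bears ``F_region``: max(1, ceil(F/f_s)).

    At least one arch everywhere, so every region is supported by a capping
    plate even where the measured force is zero.
    """
    if not f_s > 0:
        raise SnapsoleError(f"switching force must be positive, got {f_s!r}")
    if F_region < 0:
        raise SnapsoleError("region force must be nonnegative")
    return max(1, math.ceil(F_region / f_s))


def packing_check(
    geom: ArchGeometry, n: int, region_area_mm2: float, spacing_mm: float = 1.0
) -> tuple[bool, float]:
    """Row-packing test: does ``n`` arches' footprint fit the region?

    Footprint = n x (b + spacing) x (L + spacing), all in mm.
    """
    if n < 1 or region_area_mm2 <= 0 or spacing_mm < 0:
        raise SnapsoleError("packing inputs must be positive")
    footprint = n * (geom.b * 1e3 + spacing_mm) * (geom.L * 1e3 + spacing_mm)
    return footprint <= region_area_mm2, footprint


@dataclass
class RegionDesign:
    """Chosen arch array for one region."""

    region: str
    geometry_mm: dict  # L, w, b, h_mid in mm
    Q: float
    n: int
    f_s: float  # N, per arch
    array_force: float  # N, n * f_s
    switchback_ms: float
    footprint_mm2: float
    feasible_candidates: int
    design_force: float  # N, the F used for sizing
    force_cap: float  # N, threshold-derived cap


def _candidates(bounds: SearchBounds, mat: Material):
    """Enumerate valid candidate geometries with their per-arch properties.

    Cached per (bounds, material) because the candidate set is shared by all
    regions and subjects.
    """
    key = (bounds, mat)
    if key in _candidates._cache:
        return _candidates._cache[key]
    out = []
    with warnings.catch_warnings():
        # the search deliberately explores rises up to the h/L = 0.2 guard
        warnings.simplefilter("ignore")
        for L in bounds.L_mm:
            for w in bounds.w_mm:
                for Q in bounds.Q:
                    h = Q * w
                    if h / L > 0.2:  # shallowness guard
                        continue
                    for b in bounds.b_mm:
                        try:
                            geom = ArchGeometry(L=L * 1e-3, w=w * 1e-3, b=b * 1e-3, h_mid=h * 1e-3)
                            f_s = critical_dynamic_force(geom, mat)
                            t_sb = switchback_time(geom, mat) * 1e3  # ms
                        except SnapsoleError:
                            continue
                        out.append((geom, f_s, t_sb))
    _candidates._cache[key] = out
    return out


_candidates._cache = {}


def design_region(
    F_max: float,
    area_mm2: float,
    phase_ms: float,
    mat: Material = DEFAULT_MATERIAL,
    bounds: SearchBounds = SearchBounds(),
    spacing_mm: float = 1.0,
    force_cap: float | None = None,
    contact_area_mm2: float | None = None,
    region: str = "",
    max_count: int | None = None,
) -> RegionDesign:
    """Choose (geometry, count) for one region by grid search.

    Feasibility requires the force, packing, switchback and (when a cap is
    given) threshold constraints simultaneously; see the module docstring.
    ``max_count`` optionally caps the arch count (used by the part-coherence
    rule of :func:`design_insole`).

    Raises
    ------
    InfeasibleDesignError
        With a report naming the failed constraints of the best candidate.
    """
    cands = _candidates(bounds, mat)
    if not cands:
        raise InfeasibleDesignError("search bounds contain no valid arch geometry")
    F_design = float(F_max) if force_cap is None else min(float(F_max), force_cap)

    feasible = []
    best_violation = None
    for geom, f_s, t_sb in cands:
        n = arch_count(F_design, f_s)
        fits, footprint = packing_check(geom, n, area_mm2, spacing_mm)
        failed = []
        if not fits:
            failed.append("packing")
        if t_sb > phase_ms:
            failed.append("switchback")
        if force_cap is not None and n * f_s > force_cap:
            failed.append("threshold_cap")
        if max_count is not None and n > max_count:
            failed.append("count_cap")
        if not failed:
            margin = phase_ms - t_sb
            feasible.append((margin, footprint, geom, f_s, t_sb, n))
        elif best_violation is None or len(failed) < len(best_violation[0]):
            best_violation = (failed, geom, f_s, t_sb, n, footprint)

    if not feasible:
        failed, geom, f_s, t_sb, n, footprint = best_violation
        report = {
            "region": region,
            "failed_constraints": failed,
            "best_candidate": {
                "L_mm": geom.L * 1e3,
                "w_mm": geom.w * 1e3,
                "b_mm": geom.b * 1e3,
                "h_mid_mm": geom.h_mid * 1e3,
                "f_s_N": f_s,
                "switchback_ms": t_sb,
                "n": n,
                "footprint_mm2": footprint,
            },
        }
        raise InfeasibleDesignError(
            f"region {region or '?'}: no candidate satisfies {failed}", report=report
        )

    # largest switchback margin, then smallest footprint, then deterministic
    # geometry ordering
    feasible.sort(key=lambda c: (-c[0], c[1], c[2].L, c[2].w, c[2].b))
    margin, footprint, geom, f_s, t_sb, n = feasible[0]
    return RegionDesign(
        region=region,
        geometry_mm={
            "L": geom.L * 1e3,
            "w": geom.w * 1e3,
            "b": geom.b * 1e3,
            "h_mid": geom.h_mid * 1e3,
        },
        Q=geom.Q,
        n=n,
        f_s=f_s,
        array_force=n * f_s,
        switchback_ms=t_sb,
        footprint_mm2=footprint,
        feasible_candidates=len(feasible),
        design_force=F_design,
        force_cap=force_cap if force_cap is not None else float("inf"),
    )


@dataclass
class InsoleLayout:
    """The designed artifact: regional arch arrays grouped in three parts."""

    parts: dict  # part name -> {region -> RegionDesign}
    model: str
    infeasible: dict = field(default_factory=dict)  # region -> report

    @property
    def regions(self) -> dict:
        return {r: d for part in self.parts.values() for r, d in part.items()}

    def part_count(self, part: str) -> int:
        return sum(d.n for d in self.parts.get(part, {}).values())

    def to_json(self, path=None) -> str:
        payload = {
            "model": self.model,
            "parts": {
                part: {r: asdict(d) for r, d in sorted(regions.items())}
                for part, regions in sorted(self.parts.items())
            },
            "infeasible": self.infeasible,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def model_code(weight_lo: float, weight_hi: float, size_lo: float, size_hi: float) -> str:
    """Model code string, e.g. (50, 60, 6, 8) -> ``W5060S68``."""
    if weight_lo > weight_hi or size_lo > size_hi:
        raise SnapsoleError("band bounds out of order")
    w_lo, w_hi = int(round(weight_lo)), int(round(weight_hi))
    s_lo, s_hi = int(round(size_lo)), int(round(size_hi))
    return f"W{w_lo:02d}{w_hi:02d}S{s_lo}{s_hi}"


def design_insole(table: RegionForceTable, spec: DesignSpec) -> InsoleLayout:
    """Design all ten regional arrays and assemble the three-part layout.

    Regions are designed independently, except that the midfoot - clinically
    the least load-bearing part - is designed last under a part-coherence
    rule: when the heel's (or forefoot's) maximum force is at least the
    midfoot's, that part must not end up with fewer arches, so the midfoot
    count is capped accordingly.  Infeasible regions are reported in the
    layout instead of aborting the others.
    """
    missing = [r for r in REGION_NAMES if r not in table.forces.index]
    if missing:
        raise SnapsoleError(f"force table misses regions {missing}")
    F = table.max_force
    phase_ms = float(min(spec.min_phase_ms, table.durations_ms.min()))

    designs: dict[str, RegionDesign] = {}
    infeasible: dict[str, dict] = {}
    ordered = [r for r in REGION_NAMES if r != "midfoot"] + ["midfoot"]
    for name in ordered:
        max_count = None
        if name == "midfoot" and designs:
            caps = []
            heel = designs.get("heel")
            if heel is not None and F["heel"] >= F["midfoot"]:
                caps.append(heel.n)
            fore = [designs[r] for r in REGION_NAMES if PART_OF_REGION[r] == "forefoot" and r in designs]
            if fore and F[[r for r in REGION_NAMES if PART_OF_REGION[r] == "forefoot"]].max() >= F["midfoot"]:
                caps.append(sum(d.n for d in fore))
            if caps:
                max_count = min(caps)
        try:
            designs[name] = design_region(
                F_max=float(F[name]),
                area_mm2=float(spec.region_area_mm2[name]),
                phase_ms=phase_ms,
                mat=spec.material,
                bounds=spec.bounds,
                spacing_mm=spec.spacing_mm,
                force_cap=spec.force_cap(name),
                region=name,
                max_count=max_count,
            )
        except InfeasibleDesignError as exc:
            infeasible[name] = exc.report

    parts: dict[str, dict] = {"forefoot": {}, "midfoot": {}, "heel": {}}
    for name, design in designs.items():
        parts[PART_OF_REGION[name]][name] = design

    code = model_code(*spec.weight_band, *spec.size_band)
    return InsoleLayout(parts=parts, model=code, infeasible=infeasible)


def audit_layout(layout: InsoleLayout, spec: DesignSpec, table: RegionForceTable) -> list[str]:
    """Post-hoc audit: recompute every constraint by direct calls.

    Returns a list of violation strings (empty = all good).  The switching
    force and switchback time are recomputed from the stored geometries via
    :func:`snapsole.statics.critical_dynamic_force` and
    :func:`snapsole.dynamics.switchback_time`, not read from the layout.
    """
    violations = []
    phase_ms = float(min(spec.min_phase_ms, table.durations_ms.min()))
    for name, d in layout.regions.items():
        g = d.geometry_mm
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # geometry already vetted
                geom = ArchGeometry(
                    L=g["L"] * 1e-3, w=g["w"] * 1e-3, b=g["b"] * 1e-3, h_mid=g["h_mid"] * 1e-3
                )
            f_s = critical_dynamic_force(geom, spec.material)
            t_sb = switchback_time(geom, spec.material) * 1e3
        except (SnapsoleError, GeometryError) as exc:
            violations.append(f"{name}: stored geometry invalid ({exc})")
            continue
        cap = spec.force_cap(name)
        F_design = min(float(table.max_force[name]), cap)
        if d.n * f_s + 1e-9 < F_design:
            violations.append(f"{name}: array force {d.n * f_s:.3g} N < design load {F_design:.3g} N")
        if d.n * f_s > cap * (1 + 1e-9):
            violations.append(f"{name}: array snaps above the threshold cap")
        if t_sb > phase_ms * (1 + 1e-9):
            violations.append(f"{name}: switchback {t_sb:.3g} ms > phase {phase_ms:.3g} ms")
        fits, _ = packing_check(geom, d.n, float(spec.region_area_mm2[name]), spec.spacing_mm)
        if not fits:
            violations.append(f"{name}: packing does not fit")
        if d.n < 1:
            violations.append(f"{name}: no arches")
    return violations
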