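import numpy as np
import pandas as pd
import pytest

from snapsole import (
    ArchGeometry,
    InfeasibleDesignError,
    SnapsoleError,
    arch_count,
    audit_layout,
    design_insole,
    design_region,
    model_code,
    packing_check,
)
from snapsole.designer import DEFAULT_MATERIAL, DesignSpec, SearchBounds
from snapsole.dynamics import switchback_time
from snapsole.pedomap import REGION_NAMES, RegionForceTable, gait_table
from snapsole.statics import critical_dynamic_force


def make_table(forces: dict, duration_ms: float = 150.0) -> RegionForceTable:
    series = pd.Series({name: float(forces.get(name, 0.0)) for name in REGION_NAMES})
    df = pd.DataFrame({"mid_stance": series})
    return RegionForceTable(forces=df, durations_ms=pd.Series({"mid_stance": duration_ms}))


def make_spec(table, areas=None, phase_ms=150.0, **kwargs) -> DesignSpec:
    if areas is None:
        areas = pd.Series(
            {n: 5000.0 if n in ("heel", "midfoot", "toes3_5") else 1200.0 for n in REGION_NAMES}
        )
    return DesignSpec(
        region_max_force=table.max_force,
        region_area_mm2=areas,
        min_phase_ms=phase_ms,
        **kwargs,
    )


class TestArchCount:
    @pytest.mark.parametrize("F,fs,n", [(300, 50, 6), (301, 50, 7), (0, 50, 1), (49.9, 50, 1)])
    def test_ceiling_with_support_floor(self, F, fs, n):
        assert arch_count(F, fs) == n

    def test_nonpositive_switching_force_rejected(self):
        with pytest.raises(SnapsoleError):
            arch_count(100.0, 0.0)


class TestPacking:
    geom = ArchGeometry(L=20e-3, w=1e-3, b=10e-3, h_mid=2e-3)

    def test_fits_and_does_not_fit(self):
        fits, footprint = packing_check(self.geom, 1, 10_000.0)
        assert fits and footprint == pytest.approx((10 + 1) * (20 + 1))
        fits, _ = packing_check(self.geom, 100, 1000.0)
        assert not fits

    def test_footprint_monotone_in_count(self):
        footprints = [packing_check(self.geom, n, 1e9)[1] for n in range(1, 8)]
        assert np.all(np.diff(footprints) > 0)


class TestModelCode:
    @pytest.mark.parametrize(
        "args,code",
        [((50, 60, 6, 8), "W5060S68"), ((60, 70, 6, 8), "W6070S68"), ((50, 60, 9, 11), "W5060S911")],
    )
    def test_patterns(self, args, code):
        assert model_code(*args) == code

    def test_out_of_order_rejected(self):
        with pytest.raises(SnapsoleError):
            model_code(60, 50, 6, 8)


class TestDesignRegion:
    def test_singleton_bounds_return_that_geometry(self):
        bounds = SearchBounds(L_mm=(25.0,), w_mm=(1.5,), b_mm=(10.0,), Q=(3.0,))
        design = design_region(F_max=100.0, area_mm2=8000.0, phase_ms=150.0, bounds=bounds)
        assert design.geometry_mm == pytest.approx(
            {"L": 25.0, "w": 1.5, "b": 10.0, "h_mid": 4.5}, rel=1e-12
        )
        assert design.n == arch_count(100.0, design.f_s)
        assert design.feasible_candidates == 1

    def test_switchback_constraint_respected(self):
        design = design_region(F_max=150.0, area_mm2=8000.0, phase_ms=40.0)
        assert design.switchback_ms <= 40.0

    def test_returned_design_reverified_by_direct_calls(self):
        """Post-hoc audit: recompute f_s and t_sb from the chosen geometry."""
        design = design_region(F_max=200.0, area_mm2=8000.0, phase_ms=120.0)
        g = design.geometry_mm
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            geom = ArchGeometry(
                L=g["L"] * 1e-3, w=g["w"] * 1e-3, b=g["b"] * 1e-3, h_mid=g["h_mid"] * 1e-3
            )
        assert critical_dynamic_force(geom, DEFAULT_MATERIAL) == pytest.approx(design.f_s, rel=1e-12)
        assert switchback_time(geom, DEFAULT_MATERIAL) * 1e3 == pytest.approx(
            design.switchback_ms, rel=1e-12
        )
        assert design.n * design.f_s >= design.design_force

    def test_infeasible_reports_failed_constraint(self):
        with pytest.raises(InfeasibleDesignError) as err:
            design_region(F_max=5000.0, area_mm2=300.0, phase_ms=150.0)
        report = err.value.report
        assert "packing" in report["failed_constraints"]
        assert report["best_candidate"]["n"] >= 1


class TestDesignInsole:
    def test_end_to_end_synthetic_subject(self, gait42):
        table = gait_table(gait42.frames, gait42.mask)
        areas = pd.Series(
            {n: gait42.mask.region_area_cm2(n) * 100.0 for n in gait42.mask.region_names}
        )
        spec = DesignSpec(region_max_force=table.max_force, region_area_mm2=areas, min_phase_ms=120.0)
        layout = design_insole(table, spec)
        assert not layout.infeasible
        assert set(layout.regions) == set(REGION_NAMES)
        assert audit_layout(layout, spec, table) == []
        # every regional array respects the layout invariants
        for name, d in layout.regions.items():
            assert d.n >= 1
            assert d.n * d.f_s >= d.design_force
            assert d.switchback_ms <= 120.0
            assert d.footprint_mm2 <= areas[name]
        # model code for the 50-60 kg, size 6-8 band
        assert layout.model == "W5060S68"

    def test_heel_and_forefoot_parts_not_outnumbered_by_midfoot(self, gait42):
        table = gait_table(gait42.frames, gait42.mask)
        areas = pd.Series(
            {n: gait42.mask.region_area_cm2(n) * 100.0 for n in gait42.mask.region_names}
        )
        spec = DesignSpec(region_max_force=table.max_force, region_area_mm2=areas, min_phase_ms=120.0)
        layout = design_insole(table, spec)
        F = table.max_force
        if F["heel"] >= F["midfoot"]:
            assert layout.part_count("heel") >= layout.part_count("midfoot")
        fore = [n for n in REGION_NAMES if n not in ("heel", "midfoot")]
        if F[fore].max() >= F["midfoot"]:
            assert layout.part_count("forefoot") >= layout.part_count("midfoot")

    def test_doubling_forces_never_lowers_counts(self):
        base = make_table({"heel": 200.0, "MTH1": 60.0, "midfoot": 30.0})
        doubled = make_table({"heel": 400.0, "MTH1": 120.0, "midfoot": 60.0})
        spec1 = make_spec(base)
        spec2 = make_spec(doubled)
        l1 = design_insole(base, spec1)
        l2 = design_insole(doubled, spec2)
        for name in REGION_NAMES:
            d1, d2 = l1.regions.get(name), l2.regions.get(name)
            if d1 is None or d2 is None:
                continue
            if d1.geometry_mm == d2.geometry_mm:  # fixed geometry: ceiling monotone
                assert d2.n >= d1.n

    def test_all_zero_forces_give_single_arch_everywhere(self):
        table = make_table({})
        layout = design_insole(table, make_spec(table))
        assert not layout.infeasible
        assert all(d.n == 1 for d in layout.regions.values())

    def test_deterministic(self, gait42):
        table = gait_table(gait42.frames, gait42.mask)
        areas = pd.Series(
            {n: gait42.mask.region_area_cm2(n) * 100.0 for n in gait42.mask.region_names}
        )
        spec = DesignSpec(region_max_force=table.max_force, region_area_mm2=areas, min_phase_ms=120.0)
        assert design_insole(table, spec).to_json() == design_insole(table, spec).to_json()

    def test_missing_region_rejected(self):
        table = make_table({})
        table.forces.drop(index=["heel"], inplace=True)
        with pytest.raises(SnapsoleError):
            design_insole(table, make_spec(make_table({})))
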