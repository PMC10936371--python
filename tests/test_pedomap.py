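import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from snapsole import (
    ColorLUT,
    DecodeError,
    PressureFrame,
    RegionMask,
    SnapsoleError,
    classify_arch_index,
    classify_bmi,
    compute_arch_index,
    decode_pressure_image,
    default_lut,
    encode_pressure_frame,
    gait_table,
    region_force,
    sensor_area,
    synth_gait,
)
from snapsole.pedomap import REGION_NAMES, build_region_mask, force_from_pressure


class TestSensorArea:
    def test_worked_value(self):
        """A 0.7 cm sensor cell covers 0.49 cm^2, reported nominally as 0.5."""
        area = sensor_area(0.7)
        assert area.exact == pytest.approx(0.49)
        assert area.nominal == pytest.approx(0.5)

    def test_unit_side(self):
        assert sensor_area(1.0) == (1.0, 1.0)

    def test_degenerate_rejected(self):
        with pytest.raises(SnapsoleError):
            sensor_area(0.0)


class TestColorLUT:
    def test_validators(self):
        with pytest.raises(SnapsoleError):
            ColorLUT(colors=((0, 0, 0), (1, 1, 1)), pressures=(10.0, 5.0))  # not increasing
        with pytest.raises(SnapsoleError):
            ColorLUT(colors=((0, 0, 0), (0, 0, 0)), pressures=(0.0, 10.0))  # duplicate colors
        with pytest.raises(SnapsoleError):
            ColorLUT(colors=((0, 0, 0),), pressures=(-1.0,))  # negative pressure

    def test_json_round_trip(self, tmp_path):
        lut = default_lut()
        path = tmp_path / "legend.json"
        lut.to_json(path)
        assert ColorLUT.from_json(path) == lut


class TestDecode:
    def test_uniform_image_decodes_to_uniform_pressure(self):
        lut = default_lut()
        grid = np.full((6, 4), 140.0)
        frame = PressureFrame(pressures=grid, phase="mid_stance", timestamp_ms=0.0)
        img = encode_pressure_frame(frame, lut)
        dec = decode_pressure_image(img, lut)
        assert np.all(dec.pressures == 140.0)

    def test_encode_decode_round_trip_palette_exact(self, gait42):
        for frame, img in zip(gait42.frames, gait42.images):
            dec = decode_pressure_image(img, gait42.lut, phase=frame.phase)
            assert np.array_equal(dec.pressures, frame.pressures)
            # idempotent: decoding the re-encoded grid changes nothing
            again = decode_pressure_image(encode_pressure_frame(dec, gait42.lut), gait42.lut)
            assert np.array_equal(again.pressures, dec.pressures)

    def test_antialiased_boundary_pixels_resolved_by_majority(self, gait42):
        lut = gait42.lut
        img = np.asarray(encode_pressure_frame(gait42.frames[2], lut)).copy()
        img[::8, ::8] = (1, 2, 3)  # corrupt one pixel per 8x8 cell block
        dec = decode_pressure_image(img, lut)
        assert np.array_equal(dec.pressures, gait42.frames[2].pressures)

    def test_mostly_unknown_colors_raise(self):
        lut = default_lut()
        rgb = np.full((16, 16, 3), 77, dtype=np.uint8)  # off-palette everywhere
        with pytest.raises(DecodeError):
            decode_pressure_image(rgb, lut)


class TestRegionForce:
    def make_frame_mask(self):
        grid = np.zeros((10, 6))
        labels = np.full((10, 6), -1)
        grid[0:4, 0:5] = 100.0
        labels[0:4, 0:5] = REGION_NAMES.index("heel")
        return (
            PressureFrame(pressures=grid, phase="heel_strike", timestamp_ms=0.0),
            RegionMask(labels=labels),
        )

    def test_uniform_region_arithmetic(self):
        """20 cells at 100 kPa, 0.7 cm side: 100 * 0.49 * 20 * 0.1 = 98 N."""
        frame, mask = self.make_frame_mask()
        forces = region_force(frame, mask)
        assert forces["heel"] == pytest.approx(98.0)
        assert forces.drop("heel").sum() == 0.0

    def test_all_zero_frame(self):
        frame, mask = self.make_frame_mask()
        frame.pressures[:] = 0.0
        assert region_force(frame, mask).sum() == 0.0

    def test_dimension_mismatch(self):
        frame, mask = self.make_frame_mask()
        bad = RegionMask(labels=np.full((3, 3), -1))
        with pytest.raises(SnapsoleError):
            region_force(frame, bad)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(seed=st.integers(0, 10_000))
    def test_matches_elementwise_summation(self, seed):
        """Vectorized accumulation equals a brute-force per-cell loop."""
        rng = np.random.default_rng(seed)
        grid = rng.uniform(0.0, 300.0, size=(12, 8))
        labels = rng.integers(-1, 10, size=(12, 8))
        frame = PressureFrame(pressures=grid, phase="mid_stance", timestamp_ms=0.0)
        mask = RegionMask(labels=labels)
        forces = region_force(frame, mask)
        area = sensor_area(frame.sensor_side_cm).exact
        for idx, name in enumerate(REGION_NAMES):
            brute = sum(
                float(force_from_pressure(grid[i, j], area))
                for i in range(12)
                for j in range(8)
                if labels[i, j] == idx
            )
            assert forces[name] == pytest.approx(brute, rel=1e-12, abs=1e-12)

    def test_partition_conservation_and_additivity(self, gait42):
        """Region forces partition the whole-mask force exactly, and are
        additive under unions of disjoint regions."""
        for frame in gait42.frames:
            forces = region_force(frame, gait42.mask)
            area = sensor_area(frame.sensor_side_cm).exact
            whole = force_from_pressure(
                frame.pressures[gait42.mask.labels >= 0], area
            ).sum()
            assert forces.sum() == pytest.approx(whole, rel=1e-12, abs=1e-12)
            union = forces["MTH1"] + forces["MTH2"]
            merged = gait42.mask.region_cells("MTH1") | gait42.mask.region_cells("MTH2")
            direct = force_from_pressure(frame.pressures[merged], area).sum()
            assert union == pytest.approx(direct, rel=1e-12, abs=1e-12)


class TestGaitTable:
    def test_single_phase_sequence(self, gait42):
        table = gait_table(gait42.frames[:1], gait42.mask, end_ms=120.0)
        assert list(table.forces.columns) == ["heel_strike"]
        assert table.durations_ms["heel_strike"] == pytest.approx(120.0)
        assert table.max_force.equals(table.forces["heel_strike"])

    def test_synthetic_truth_recovered(self, gait42):
        table = gait_table(gait42.frames, gait42.mask)
        truth = gait42.truth
        pd.testing.assert_frame_equal(
            table.forces[truth.forces.columns], truth.forces, rtol=1e-12
        )
        pd.testing.assert_series_equal(
            table.max_force, truth.max_force, rtol=1e-12, check_names=False
        )

    def test_non_monotone_timestamps_rejected(self, gait42):
        frames = list(gait42.frames)
        frames[1] = PressureFrame(
            pressures=frames[1].pressures, phase=frames[1].phase, timestamp_ms=-5.0
        )
        with pytest.raises(SnapsoleError):
            gait_table(frames, gait42.mask)

    def test_region_permutation_equivariance(self, gait42):
        order = tuple(reversed(REGION_NAMES))
        permuted = gait42.mask.permuted(order)
        t1 = gait_table(gait42.frames, gait42.mask)
        t2 = gait_table(gait42.frames, permuted)
        pd.testing.assert_frame_equal(t2.forces, t1.forces.reindex(list(order)), rtol=1e-12)

    def test_csv_round_trip(self, gait42, tmp_path):
        table = gait_table(gait42.frames, gait42.mask)
        path = tmp_path / "forces.csv"
        table.to_csv(path)
        back = type(table).from_csv(path)
        np.testing.assert_allclose(back.forces.values, table.forces.values, rtol=1e-5)
        np.testing.assert_allclose(
            back.durations_ms.values, table.durations_ms.values, rtol=1e-6
        )


class TestSynthGait:
    def test_deterministic_for_fixed_seed(self, gait42):
        other = synth_gait(weight_kg=55.0, foot_size_in=6.0, seed=42)
        for f1, f2 in zip(gait42.frames, other.frames):
            assert np.array_equal(f1.pressures, f2.pressures)
        assert gait42.truth.forces.equals(other.truth.forces)
        different = synth_gait(weight_kg=55.0, foot_size_in=6.0, seed=43)
        assert any(
            not np.array_equal(f1.pressures, f2.pressures)
            for f1, f2 in zip(gait42.frames, different.frames)
        )

    def test_mid_stance_supports_body_weight(self, gait42):
        meta = gait42.meta
        total = meta["mid_stance_total_force_N"]
        target = meta["target_total_force_N"]
        assert abs(total - target) / target <= meta["total_force_tol"]

    def test_high_peak_region_exceeds_offloading_threshold(self):
        gait = synth_gait(seed=7, peak_pressures_kpa={"MTH1": 250.0})
        peak = max(g[gait.mask.region_cells("MTH1")].max() for g in gait.truth_grids)
        assert peak > 200.0  # flagged for offloading at the 200 kPa criterion

    def test_heel_loaded_early_forefoot_loaded_late(self, gait42):
        f = gait42.truth.forces
        assert f.loc["heel", "heel_strike"] > f.loc["heel", "toe_off"]
        assert f.loc["MTH1", "heel_off"] > f.loc["MTH1", "heel_strike"]
        assert f.loc["hallux", "toe_off"] > 0.0


class TestClassification:
    @pytest.mark.parametrize(
        "bmi,category",
        [
            (17.0, "underweight"),
            (18.4, "underweight"),
            (18.6, "normal"),
            (24.9, "normal"),
            (25.1, "overweight"),
            (26.0, "overweight"),
            (27.9, "overweight"),
            (28.1, "obese"),
            (30.0, "obese"),
        ],
    )
    def test_bmi_cutoffs(self, bmi, category):
        assert classify_bmi(bmi) == category

    def test_bmi_rejects_nonpositive(self):
        with pytest.raises(SnapsoleError):
            classify_bmi(0.0)

    @pytest.mark.parametrize(
        "ai,category",
        [(0.19, "high"), (0.209, "high"), (0.211, "normal"), (0.279, "normal"), (0.281, "low")],
    )
    def test_arch_index_cutoffs(self, ai, category):
        assert classify_arch_index(ai) == category

    def test_uniform_rectangle_gives_one_third(self):
        """A uniform rectangular toeless footprint has arch index exactly
        1/3 (equal thirds), classified as low arch."""
        grid = np.zeros((40, 10))
        grid[:28, 2:8] = 150.0  # contact only below the toe band (73%)
        fp = np.zeros((40, 10), dtype=bool)
        fp[:40, 2:8] = True  # full-length footprint sets the region bands
        mask = build_region_mask(fp)
        frame = PressureFrame(pressures=grid, phase="mid_stance", timestamp_ms=0.0)
        ai = compute_arch_index(frame, mask)
        assert ai == pytest.approx(1.0 / 3.0, rel=1e-12)
        assert classify_arch_index(ai) == "low"

    def test_zero_midfoot_contact_is_high_arch(self):
        """Heel and forefoot islands with an unloaded midfoot: the middle
        third of the toeless print carries no contact, so the index is 0."""
        fp = np.zeros((40, 10), dtype=bool)
        fp[:40, 2:8] = True
        mask = build_region_mask(fp)
        grid = np.zeros((40, 10))
        grid[0:9, 2:8] = 180.0  # heel island
        grid[22:29, 2:8] = 160.0  # metatarsal island (below the toe band)
        frame = PressureFrame(pressures=grid, phase="mid_stance", timestamp_ms=0.0)
        ai = compute_arch_index(frame, mask)
        assert ai == pytest.approx(0.0, abs=1e-12)
        assert classify_arch_index(ai) == "high"

    def test_zero_contact_rejected(self):
        fp = np.zeros((40, 10), dtype=bool)
        fp[:40, 2:8] = True
        mask = build_region_mask(fp)
        frame = PressureFrame(pressures=np.zeros((40, 10)), phase="mid_stance", timestamp_ms=0.0)
        with pytest.raises(SnapsoleError):
            compute_arch_index(frame, mask)
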