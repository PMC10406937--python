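"""Generator behaviour: determinism, acquisition physics, time-course shape."""

import numpy as np
import pandas as pd
import pytest

from slicemech import (
    GroundTruth,
    TimeCourseSpec,
    TissueMechanics,
    batch_fit_grid,
    segment_slice_area,
    simulate_force_curve,
    simulate_force_grid,
    simulate_slice_images,
    simulate_timecourse,
)
from slicemech.curves import RETRACT
from slicemech.errors import ConfigurationError


class TestForceCurveGenerator:
    def test_setpoint_reached_within_one_sample(self, clean_hertz_curve):
        f_max = clean_hertz_curve.force.max()
        assert f_max >= 700e-12
        # overshoot bounded by one sample of force increase
        assert f_max < 700e-12 * 1.01

    def test_identical_seed_identical_curve(self, probe, soft_tissue):
        truth = GroundTruth(tissue=soft_tissue, noise_sigma=5e-12, seed=42)
        c1 = simulate_force_curve(truth, probe)
        c2 = simulate_force_curve(truth, probe)
        assert np.array_equal(c1.piezo, c2.piezo)
        assert np.array_equal(c1.force, c2.force)

    def test_adhesive_retract_dip(self, clean_adhesive_curve):
        retract = clean_adhesive_curve.force[clean_adhesive_curve.segment == RETRACT]
        assert retract.min() < 0

    def test_unreachable_setpoint_rejected(self, probe):
        truth = GroundTruth(tissue=TissueMechanics(2.0, 0.5), noise_sigma=0.0)
        with pytest.raises(ConfigurationError):
            simulate_force_curve(truth, probe, piezo_range=4e-6)

    def test_metadata_carries_ground_truth(self, clean_hertz_curve):
        meta = clean_hertz_curve.metadata
        assert meta["true_E_Pa"] == 330.0
        assert meta["true_contact_point_m"] == 2.0e-6
        assert meta["seed"] == 0


class TestForceGrid:
    def test_zero_noise_curves_identical(self, probe, soft_tissue):
        truth = GroundTruth(tissue=soft_tissue, noise_sigma=0.0, seed=1)
        curves = simulate_force_grid(truth, probe, n_curves=5)
        for c in curves[1:]:
            assert np.array_equal(c.force, curves[0].force)

    def test_grid_fit_recovers_truth(self, probe, soft_tissue):
        truth = GroundTruth(tissue=soft_tissue, noise_sigma=0.0, seed=2)
        _, summary = batch_fit_grid(simulate_force_grid(truth, probe, n_curves=4))
        assert summary["E_mean_Pa"] == pytest.approx(330.0, rel=0.01)

    def test_single_curve_grid(self, probe, soft_tissue):
        truth = GroundTruth(tissue=soft_tissue, noise_sigma=0.0, seed=3)
        (curve,) = simulate_force_grid(truth, probe, n_curves=1)
        assert curve.metadata["curve_id"] == "r0c0"

    def test_ids_encode_square_grid(self, probe, soft_tissue):
        truth = GroundTruth(tissue=soft_tissue, noise_sigma=0.0, seed=4)
        curves = simulate_force_grid(truth, probe, n_curves=60)
        ids = {c.metadata["curve_id"] for c in curves}
        assert len(ids) == 60
        assert all(c.metadata["grid_row"] < 8 and c.metadata["grid_col"] < 8 for c in curves)


class TestTimecourse:
    def test_zero_variance_identical_animals(self):
        spec = TimeCourseSpec(330.0, 122.0, animal_cv=0.0, condition="300mOsm")
        table = simulate_timecourse(spec, metric="modulus", seed=0)
        pivot = table.pivot(index="time_h", columns="animal_id", values="value")
        assert np.allclose(pivot.to_numpy(), pivot.to_numpy()[:, [0]])

    def test_modulus_reaches_plateau_by_4h(self):
        """Emulating the 300 mOsm course: 330 Pa at 0.5 h down to ~122 Pa."""
        spec = TimeCourseSpec(330.0, 122.0, animal_cv=0.0)
        table = simulate_timecourse(spec, metric="modulus", seed=0)
        end = table[table["time_h"] == 4.0]["value"].mean()
        start = table[table["time_h"] == 0.5]["value"].mean()
        assert start == pytest.approx(330.0)
        assert end == pytest.approx(122.0, rel=0.05)

    def test_within_5pct_of_plateau_at_plateau_time(self):
        spec = TimeCourseSpec(330.0, 122.0, plateau_time_h=2.0, animal_cv=0.0)
        table = simulate_timecourse(spec, metric="modulus", seed=0)
        at_2h = table[table["time_h"] == 2.0]["value"].iloc[0]
        assert abs(at_2h - 122.0) <= 0.05 * 122.0 + 1e-9

    def test_determinism(self):
        spec = TimeCourseSpec(88.0, 91.0, condition="300mOsm")
        t1 = simulate_timecourse(spec, metric="hydration", seed=5)
        t2 = simulate_timecourse(spec, metric="hydration", seed=5)
        pd.testing.assert_frame_equal(t1, t2)

    def test_hydration_stays_below_100(self):
        spec = TimeCourseSpec(88.0, 92.0, animal_cv=0.5)
        table = simulate_timecourse(spec, metric="hydration", seed=11)
        assert (table["value"] < 100.0).all()

    def test_volume_baseline_is_one(self):
        spec = TimeCourseSpec(1.0, 1.3, animal_cv=0.3)
        table = simulate_timecourse(spec, metric="volume", seed=7)
        assert np.allclose(table[table["time_h"] == 0.5]["value"], 1.0)

    def test_default_group_sizes(self):
        spec = TimeCourseSpec(330.0, 122.0)
        assert simulate_timecourse(spec, metric="modulus", seed=0)["animal_id"].nunique() == 6
        assert simulate_timecourse(spec, metric="volume", seed=0)["animal_id"].nunique() == 4

    def test_plateau_outside_window_rejected(self):
        with pytest.raises(ConfigurationError):
            TimeCourseSpec(330.0, 122.0, plateau_time_h=9.0)


class TestSliceImages:
    def test_constant_volume_constant_area(self):
        images, truth = simulate_slice_images(np.ones(4))
        areas = [segment_slice_area(img) for img in images]
        assert len(set(areas)) == 1

    def test_swelling_roundtrip_through_segmentation(self):
        """A 1.3x volume ratio appears as a 1.3^(2/3) planar-area ratio."""
        images, truth = simulate_slice_images(np.array([1.0, 1.3]))
        a0, a1 = (segment_slice_area(img) for img in images)
        assert a1 / a0 == pytest.approx(1.3 ** (2.0 / 3.0), rel=0.01)

    def test_seeded_noise_reproducible(self):
        im1, _ = simulate_slice_images(np.array([1.0, 1.2]), noise_sigma=0.05, seed=3)
        im2, _ = simulate_slice_images(np.array([1.0, 1.2]), noise_sigma=0.05, seed=3)
        assert all(np.array_equal(a, b) for a, b in zip(im1, im2))

    def test_frame_overflow_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_slice_images(np.array([8.0]), initial_axes=(100.0, 100.0))

    def test_truth_table_analytic_areas(self):
        images, truth = simulate_slice_images(np.array([1.0, 1.3]))
        segmented = segment_slice_area(images[1])
        assert segmented == pytest.approx(truth["analytic_area_px2"].iloc[1], rel=0.01)
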