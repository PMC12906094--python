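"""Dose accumulation, planned-to-same-MU, and forecasting."""

import numpy as np
import pytest

import mrdose as m
from mrdose import phantoms as ph
from mrdose.accumulation import (
    AccumulatedDose,
    AnatomyState,
    accumulate,
    calibrate_output,
    forecast,
    plan_segment_doses,
    planned_to_delivered_mu,
    reconstruct_segment,
)
from mrdose.registration import invert_dvf, warp
from mrdose.stream import BeamSegment


@pytest.fixture(scope="module")
def seg(open_aperture=None):
    return BeamSegment(0.0, 1.0, 50.0, m.Aperture.open_field(10.0, 10.0), 0.0)


class TestAnatomyState:
    def test_exactly_one_transform_required(self, film_phantom):
        with pytest.raises(ValueError):
            AnatomyState(0.0)
        with pytest.raises(ValueError):
            AnatomyState(
                0.0,
                translation_mm=(0, 0, 0),
                dvf=ph.roll_dvf(film_phantom.density, (0, 0), 1.0, 20.0),
            )


class TestReconstructSegment:
    def test_identity_state_equals_direct_engine(self, water_phantom,
                                                 clean_model, seg):
        st = AnatomyState(0.0, translation_mm=(0.0, 0.0, 0.0))
        a = reconstruct_segment(water_phantom.density, st, seg, clean_model)
        b = m.compute_segment_dose(water_phantom.density, seg, clean_model)
        assert np.array_equal(a.values, b.values)

    def test_cc_shift_consistency(self, water_phantom, clean_model, seg):
        """Mapped-back dose equals the unshifted profile read at p + t."""
        t = (0.0, 0.0, 12.0)
        st = AnatomyState(0.0, translation_mm=t)
        r = reconstruct_segment(water_phantom.density, st, seg, clean_model)
        r0 = m.compute_segment_dose(water_phantom.density, seg, clean_model)
        g = water_phantom.density
        z = g.axis_coords(2)
        prof = r.values[32, 32, :]
        expected = np.interp(z + 12.0, z, r0.values[32, 32, :])
        sel = prof > 0.2 * prof.max()
        assert np.abs(prof - expected)[sel].max() < 0.01 * prof.max()

    def test_deformable_matches_pullback_oracle(self, film_phantom, clean_model,
                                                seg):
        """Reconstruction through a known DVF equals the direct pull-back
        composition of the current-anatomy dose."""
        motion = ph.roll_dvf(film_phantom.density, (-24.0, 0.0), 6.0, 24.0)
        u = invert_dvf(motion)
        st = AnatomyState(0.0, dvf=u, dvf_inverse=motion)
        rec = reconstruct_segment(film_phantom.density, st, seg, clean_model)
        current = warp(film_phantom.density, u)
        dose_cur = m.compute_segment_dose(current, seg, clean_model)
        oracle = warp(dose_cur, motion)
        sel = oracle.values > 0.2 * oracle.values.max()
        err = np.abs(rec.values - oracle.values)[sel].max()
        assert err < 2e-2 * oracle.values.max()


class TestAccumulate:
    def test_ledger_tracks_mu(self, water_phantom, clean_model, seg):
        acc = AccumulatedDose.zeros(water_phantom.density)
        d = m.compute_segment_dose(water_phantom.density, seg, clean_model)
        acc = accumulate(acc, d, 50.0, state_id=0)
        acc = accumulate(acc, d, 25.0, state_id=1)
        assert acc.delivered_mu == pytest.approx(75.0)
        assert acc.ledger_mu() == pytest.approx(acc.delivered_mu)

    def test_zero_mu_rejected_unless_bookkeeping(self, water_phantom, clean_model,
                                                 seg):
        acc = AccumulatedDose.zeros(water_phantom.density)
        d = water_phantom.density.like(np.zeros(water_phantom.density.shape))
        with pytest.raises(ValueError):
            accumulate(acc, d, 0.0)
        out = accumulate(acc, d, 0.0, allow_zero_mu=True)
        assert out.delivered_mu == 0.0

    def test_grid_mismatch_rejected(self, water_phantom, clean_model):
        acc = AccumulatedDose.zeros(water_phantom.density)
        other = m.Volume(np.zeros((8, 8, 8)), (3, 3, 3))
        with pytest.raises(ValueError):
            accumulate(acc, other, 1.0)

    def test_all_segments_static_equal_plan_dose(self, delta4_phantom,
                                                 clean_model):
        plan = ph.make_plan(5, 7.0, 7.5, seed=6, total_mu=35.0)
        seg_doses = plan_segment_doses(plan, delta4_phantom.density, clean_model)
        acc = AccumulatedDose.zeros(delta4_phantom.density)
        for s, d in zip(plan.segments, seg_doses):
            acc = accumulate(acc, d, s.mu)
        planned = planned_to_delivered_mu(
            plan, delta4_phantom.density, plan.total_mu, clean_model,
            segment_doses=seg_doses,
        )
        assert np.abs(acc.dose.values - planned.values).max() < 1e-9


class TestPlannedToDeliveredMu:
    def test_full_and_zero_mu(self, delta4_phantom, clean_model, small_plan):
        seg_doses = plan_segment_doses(small_plan, delta4_phantom.density,
                                       clean_model)
        full = planned_to_delivered_mu(
            small_plan, delta4_phantom.density, small_plan.total_mu,
            clean_model, segment_doses=seg_doses,
        )
        zero = planned_to_delivered_mu(
            small_plan, delta4_phantom.density, 0.0, clean_model,
            segment_doses=seg_doses,
        )
        assert np.all(zero.values == 0.0)
        assert full.values.max() > 0

    def test_straddled_segment_scales_linearly(self, water_phantom, clean_model):
        ap = m.Aperture.open_field(10.0, 10.0)
        plan = m.TreatmentPlan(
            (m.PlanSegment(ap, 0.0, 100.0), m.PlanSegment(ap, 90.0, 100.0)), 7.5
        )
        seg_doses = plan_segment_doses(plan, water_phantom.density, clean_model)
        got = planned_to_delivered_mu(
            plan, water_phantom.density, 150.0, clean_model,
            segment_doses=seg_doses,
        )
        expected = seg_doses[0].values + 0.5 * seg_doses[1].values
        assert np.abs(got.values - expected).max() < 1e-12

    def test_mu_out_of_range_rejected(self, water_phantom, clean_model,
                                      small_plan):
        with pytest.raises(ValueError):
            planned_to_delivered_mu(
                small_plan, water_phantom.density, small_plan.total_mu + 5.0,
                clean_model,
            )


class TestCalibrateOutput:
    def test_mean_ctv_dose_equals_prescription(self, delta4_phantom):
        plan = ph.make_plan(6, 7.0, 7.5, seed=7, total_mu=60.0)
        model = calibrate_output(
            m.BeamModel(), plan, delta4_phantom.density, delta4_phantom.masks["ctv"]
        )
        total = np.sum(
            [d.values for d in plan_segment_doses(plan, delta4_phantom.density, model)],
            axis=0,
        )
        assert total[delta4_phantom.masks["ctv"]].mean() == pytest.approx(
            7.5, rel=1e-9
        )


@pytest.fixture(scope="module")
def setup(delta4_phantom):
    plan = ph.make_plan(6, 7.0, 7.5, seed=8, total_mu=60.0)
    model = calibrate_output(
        m.BeamModel(noise_rel_sd=0.0), plan, delta4_phantom.density,
        delta4_phantom.masks["ctv"],
    )
    seg_doses = plan_segment_doses(plan, delta4_phantom.density, model)
    return plan, model, seg_doses


class TestForecast:
    def test_at_zero_mu_static_forecast_is_plan(self, delta4_phantom, setup):
        plan, model, seg_doses = setup
        acc = AccumulatedDose.zeros(delta4_phantom.density)
        st = AnatomyState(0.0, translation_mm=(0.0, 0.0, 0.0))
        fc = forecast(acc, plan, st, delta4_phantom.density, model,
                      delta4_phantom.masks["ctv"])
        planned = np.sum([d.values for d in seg_doses], axis=0)
        assert np.abs(fc.dose.values - planned).max() < 1e-9
        assert fc.v95_pct == m.v_threshold(
            delta4_phantom.density.like(planned), delta4_phantom.masks["ctv"], 7.5
        )

    def test_fully_delivered_forecast_is_accumulated(self, delta4_phantom, setup):
        plan, model, seg_doses = setup
        acc = AccumulatedDose.zeros(delta4_phantom.density)
        for s, d in zip(plan.segments, seg_doses):
            acc = accumulate(acc, d, s.mu)
        st = AnatomyState(0.0, translation_mm=(0.0, 0.0, 5.0))
        fc = forecast(acc, plan, st, delta4_phantom.density, model,
                      delta4_phantom.masks["ctv"])
        assert np.array_equal(fc.dose.values, acc.dose.values)

    def test_persistent_drift_lowers_forecast_coverage(self, delta4_phantom,
                                                       setup):
        """A frozen 10 mm CC offset from mid-treatment drops V95 below the
        static forecast."""
        plan, model, seg_doses = setup
        acc = AccumulatedDose.zeros(delta4_phantom.density)
        half = len(plan.segments) // 2
        for s, d in zip(plan.segments[:half], seg_doses[:half]):
            acc = accumulate(acc, d, s.mu)
        ctv = delta4_phantom.masks["ctv"]
        static = forecast(
            acc, plan, AnatomyState(0.0, translation_mm=(0, 0, 0)),
            delta4_phantom.density, model, ctv,
        )
        drifted = forecast(
            acc, plan, AnatomyState(0.0, translation_mm=(0, 0, 10.0)),
            delta4_phantom.density, model, ctv,
        )
        assert drifted.v95_pct < static.v95_pct

    def test_forecast_consistency_at_any_cut(self, delta4_phantom, setup):
        """Delivered-so-far plus remainder equals the plan for identity
        states and no noise, at every cut point."""
        plan, model, seg_doses = setup
        planned = np.sum([d.values for d in seg_doses], axis=0)
        st = AnatomyState(0.0, translation_mm=(0.0, 0.0, 0.0))
        acc = AccumulatedDose.zeros(delta4_phantom.density)
        for s, d in zip(plan.segments[:3], seg_doses[:3]):
            acc = accumulate(acc, d, s.mu)
        fc = forecast(acc, plan, st, delta4_phantom.density, model,
                      delta4_phantom.masks["ctv"])
        assert np.abs(fc.dose.values - planned).max() < 1e-9
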