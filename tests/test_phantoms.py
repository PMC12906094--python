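"""Synthetic phantoms, plans, streams, motion traces and measurements."""

import numpy as np
import pytest

import mrdose as m
from mrdose import phantoms as ph
from mrdose.stream import plan_to_json


class TestBuildPhantom:
    def test_water_cylinder_homogeneous(self):
        p = ph.build_phantom("water_cylinder", air_density=0.0)
        body = p.masks["body"]
        assert np.all(p.density.values[body] == 1.0)
        assert np.all(p.density.values[~body] == 0.0)

    def test_cylinder_exceeding_grid_rejected(self):
        with pytest.raises(ValueError):
            ph.build_phantom("water_cylinder", radius_mm=500.0)

    def test_delta4_diodes_inside_body(self, delta4_phantom):
        p = delta4_phantom
        idx = np.round(p.density.world_to_index(p.diodes.positions_mm)).astype(int)
        assert np.all(p.masks["body"][idx[:, 0], idx[:, 1], idx[:, 2]])
        # two orthogonal planes: every diode lies on x=0 or y=0
        on_planes = (np.abs(p.diodes.positions_mm[:, 0]) < 1e-9) | (
            np.abs(p.diodes.positions_mm[:, 1]) < 1e-9
        )
        assert np.all(on_planes)

    def test_delta4_lattice_spacing(self, delta4_phantom):
        pos = delta4_phantom.diodes.positions_mm
        z = np.unique(pos[:, 2])
        assert np.allclose(np.diff(z), 5.0)

    def test_delta4_ctv_inside_high_dose_core(self, delta4_phantom):
        ctv = delta4_phantom.masks["ctv"]
        assert ctv.sum() > 100
        assert np.all(delta4_phantom.masks["body"][ctv])

    def test_waterbag_film_interface_and_markers(self, film_phantom):
        p = film_phantom
        film = p.film
        # film plane sits at the water/slab interface: water above, slab below
        pts = film.points()
        above = pts + np.array([0.0, 2 * p.density.spacing[1], 0.0])
        below = pts - np.array([0.0, 2 * p.density.spacing[1], 0.0])
        assert np.median(p.density.sample(above)) == pytest.approx(1.0, abs=0.05)
        assert np.median(p.density.sample(below)) == pytest.approx(1.02, abs=0.05)
        # fiducial markers bright in the image channel at the film ends
        assert p.image.values.max() > 1.5

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            ph.build_phantom("banana")


class TestMakePlan:
    def test_single_segment_is_open_10x10(self):
        plan = ph.make_plan(1, 10.0, 7.5, total_mu=150.0)
        seg = plan.segments[0]
        assert seg.gantry_deg == 0.0
        assert seg.aperture.jaws_cm == (-5.0, 5.0, -5.0, 5.0)
        assert plan.total_mu == 150.0

    def test_total_mu_is_sum_of_segments(self):
        plan = ph.make_plan(9, 7.0, 7.5, seed=2, total_mu=117.0)
        assert plan.total_mu == pytest.approx(
            sum(s.mu for s in plan.segments), abs=1e-9
        )
        assert plan.total_mu == pytest.approx(117.0, abs=1e-9)

    def test_same_seed_byte_identical_json(self):
        a = plan_to_json(ph.make_plan(8, 7.0, 7.5, seed=11))
        b = plan_to_json(ph.make_plan(8, 7.0, 7.5, seed=11))
        c = plan_to_json(ph.make_plan(8, 7.0, 7.5, seed=12))
        assert a == b
        assert a != c

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            ph.make_plan(0)
        with pytest.raises(ValueError):
            ph.make_plan(3, field_size_cm=-1.0)


class TestGenStream:
    def test_message_spacing_at_5hz(self, small_plan):
        msgs = ph.gen_stream(small_plan, msg_rate_hz=5.0)
        dt = np.diff([x.t for x in msgs])
        assert np.allclose(dt, 0.2, atol=1e-9)

    def test_final_mu_equals_plan_total(self, small_plan):
        msgs = ph.gen_stream(small_plan)
        assert msgs[-1].mu == pytest.approx(small_plan.total_mu, abs=1e-9)
        assert not msgs[-1].beam_on

    def test_mu_flat_and_beam_off_during_hold(self, small_plan):
        msgs = ph.gen_stream(small_plan, beam_holds=[(1.0, 2.0)])
        for a, b in zip(msgs, msgs[1:]):
            if 1.0 - 1e-9 <= a.t < 2.0 - 1e-9:
                assert not a.beam_on
                assert b.mu == a.mu

    def test_stream_is_valid_and_conserves_mu(self, small_plan):
        msgs = ph.gen_stream(small_plan)
        segs = m.make_segments(msgs)
        assert sum(s.delta_mu for s in segs) == pytest.approx(
            small_plan.total_mu, abs=1e-9
        )

    def test_excessive_dose_rate_rejected(self, small_plan):
        with pytest.raises(ValueError):
            ph.gen_stream(small_plan, dose_rate_mu_per_min=500.0)


class TestGenMotion:
    def test_static_all_zero(self):
        tr = ph.gen_motion("static", 10.0)
        assert np.all(tr.translations() == 0.0)

    def test_linear_drift_reaches_10mm_cc(self):
        tr = ph.gen_motion("linear_drift", 60.0, amplitude_mm=10.0)
        t = tr.translations()
        assert t[-1].tolist() == [0.0, 0.0, 10.0]
        assert np.all(np.diff(t[:, 2]) >= 0)  # monotone CC drift
        assert np.all(t[:, :2] == 0.0)

    def test_patient_like_apex_and_return(self):
        tr = ph.gen_motion("patient_like", 100.0, apex_mm=8.0, return_to_mm=2.0)
        cc = tr.translations()[:, 2]
        assert cc.max() == pytest.approx(8.0, abs=1e-9)
        assert cc[-1] == pytest.approx(2.0, abs=1e-6)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            ph.gen_motion("wobble", 10.0)


class TestRollDvf:
    def test_zero_amplitude_zero_field(self, film_phantom):
        u = ph.roll_dvf(film_phantom.density, (0.0, 0.0), 0.0, 20.0)
        assert np.all(u.disp == 0.0)

    def test_crest_magnitude_equals_amplitude(self, film_phantom):
        g = film_phantom.density
        # voxel-aligned crest inside the taper margin
        cy = float(g.axis_coords(1)[24])
        cz = float(g.axis_coords(2)[32])
        u = ph.roll_dvf(g, (cy, cz), 8.0, 22.0)
        assert u.magnitude().max() == pytest.approx(8.0, abs=1e-6)

    def test_gaussian_tail_below_1pct_beyond_3_widths(self, film_phantom):
        g = film_phantom.density
        width = 20.0
        u = ph.roll_dvf(g, (0.0, 0.0), 10.0, width)
        X, Y, Z = np.meshgrid(
            g.axis_coords(0), g.axis_coords(1), g.axis_coords(2), indexing="ij"
        )
        far = np.sqrt(Y**2 + Z**2) > 3 * width
        assert u.magnitude()[far].max() < 0.01 * 10.0

    def test_smoothness_bound(self, film_phantom):
        """Local finite differences of the field stay below one voxel."""
        u = ph.roll_dvf(film_phantom.density, (-24.0, 0.0), 8.0, 22.0)
        sp = film_phantom.density.spacing
        for a in range(3):
            for ax in range(3):
                d = np.abs(np.diff(u.disp[a], axis=ax))
                assert d.max() < sp[ax]


class TestVirtualMeasurement:
    def test_static_measurement_equals_plan_at_diodes(self, delta4_phantom,
                                                      clean_model):
        plan = ph.make_plan(3, 7.0, 7.5, seed=4, total_mu=21.0)
        msgs = ph.gen_stream(plan)
        trace = ph.gen_motion("static", duration_s=msgs[-1].t + 1)
        _, cum, mu_axis = ph.virtual_measurement_rigid(
            delta4_phantom, msgs, trace, clean_model
        )
        from mrdose.accumulation import plan_segment_doses

        seg_doses = plan_segment_doses(plan, delta4_phantom.density, clean_model)
        planned = np.sum(
            [d.sample(delta4_phantom.diodes.positions_mm) for d in seg_doses],
            axis=0,
        )
        assert np.abs(cum[-1] - planned).max() < 1e-9
        assert mu_axis[-1] == pytest.approx(plan.total_mu, abs=1e-9)

    def test_readout_sample_count_at_40hz(self, delta4_phantom, clean_model):
        plan = ph.make_plan(1, 7.0, 7.5, total_mu=7.0)
        msgs = ph.gen_stream(plan)
        trace = ph.gen_motion("static", duration_s=msgs[-1].t + 1)
        df, _, _ = ph.virtual_measurement_rigid(
            delta4_phantom, msgs, trace, clean_model
        )
        duration = msgs[-1].t - msgs[0].t
        n_per_diode = df.groupby("diode_id").size().unique()
        assert list(n_per_diode) == [int(np.ceil(duration * 40.0))]

    def test_cc_shift_changes_gradient_diode_by_gradient_times_shift(
        self, delta4_phantom, clean_model
    ):
        """A diode on a dose gradient sees gradient x shift, within 10%."""
        plan = ph.make_plan(1, 7.0, 7.5, total_mu=50.0)
        msgs = ph.gen_stream(plan)
        static = ph.gen_motion("static", duration_s=msgs[-1].t + 1)
        _, cum0, _ = ph.virtual_measurement_rigid(
            delta4_phantom, msgs, static, clean_model
        )
        shift = 10.0
        shifted = ph.MotionTrace(
            "constant",
            [
                ph.MotionSample(s.t, (0.0, 0.0, shift))
                for s in static.samples
            ],
        )
        _, cum1, _ = ph.virtual_measurement_rigid(
            delta4_phantom, msgs, shifted, clean_model
        )
        pos = delta4_phantom.diodes.positions_mm
        from mrdose.accumulation import plan_segment_doses

        planned = plan_segment_doses(plan, delta4_phantom.density, clean_model)[0]
        # CC gradient of the planned dose estimated across the shift span:
        # the cylinder is z-uniform, so a +CC anatomy shift reads the
        # planned field at p + shift in the reference frame
        grad = (
            planned.sample(pos + [0, 0, shift]) - planned.sample(pos)
        ) / shift
        j = int(np.argmax(np.abs(grad)))
        predicted = grad[j] * shift
        observed = cum1[-1, j] - cum0[-1, j]
        assert observed == pytest.approx(predicted, rel=0.10)
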