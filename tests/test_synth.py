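"""Synthetic generator: waveforms, rasterisation, corruption, phantoms."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cranioflow.quantify import CM_S_MM2_TO_ML_S
from cranioflow.synth import (
    SYSTOLIC_FRACTION,
    AcquisitionSpec,
    VesselSpec,
    WaveformSpec,
    corrupt,
    make_circle_of_willis_phantom,
    make_straight_vessel,
    rasterize,
    realize_waveform,
    simulate_2d,
    wrap_phase,
)
from cranioflow.studies import vessel_plane


def systolic_pulse_oracle(n_frames: int, mean_flow: float, pi_target: float):
    """Direct evaluation of the sampled systolic-pulse shape (independent of
    the implementation's vectorised path)."""
    d = SYSTOLIC_FRACTION
    q = []
    for k in range(n_frames):
        phi = k / n_frames
        g = np.sin(np.pi * phi / d) ** 2 if phi < d else 0.0
        q.append(mean_flow * (1.0 + 0.5 * pi_target * 2.0 * (g - d / 2.0)))
    q = np.array(q)
    return q, (q.max() - q.min()) / q.mean()


class TestRealizeWaveform:
    def test_zero_pi_is_constant(self):
        r = realize_waveform(WaveformSpec(mean_flow=2.0, pi_target=0.0,
                                          shape="sinusoid", n_frames=8))
        assert np.allclose(r.waveform.flow, 2.0)
        assert r.pi == 0.0

    def test_sinusoid_four_frames_hits_extremes(self):
        r = realize_waveform(WaveformSpec(mean_flow=2.0, pi_target=1.0,
                                          shape="sinusoid", n_frames=4))
        assert np.allclose(r.waveform.flow, [2.0, 3.0, 2.0, 1.0])
        assert r.mean_flow == pytest.approx(2.0)
        assert r.pi == pytest.approx(1.0)

    def test_systolic_pulse_matches_direct_evaluation(self):
        spec = WaveformSpec(mean_flow=3.0, pi_target=0.8, shape="systolic_pulse",
                            n_frames=25)
        r = realize_waveform(spec)
        q_ref, pi_ref = systolic_pulse_oracle(25, 3.0, 0.8)
        np.testing.assert_allclose(r.waveform.flow, q_ref, rtol=1e-12)
        assert r.pi == pytest.approx(pi_ref, rel=1e-12)
        # discrete sampling misses the continuous peak, so realized PI < target
        assert r.pi < 0.8

    def test_negative_flow_rejected(self):
        with pytest.raises(ValueError, match="negative flow"):
            realize_waveform(WaveformSpec(mean_flow=1.0, pi_target=4.5,
                                          shape="sinusoid", n_frames=16))

    @pytest.mark.parametrize("shape", ["sinusoid", "systolic_pulse"])
    def test_realized_pi_converges_to_target(self, shape):
        # frame counts chosen so no sample lands exactly on the extremes
        pis = [realize_waveform(WaveformSpec(mean_flow=2.0, pi_target=0.7,
                                             shape=shape, n_frames=n)).pi
               for n in (5, 23, 1999)]
        errs = [abs(p - 0.7) for p in pis]
        assert errs[2] < errs[1] < errs[0]
        assert errs[2] < 1e-4

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            WaveformSpec(mean_flow=-1.0)
        with pytest.raises(ValueError):
            WaveformSpec(mean_flow=1.0, n_frames=1)
        with pytest.raises(ValueError):
            WaveformSpec(mean_flow=1.0, shape="square")


class TestRasterize:
    def test_poiseuille_peak_velocity_closed_form(self, straight_vessel, clean_volume):
        # peak centerline velocity = 2 Q / (pi R^2), R in cm
        from cranioflow.synth import _vessel_profile

        q = realize_waveform(replace(straight_vessel.waveform, n_frames=25)).waveform.flow
        expected_peak = 2.0 * q.max() / (np.pi * 0.3**2)
        svel, inside = _vessel_profile(np.array([[11.5, 11.5, 5.0]]), straight_vessel)
        assert inside[0]
        assert svel[0, 2] * q.max() == pytest.approx(expected_peak, rel=1e-12)
        # the voxel-averaged peak sits a few percent below the analytic one
        assert clean_volume.vz.max() == pytest.approx(expected_peak, rel=0.10)
        assert clean_volume.vz.max() < expected_peak

    def test_plug_cross_section_conserves_flow(self):
        wf = WaveformSpec(mean_flow=3.0, pi_target=0.5, shape="sinusoid", n_frames=6)
        vessel = make_straight_vessel("plug", (11.5, 11.5), (0.0, 11.0), 3.0, wf,
                                      profile="plug")
        acq = AcquisitionSpec(voxel_size=(1.0, 1.0, 1.0), grid_shape=(24, 24, 12),
                              n_frames=6, supersample=6)
        vol = rasterize([vessel], acq)
        q_ref = realize_waveform(wf).waveform.flow
        # sum of voxel velocities x voxel area over a mid-z cross-section
        flow = vol.vz[:, :, 6, :].sum(axis=(0, 1)) * 1.0 * CM_S_MM2_TO_ML_S
        np.testing.assert_allclose(flow, q_ref, rtol=5e-3)

    def test_quadrature_error_shrinks_with_supersampling(self, straight_vessel):
        errs = []
        q_ref = realize_waveform(replace(straight_vessel.waveform, n_frames=4)
                                 ).waveform.flow
        for ss in (1, 2, 4):
            acq = AcquisitionSpec(voxel_size=(1.0, 1.0, 1.0), grid_shape=(24, 24, 12),
                                  n_frames=4, supersample=ss)
            vol = rasterize([straight_vessel], acq)
            flow = vol.vz[:, :, 6, :].sum(axis=(0, 1)) * CM_S_MM2_TO_ML_S
            errs.append(np.max(np.abs(flow - q_ref) / q_ref))
        assert errs[0] > errs[1] > errs[2]

    def test_empty_vessel_list(self, acq_1mm):
        vol = rasterize([], acq_1mm)
        assert not vol.vx.any() and not vol.vy.any() and not vol.vz.any()
        assert np.allclose(vol.magnitude, 1.0)

    def test_magnitude_two_level_contrast(self, clean_volume):
        assert clean_volume.magnitude.max() == pytest.approx(10.0)
        assert clean_volume.magnitude.min() == pytest.approx(1.0)

    def test_overlapping_vessels_rejected(self, straight_vessel):
        twin = replace(straight_vessel, name="twin")
        acq = AcquisitionSpec(grid_shape=(24, 24, 12))
        with pytest.raises(ValueError, match="overlap"):
            rasterize([straight_vessel, twin], acq)

    def test_vessel_outside_grid_rejected(self, straight_vessel):
        acq = AcquisitionSpec(grid_shape=(8, 8, 4))
        with pytest.raises(ValueError, match="leaves the grid"):
            rasterize([straight_vessel], acq)

    def test_centerline_validation(self):
        wf = WaveformSpec(mean_flow=1.0)
        with pytest.raises(ValueError, match="coincide"):
            VesselSpec("bad", np.array([[0, 0, 0], [0, 0, 0]]), 1.0, wf)
        with pytest.raises(ValueError):
            VesselSpec("bad", np.array([[0, 0, 0]]), 1.0, wf)


class TestCorrupt:
    def test_wrap_examples(self):
        assert wrap_phase(90.0, 80.0) == pytest.approx(-70.0)
        assert wrap_phase(-80.0, 80.0) == pytest.approx(-80.0)
        assert wrap_phase(80.0, 80.0) == pytest.approx(-80.0)  # half-open interval

    @given(st.floats(-500, 500), st.floats(10, 200))
    def test_wrap_idempotent_and_in_range(self, v, venc):
        w = wrap_phase(v, venc)
        assert -venc <= w < venc
        assert wrap_phase(w, venc) == w

    def test_identity_when_nothing_to_corrupt(self, clean_volume, acq_1mm):
        out = corrupt(clean_volume, acq_1mm)
        np.testing.assert_array_equal(out.vz, clean_volume.vz)
        np.testing.assert_array_equal(out.magnitude, clean_volume.magnitude)

    def test_bit_reproducible_given_seed(self, clean_volume, acq_1mm):
        acq = replace(acq_1mm, noise_sigma=5.0, background_poly=(1.0, 0.1, 0.0, -0.05))
        a = corrupt(clean_volume, acq, seed=99)
        b = corrupt(clean_volume, acq, seed=99)
        np.testing.assert_array_equal(a.vx, b.vx)
        np.testing.assert_array_equal(a.magnitude, b.magnitude)
        c = corrupt(clean_volume, acq, seed=100)
        assert not np.array_equal(a.vx, c.vx)

    def test_background_offset_is_linear_in_space(self, clean_volume, acq_1mm):
        acq = replace(acq_1mm, background_poly=(2.0, 0.5, -0.25, 0.1))
        out = corrupt(clean_volume, acq)
        added = out.vx - clean_volume.vx
        # time-constant
        assert np.allclose(added.std(axis=3), 0.0)
        xs, ys, zs = clean_volume.voxel_centers_world()
        expected = (2.0 + 0.5 * xs[:, None, None] + -0.25 * ys[None, :, None]
                    + 0.1 * zs[None, None, :])
        np.testing.assert_allclose(added[..., 0], expected, atol=1e-12)


class TestSimulate2D:
    def test_plug_flow_constant_across_lumen(self, straight_vessel):
        plug = replace(straight_vessel, profile="plug")
        acq2d = AcquisitionSpec(voxel_size=(0.8, 0.8, 3.1), grid_shape=(1, 1, 1),
                                n_frames=32, venc=50.0)
        plane = vessel_plane(straight_vessel, fov=(16.0, 16.0))
        slc = simulate_2d(plug, plane, acq2d)
        # interior pixels (r < R - pixel diagonal) all carry the plug velocity
        pts = slc.plane.pixel_centers()
        r = np.linalg.norm(pts - plane.origin, axis=2)
        interior = r < 3.0 - 1.2
        v0 = slc.v_parallel[interior, 0]
        assert v0.std() < 1e-9 * max(1.0, abs(v0.mean()))

    def test_no_wrap_below_venc(self, straight_vessel):
        acq2d = AcquisitionSpec(voxel_size=(0.8, 0.8, 3.1), grid_shape=(1, 1, 1),
                                n_frames=32, venc=50.0)
        plane = vessel_plane(straight_vessel, fov=(16.0, 16.0))
        slc = simulate_2d(straight_vessel, plane, acq2d)
        # peak velocity ~ 21 cm/s stays below venc: wrapping never triggers
        assert np.abs(slc.v_parallel).max() < 50.0

    def test_missing_plane_warns_and_zero_fills(self, straight_vessel):
        from cranioflow.geometry import FlowPlane

        acq2d = AcquisitionSpec(voxel_size=(0.8, 0.8, 3.1), grid_shape=(1, 1, 1),
                                n_frames=8, venc=50.0)
        far = FlowPlane.from_direction((80.0, 80.0, 5.0), (0, 0, 1), fov=(8, 8))
        with pytest.warns(UserWarning, match="misses"):
            slc = simulate_2d(straight_vessel, far, acq2d)
        assert not slc.v_parallel.any()


class TestCircleOfWillisPhantom:
    def test_per_frame_mass_conservation(self):
        vessels = make_circle_of_willis_phantom(3)
        flows = {v.name: realize_waveform(v.waveform).waveform.flow for v in vessels}
        inflow = sum(flows[n] for n in ("ICA_L", "ICA_R", "BA"))
        outflow = sum(flows[n] for n in
                      ("MCA_L", "MCA_R", "ACA_L", "ACA_R", "PCA_L", "PCA_R"))
        np.testing.assert_allclose(inflow, outflow, atol=1e-12)
        assert inflow.mean() == pytest.approx(7.0, rel=0.01)

    def test_seed_reproducibility(self):
        a = make_circle_of_willis_phantom(11)
        b = make_circle_of_willis_phantom(11)
        for va, vb in zip(a, b):
            np.testing.assert_array_equal(va.centerline, vb.centerline)
        c = make_circle_of_willis_phantom(12)
        assert any(not np.array_equal(va.centerline, vc.centerline)
                   for va, vc in zip(a, c))

    def test_inflow_means_match_design(self):
        vessels = {v.name: v for v in make_circle_of_willis_phantom(0)}
        assert vessels["ICA_L"].waveform.mean_flow == 2.5
        assert vessels["BA"].waveform.mean_flow == 2.0
        total_out = sum(vessels[n].waveform.mean_flow for n in
                        ("MCA_L", "MCA_R", "ACA_L", "ACA_R", "PCA_L", "PCA_R"))
        assert total_out == pytest.approx(7.0)
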