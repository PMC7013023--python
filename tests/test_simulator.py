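"""Rasterization, forward projection, noise and OSEM reconstruction."""

import dataclasses

import numpy as np
import pytest

from spectrc import phantom as ph
from spectrc import simulator as sim
from spectrc.calibration import CalibrationFactor, counts_to_concentration


def small_cylinder(diameter=160.0, height=100.0) -> ph.PhantomDefinition:
    """A short uniform cylinder fully inside the axial detector slab."""
    return ph.PhantomDefinition(cylinder_diameter=diameter, cylinder_height=height,
                                spheres=())


TOY_PROFILE = sim.SystemProfile(
    name="toy", voxel_size=4.8, psf_fwhm=8.0, iterations=5, subsets=16,
    post_filter_fwhm=0.0, sensitivity=10.0, model_psf_fraction=1.0)


def toy_acq(n_proj=64, t=40.0, timestamp=0.0) -> sim.AcquisitionSpec:
    return sim.AcquisitionSpec(n_projections=n_proj, reference_projection_time=t,
                               timestamp_h=timestamp)


class TestRasterize:
    def test_uniform_background_interior_value(self):
        p = small_cylinder()
        fill = ph.ActivityFill(0.0, 80.0)
        grid = sim.ImageGrid(n_xy=40, n_z=16, voxel_size=4.8, center_z=-24.0)
        img = sim.rasterize(p, fill, grid, oversample=1)
        iz, iy, ix = (int(round(i)) for i in grid.world_to_index((0.0, 0.0, -24.0)))
        assert img[iz, iy, ix] == pytest.approx(80.0)

    def test_total_activity_matches_analytic(self):
        p = ph.PhantomDefinition(
            cylinder_diameter=160.0, cylinder_height=90.0,
            spheres=(ph.SphereInsert("a", 30.0, (40.0, 0.0, 0.0)),
                     ph.SphereInsert("b", 50.0, (-40.0, 0.0, 0.0))))
        fill = ph.ActivityFill(500.0, 50.0)
        grid = sim.ImageGrid(n_xy=58, n_z=34, voxel_size=3.0, center_z=0.0)
        img = sim.rasterize(p, fill, grid, oversample=3)
        total = img.sum() * grid.voxel_volume_ml
        v_sph = p.total_sphere_volume_ml
        analytic = (fill.background_concentration * (p.cylinder_volume_l * 1000 - v_sph)
                    + fill.sphere_concentration * v_sph)
        assert total == pytest.approx(analytic, rel=0.005)

    def test_oversampling_reduces_boundary_error(self):
        p = ph.default_phantom()
        grid = sim.ImageGrid(n_xy=49, n_z=28, voxel_size=4.8, center_z=-24.0)
        errs = []
        for os_ in (1, 3):
            num = sim.rasterized_sphere_volume_ml(p, "d60", grid, oversample=os_)
            errs.append(abs(num - ph.sphere_volume(60.0)))
        assert errs[1] < errs[0]

    def test_grid_smaller_than_phantom_rejected(self):
        grid = sim.ImageGrid(n_xy=10, n_z=10, voxel_size=4.8)
        with pytest.raises(ValueError, match="smaller"):
            sim.rasterize(ph.default_phantom(), ph.nominal_fill(), grid)


class TestForwardProject:
    def test_rotational_symmetry_of_uniform_cylinder(self):
        p = small_cylinder()
        fill = ph.ActivityFill(0.0, 80.0)
        grid = sim.truth_grid(voxel=4.0)
        img = sim.rasterize(p, fill, grid, oversample=2)
        sino = sim.forward_project(img, grid, TOY_PROFILE, toy_acq(8),
                                   cylinder_radius_mm=80.0)
        peak = sino.values[0].max()
        for k in range(1, 8):
            # pointwise agreement limited by bilinear-rotation edge error at
            # the cylinder rim; the mean profile agrees to ~0.1% of the peak
            np.testing.assert_allclose(sino.values[k], sino.values[0],
                                       atol=0.02 * peak)
            assert np.abs(sino.values[k] - sino.values[0]).mean() < 2e-3 * peak

    def test_projection_time_linearity(self):
        p = small_cylinder()
        grid = sim.truth_grid(voxel=4.8)
        img = sim.rasterize(p, ph.ActivityFill(0.0, 50.0), grid, oversample=1)
        s1 = sim.forward_project(img, grid, TOY_PROFILE, toy_acq(4, t=40.0),
                                 cylinder_radius_mm=80.0)
        s2 = sim.forward_project(img, grid, TOY_PROFILE, toy_acq(4, t=80.0),
                                 cylinder_radius_mm=80.0)
        np.testing.assert_allclose(s2.values, 2.0 * s1.values, rtol=1e-12)

    def test_central_bin_equals_disk_chord_integral(self):
        """Central-bin line integral of a uniform disk is 2 R c (no blur/attenuation)."""
        R, c = 70.0, 100.0
        p = small_cylinder(diameter=2 * R, height=100.0)
        grid = sim.truth_grid(voxel=2.0)
        img = sim.rasterize(p, ph.ActivityFill(0.0, c), grid, oversample=2)
        prof = dataclasses.replace(TOY_PROFILE, psf_fwhm=0.0, attenuation_mu=0.0)
        acq = toy_acq(1, t=1.0)
        sino = sim.forward_project(img, grid, prof, acq, cylinder_radius_mm=R)
        det = sim.DetectorGeometry()
        central = sino.values[0, det.n_axial // 2, det.n_bins // 2]
        # counts = (sens/1e6) * t * det_bin_x * det_bin_z * line_integral
        scale = prof.sensitivity / 1e6 * 1.0 * det.bin_mm * det.axial_mm
        assert central / scale == pytest.approx(2 * R * c, rel=0.01)

    def test_decay_adjustment_keeps_expected_counts_constant(self):
        p = small_cylinder()
        grid = sim.truth_grid(voxel=4.8)
        img = sim.rasterize(p, ph.ActivityFill(0.0, 50.0), grid, oversample=1)
        s0 = sim.forward_project(img, grid, TOY_PROFILE, toy_acq(4, timestamp=0.0),
                                 cylinder_radius_mm=80.0)
        s1 = sim.forward_project(img, grid, TOY_PROFILE, toy_acq(4, timestamp=50.0),
                                 cylinder_radius_mm=80.0)
        np.testing.assert_allclose(s1.values, s0.values, rtol=1e-12)


class TestNoise:
    def _sino(self, value, shape=(2, 3, 3)):
        det = sim.DetectorGeometry(n_bins=3, n_axial=3)
        return sim.Sinogram(values=np.full(shape, float(value)),
                            angles_deg=np.array([0.0, 180.0]), det=det,
                            acquisition=toy_acq(2))

    def test_zero_sinogram_stays_zero(self):
        noisy = sim.add_noise(self._sino(0.0), seed=7)
        assert not noisy.values.any()

    def test_same_seed_reproducible(self):
        a = sim.add_noise(self._sino(100.0), seed=3)
        b = sim.add_noise(self._sino(100.0), seed=3)
        np.testing.assert_array_equal(a.values, b.values)

    def test_poisson_mean_within_clt_bound(self):
        draws = [sim.add_noise(self._sino(100.0), seed=s).values[0, 0, 0]
                 for s in range(500)]
        assert np.mean(draws) == pytest.approx(100.0, abs=3 * np.sqrt(100.0 / 500))

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            det = sim.DetectorGeometry(n_bins=3, n_axial=3)
            sim.Sinogram(values=-np.ones((2, 3, 3)), angles_deg=np.array([0.0, 180.0]),
                         det=det, acquisition=toy_acq(2))


class TestOsem:
    def test_zero_sinogram_gives_zero_image(self):
        det = sim.DetectorGeometry()
        sino = sim.Sinogram(values=np.zeros((16, det.n_axial, det.n_bins)),
                            angles_deg=np.arange(16) * 22.5, det=det,
                            acquisition=toy_acq(16))
        img = sim.osem_reconstruct(sino, TOY_PROFILE, cylinder_radius_mm=80.0)
        assert not img.voxels.any()

    def test_noiseless_uniform_cylinder_recovers_concentration(self):
        """Model-matched OSEM, 5 it x 16 ss: interior mean within 2% of truth."""
        p = small_cylinder()
        conc = 60.0
        grid = sim.truth_grid(voxel=3.0)
        img = sim.rasterize(p, ph.ActivityFill(0.0, conc), grid, oversample=2)
        sino = sim.forward_project(img, grid, TOY_PROFILE, toy_acq(64),
                                   cylinder_radius_mm=80.0)
        rec = sim.osem_reconstruct(sino, TOY_PROFILE, cylinder_radius_mm=80.0)
        cf = CalibrationFactor(value=TOY_PROFILE.sensitivity / 1000.0)
        a = counts_to_concentration(rec, cf)
        g = rec.grid
        xy = g.xy_coords()
        core = ((xy[:, None] ** 2 + xy[None, :] ** 2) < 40.0**2)
        # interior region clear of the cylinder's axial edge (Gibbs ringing
        # from the resolution-modelled reconstruction lives at the boundary)
        zmask = (g.z_coords() > -20.0) & (g.z_coords() < 40.0)
        mean = a[zmask][:, core].mean()
        assert mean == pytest.approx(conc, rel=0.02)

    def test_more_iterations_increase_small_sphere_recovery(self):
        """Recovered mean of the 15.4 mm sphere grows from 1 to 5 iterations."""
        p = ph.default_phantom()
        fill = ph.nominal_fill()
        grid = sim.truth_grid(voxel=3.0)
        truth = sim.rasterize(p, fill, grid, oversample=2)
        prof = dataclasses.replace(TOY_PROFILE, psf_fwhm=11.9)
        sino = sim.forward_project(truth, grid, prof, toy_acq(64))
        sphere = p.sphere("d15.4")
        means = []
        for it in (1, 5):
            rec = sim.osem_reconstruct(sino, dataclasses.replace(prof, iterations=it))
            cf = CalibrationFactor(value=prof.sensitivity / 1000.0)
            a = counts_to_concentration(rec, cf)
            g = rec.grid
            xy, zs = g.xy_coords(), g.z_coords()
            cx, cy, cz = sphere.center
            d2 = ((xy[None, None, :] - cx) ** 2 + (xy[None, :, None] - cy) ** 2
                  + (zs[:, None, None] - cz) ** 2)
            means.append(a[d2 <= sphere.radius**2].mean())
        assert means[1] > means[0]

    def test_count_consistency_of_converged_reconstruction(self):
        """Reprojection of the converged noiseless recon matches the sinogram <= 1%."""
        p = small_cylinder()
        grid = sim.truth_grid(voxel=3.0)
        img = sim.rasterize(p, ph.ActivityFill(0.0, 60.0), grid, oversample=2)
        prof = dataclasses.replace(TOY_PROFILE, iterations=15, subsets=8)
        sino = sim.forward_project(img, grid, prof, toy_acq(64),
                                   cylinder_radius_mm=80.0)
        rec = sim.osem_reconstruct(sino, prof, cylinder_radius_mm=80.0)
        cf_scale = (rec.projection_time_s * rec.acquisition.n_projections
                    * rec.grid.voxel_volume_ml * prof.sensitivity / 1000.0)
        activity = rec.voxels / cf_scale
        reproj = sim.forward_project(activity, rec.grid, prof, toy_acq(64),
                                     cylinder_radius_mm=80.0)
        assert reproj.values.sum() == pytest.approx(sino.values.sum(), rel=0.01)

    def test_gibbs_overshoot_and_post_filter(self):
        """PSF-modelled OSEM overshoots at the 60 mm sphere edge; a 5 mm
        Gaussian post-filter reduces the overshoot."""
        p = ph.default_phantom()
        fill = ph.nominal_fill()
        grid = sim.truth_grid(voxel=3.0)
        truth = sim.rasterize(p, fill, grid, oversample=2)
        prof = dataclasses.replace(TOY_PROFILE, psf_fwhm=11.9, iterations=8, subsets=8)
        sino = sim.forward_project(truth, grid, prof, toy_acq(64))
        maxima = {}
        for filt in (0.0, 5.0):
            rec = sim.osem_reconstruct(
                sino, dataclasses.replace(prof, post_filter_fwhm=filt))
            cf = CalibrationFactor(value=prof.sensitivity / 1000.0)
            a = counts_to_concentration(rec, cf)
            g = rec.grid
            xy, zs = g.xy_coords(), g.z_coords()
            cx, cy, cz = p.sphere("d60").center
            d2 = ((xy[None, None, :] - cx) ** 2 + (xy[None, :, None] - cy) ** 2
                  + (zs[:, None, None] - cz) ** 2)
            maxima[filt] = a[d2 <= p.sphere("d60").radius**2].max()
        assert maxima[0.0] > fill.sphere_concentration  # edge overshoot
        assert maxima[5.0] < maxima[0.0]  # smoothing damps it


class TestExperiment:
    def test_cardinality_and_determinism(self):
        p = ph.default_phantom()
        fill = ph.nominal_fill()
        profiles = (sim.T16_SYSTEM1, sim.T16_SYSTEM2)
        kwargs = dict(n_repeats=3, master_seed=42, truth_voxel=4.8,
                      acquisition=sim.AcquisitionSpec(n_projections=16),
                      modes=("vendor_specific", "vendor_neutral"))
        imgs1 = sim.simulate_experiment(p, fill, profiles, **kwargs)
        assert len(imgs1) == 2 * 3 * 2
        imgs2 = sim.simulate_experiment(p, fill, profiles, **kwargs)
        for a, b in zip(imgs1, imgs2):
            np.testing.assert_array_equal(a.voxels, b.voxels)

    def test_repeat_seeds_differ(self):
        assert sim.derive_seed(1, "sys", 0) != sim.derive_seed(1, "sys", 1)
        assert sim.derive_seed(1, "a", 0) != sim.derive_seed(1, "b", 0)
        assert 0 <= sim.derive_seed(2**20, "sys", 2) < 2**31

    def test_rc_ordering_noiseless(self, noiseless_run):
        """RC_mean is non-decreasing with diameter for the five smallest
        spheres on noiseless data, for every preset profile and mode
        (up to a 0.005 tolerance for discrete-voxel mask effects)."""
        df = noiseless_run.per_sphere
        for (system, mode), sub in df.groupby(["system", "recon_mode"]):
            sub = sub[sub["diameter_mm"] < 60.0].sort_values("diameter_mm")
            rc = sub["rc_mean"].to_numpy()
            assert np.all(np.diff(rc) >= -0.005), (system, mode, rc)


class TestCalibrationPhantomSimulation:
    def test_noiseless_uniformity_and_determinism(self):
        img, conc = sim.simulate_calibration_phantom(
            profile=dataclasses.replace(sim.T16_SYSTEM2, model_psf_fraction=1.0),
            seed=None, truth_voxel=3.0)
        cf = CalibrationFactor(value=sim.T16_SYSTEM2.sensitivity / 1000.0)
        a = counts_to_concentration(img, cf)
        g = img.grid
        xy = g.xy_coords()
        core = (xy[:, None] ** 2 + xy[None, :] ** 2) < 50.0**2
        zmask = np.abs(g.z_coords() + 24.0) < 40.0
        vals = a[zmask][:, core]
        assert vals.std() / vals.mean() < 0.02
        img2, _ = sim.simulate_calibration_phantom(
            profile=sim.T16_SYSTEM2, seed=5, truth_voxel=4.8)
        img3, _ = sim.simulate_calibration_phantom(
            profile=sim.T16_SYSTEM2, seed=5, truth_voxel=4.8)
        np.testing.assert_array_equal(img2.voxels, img3.voxels)


class TestNiftiRoundTrip:
    def test_lossless_save_load(self, tmp_path):
        p = small_cylinder()
        grid = sim.truth_grid(voxel=4.8)
        act = sim.rasterize(p, ph.ActivityFill(0.0, 50.0), grid, oversample=1)
        sino = sim.forward_project(act, grid, TOY_PROFILE, toy_acq(16),
                                   cylinder_radius_mm=80.0)
        rec = sim.osem_reconstruct(sino, TOY_PROFILE, cylinder_radius_mm=80.0)
        rec.repeat_index = 2
        rec.mode = "vendor_neutral"
        path = str(tmp_path / "img.nii")
        sim.save_recon(rec, path)
        back = sim.load_recon(path)
        np.testing.assert_array_equal(back.voxels, rec.voxels)
        assert back.grid == rec.grid
        assert back.system == rec.system
        assert back.repeat_index == 2
        assert back.mode == "vendor_neutral"
        assert back.projection_time_s == pytest.approx(rec.projection_time_s)

    def test_sinogram_round_trip(self, tmp_path):
        p = small_cylinder()
        grid = sim.truth_grid(voxel=4.8)
        act = sim.rasterize(p, ph.ActivityFill(0.0, 50.0), grid, oversample=1)
        sino = sim.add_noise(
            sim.forward_project(act, grid, TOY_PROFILE, toy_acq(16),
                                cylinder_radius_mm=80.0), seed=4)
        path = str(tmp_path / "sino.nii")
        sim.save_sinogram(sino, path)
        back = sim.load_sinogram(path)
        np.testing.assert_array_equal(back.values, sino.values)
        np.testing.assert_array_equal(back.angles_deg, sino.angles_deg)
        assert back.det == sino.det
        assert back.noisy

    def test_header_sidecar_mismatch_rejected(self, tmp_path):
        import json
        p = small_cylinder()
        grid = sim.truth_grid(voxel=4.8)
        act = sim.rasterize(p, ph.ActivityFill(0.0, 50.0), grid, oversample=1)
        sino = sim.forward_project(act, grid, TOY_PROFILE, toy_acq(16),
                                   cylinder_radius_mm=80.0)
        rec = sim.osem_reconstruct(sino, TOY_PROFILE, cylinder_radius_mm=80.0)
        path = str(tmp_path / "img.nii")
        sim.save_recon(rec, path)
        sc_path = path[:-4] + ".json"
        sc = json.load(open(sc_path))
        sc["voxel_size_mm"] = 2.0
        json.dump(sc, open(sc_path, "w"))
        with pytest.raises(ValueError, match="voxel size mismatch"):
            sim.load_recon(path)
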