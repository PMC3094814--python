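"""OSEM reconstruction, uniform/nonuniform AC, smoothing, Chang factor."""

import numpy as np
import pytest

import striatospect as ss
from striatospect.projector import SpectOperator
from striatospect.recon import (chang_first_order_factor, ellipse_mu_map,
                                gaussian_smooth, osem_reconstruct)


def _noiseless(phantom, geometry, psf, mu=True):
    return ss.forward_project(phantom.activity,
                              phantom.mu_map if mu else None,
                              geometry, psf, phantom.grid.voxel_size_mm)


# ---------------------------------------------------------------- ellipse AC

def test_ellipse_fit_recovers_circle_with_dilation():
    """Circular support of radius 80 mm dilated by 11.8 mm -> semi-axes
    91.8 mm within one voxel."""
    vox = 5.9
    n = 64
    x, y = np.meshgrid(np.arange(n) - (n - 1) / 2, np.arange(n) - (n - 1) / 2,
                       indexing="ij")
    support = ((x**2 + y**2) <= (80.0 / vox) ** 2)[:, :, None]
    mu = ellipse_mu_map(support, vox, mu_uniform=0.11, scalp_dilation_mm=11.8)
    area_mm2 = mu[:, :, 0].astype(bool).sum() * vox**2
    radius = np.sqrt(area_mm2 / np.pi)
    assert radius == pytest.approx(91.8, abs=vox)
    assert set(np.unique(mu)) <= {0.0, 0.11}


def test_ellipse_fit_recovers_anisotropic_mask():
    vox = 5.9
    n = 64
    x, y = np.meshgrid(np.arange(n) - (n - 1) / 2, np.arange(n) - (n - 1) / 2,
                       indexing="ij")
    a, b = 84.0 / vox, 48.0 / vox
    support = (((x / a) ** 2 + (y / b) ** 2) <= 1.0)[:, :, None]
    mu = ellipse_mu_map(support, vox, mu_uniform=0.15, scalp_dilation_mm=0.0)
    got = mu[:, :, 0].astype(bool)
    # recovered region reproduces the mask itself within a one-voxel rim
    sym_diff = np.logical_xor(got, support[:, :, 0]).sum()
    rim = support[:, :, 0].sum() - np.count_nonzero(
        ((x / (a - 1)) ** 2 + (y / (b - 1)) ** 2) <= 1.0)
    assert sym_diff <= max(2 * rim, 8)


def test_empty_support_rejected():
    with pytest.raises(ValueError):
        ellipse_mu_map(np.zeros((16, 16, 4), dtype=bool), 5.9)


# ---------------------------------------------------------------------- OSEM

def test_em_fixed_point_on_matched_noiseless_data(small_phantom, small_geometry):
    """Noiseless data from model M, reconstructed with M starting at the
    truth, stays at the truth (EM fixed point)."""
    psf = ss.PsfModel.method1()
    sino = _noiseless(small_phantom, small_geometry, psf)
    spec = ss.ReconSpec(ac_mode="ct", psf_correction=psf)
    recon = osem_reconstruct(sino, spec, mu_map=small_phantom.mu_map,
                             initial=small_phantom.activity)
    truth = small_phantom.activity
    pos = truth > 0
    rel = np.abs(recon.values[pos] - truth[pos]) / truth[pos]
    assert rel.max() < 1e-6


def test_noiseless_recovery_of_disk_mean():
    """Unattenuated, unblurred disk reconstructs to within 2% of truth in a
    central VOI after the standard 30x10 schedule."""
    shape, vox = (32, 32, 16), 5.9
    x, y, z = np.meshgrid(*(np.arange(s) - (s - 1) / 2 for s in shape),
                          indexing="ij")
    act = np.where((x**2 + y**2) * vox**2 <= 70.0**2, 1.0, 0.0)
    act[:, :, :2] = act[:, :, -2:] = 0.0
    geom = ss.AcquisitionGeometry(orbit_radius_mm=120.0)
    sino = ss.forward_project(act, None, geom, ss.PsfModel.none(), vox)
    spec = ss.ReconSpec(ac_mode="none", psf_correction=ss.PsfModel.none())
    recon = osem_reconstruct(sino, spec)
    central = ((x**2 + y**2) * vox**2 <= 30.0**2) & (np.abs(z) <= 3)
    assert recon.values[central].mean() == pytest.approx(1.0, rel=0.02)


def test_count_consistency_at_convergence(small_phantom, small_geometry):
    psf = ss.PsfModel.none()
    sino = _noiseless(small_phantom, small_geometry, psf)
    spec = ss.ReconSpec(ac_mode="ct", psf_correction=psf)
    recon = osem_reconstruct(sino, spec, mu_map=small_phantom.mu_map)
    op = SpectOperator(recon.values.shape, 5.9, small_geometry, psf,
                       small_phantom.mu_map)
    assert op.forward(recon.values).sum() == pytest.approx(sino.counts.sum(),
                                                           rel=5e-3)


def test_full_em_log_likelihood_non_decreasing(small_phantom):
    """With a single subset (plain MLEM) the Poisson log-likelihood is
    non-decreasing over iterations."""
    geom = ss.AcquisitionGeometry(n_views=24, angular_step_deg=15.0,
                                  orbit_radius_mm=120.0)
    sino = _noiseless(small_phantom, geom, ss.PsfModel.none())
    noisy = ss.add_counting_noise(sino, 2e5, rng_seed=11)
    y = noisy.counts
    op = SpectOperator(small_phantom.activity.shape, 5.9, geom,
                       ss.PsfModel.none(), small_phantom.mu_map)

    def loglike(vol):
        p = op.forward(vol)
        mask = p > 0
        return float(np.sum(y[mask] * np.log(p[mask]) - p[mask]))

    lls = []
    for n_iter in (1, 2, 4, 8):
        spec = ss.ReconSpec(ac_mode="ct", psf_correction=ss.PsfModel.none(),
                            n_subsets=1, n_iterations=n_iter)
        recon = osem_reconstruct(noisy, spec, mu_map=small_phantom.mu_map)
        lls.append(loglike(recon.values))
    assert all(b >= a - 1e-6 * abs(a) for a, b in zip(lls, lls[1:]))


def test_mismatched_blur_model_underestimates_striatum(small_phantom,
                                                       small_geometry):
    """Data blurred by the camera PSF, reconstructed without PSF correction,
    yields a lower striatal mean than the matched-model reconstruction."""
    psf = ss.PsfModel.method2()
    sino = _noiseless(small_phantom, small_geometry, psf)
    matched = osem_reconstruct(
        sino, ss.ReconSpec(ac_mode="ct", psf_correction=psf),
        mu_map=small_phantom.mu_map)
    unmatched = osem_reconstruct(
        sino, ss.ReconSpec(ac_mode="ct", psf_correction=ss.PsfModel.none()),
        mu_map=small_phantom.mu_map)
    striatum = small_phantom.striatal_mask_left | small_phantom.striatal_mask_right
    assert unmatched.values[striatum].mean() < matched.values[striatum].mean()


def test_no_ac_underestimates_deep_structures(small_phantom, small_geometry):
    """Attenuated data reconstructed without AC underestimates deep VOI
    means relative to either AC mode."""
    sino = _noiseless(small_phantom, small_geometry, ss.PsfModel.none())
    striatum = small_phantom.striatal_mask_left | small_phantom.striatal_mask_right
    means = {}
    for ac, mu in (("none", None), ("ct", small_phantom.mu_map), ("ell", None)):
        spec = ss.ReconSpec(ac_mode=ac, ac_mu_uniform=0.15,
                            psf_correction=ss.PsfModel.none())
        recon = osem_reconstruct(sino, spec, mu_map=mu,
                                 support=small_phantom.labels > 0)
        means[ac] = recon.values[striatum].mean()
    assert means["none"] < means["ct"]
    assert means["none"] < means["ell"]


def test_ell_matches_ct_when_truth_is_uniform_ellipse():
    """When the true mu-map is uniform inside an ellipsoid, ellipse-based AC
    and CT-based AC agree on striatal means within 2%."""
    grid = ss.VoxelGrid((32, 32, 16), 5.9)
    spec_ph = ss.PhantomSpec(
        grid=grid, head_semiaxes_mm=(60.0, 70.0, 40.0), scalp_thickness_mm=0.0,
        chambers={
            "left_caudate": ss.Ellipsoid((-14.0, 18.0, 2.0), (7.0, 13.0, 10.0)),
            "right_caudate": ss.Ellipsoid((14.0, 18.0, 2.0), (7.0, 13.0, 10.0)),
            "left_putamen": ss.Ellipsoid((-26.0, -8.0, 0.0), (8.0, 14.0, 10.0)),
            "right_putamen": ss.Ellipsoid((26.0, -8.0, 0.0), (8.0, 14.0, 10.0)),
        },
        mu_background=0.15, mu_chambers=0.15)
    phantom = ss.build_phantom(spec_ph)
    geom = ss.AcquisitionGeometry(orbit_radius_mm=120.0)
    sino = _noiseless(phantom, geom, ss.PsfModel.none())
    striatum = phantom.striatal_mask_left | phantom.striatal_mask_right
    ct = osem_reconstruct(sino, ss.ReconSpec(ac_mode="ct",
                                             psf_correction=ss.PsfModel.none()),
                          mu_map=phantom.mu_map)
    ell = osem_reconstruct(sino, ss.ReconSpec(ac_mode="ell", ac_mu_uniform=0.15,
                                              scalp_dilation_mm=0.0,
                                              psf_correction=ss.PsfModel.none()),
                           support=phantom.labels > 0)
    assert ell.values[striatum].mean() == pytest.approx(
        ct.values[striatum].mean(), rel=0.02)


def test_subset_divisibility_enforced(small_phantom, small_geometry):
    sino = _noiseless(small_phantom, small_geometry, ss.PsfModel.none(), mu=False)
    with pytest.raises(ValueError, match="divisible"):
        osem_reconstruct(sino, ss.ReconSpec(ac_mode="none", n_subsets=7))


def test_reconstruction_nonnegative_and_zero_outside_fov(small_phantom,
                                                         small_geometry):
    sino = _noiseless(small_phantom, small_geometry, ss.PsfModel.none(), mu=False)
    noisy = ss.add_counting_noise(sino, 1e5, rng_seed=2)
    recon = osem_reconstruct(noisy, ss.ReconSpec(ac_mode="none"))
    assert np.all(recon.values >= 0)
    n = recon.values.shape[0]
    x, y = np.meshgrid(np.arange(n) - (n - 1) / 2, np.arange(n) - (n - 1) / 2,
                       indexing="ij")
    outside = (x**2 + y**2) > (n / 2.0) ** 2
    assert np.all(recon.values[outside, :] == 0)


# ----------------------------------------------------------------- smoothing

def test_smoothing_identity_and_mass_preservation(small_phantom):
    vol = ss.ReconVolume(values=small_phantom.activity.copy(),
                         spec=ss.ReconSpec(), voxel_size_mm=5.9)
    same = gaussian_smooth(vol, 0.0)
    assert np.array_equal(same.values, vol.values)
    sm = gaussian_smooth(vol, 8.0)
    assert sm.values.sum() == pytest.approx(vol.values.sum(), rel=1e-3)
    assert sm.smoothing_fwhm_mm == 8.0


def test_smoothing_width_matches_requested_fwhm():
    vox = 2.0
    vals = np.zeros((41, 41, 41))
    vals[20, 20, 20] = 1.0
    vol = ss.ReconVolume(values=vals, spec=ss.ReconSpec(), voxel_size_mm=vox)
    sm = gaussian_smooth(vol, 10.0)
    profile = sm.values[:, 20, 20]
    u = (np.arange(41) - 20) * vox
    sigma = np.sqrt(np.sum(u**2 * profile) / profile.sum())
    assert sigma / ss.projector.FWHM_TO_SIGMA == pytest.approx(10.0, abs=0.5)


def test_negative_smoothing_rejected(small_phantom):
    vol = ss.ReconVolume(values=small_phantom.activity, spec=ss.ReconSpec(),
                         voxel_size_mm=5.9)
    with pytest.raises(ValueError):
        gaussian_smooth(vol, -1.0)


# -------------------------------------------------------------- Chang factor

def test_chang_factor_closed_form_disk_centre():
    """C = exp(mu R) at the centre of a uniform disk; mu=0.11/cm, R=10 cm."""
    n, vox = 128, 2.0
    x, y = np.meshgrid(np.arange(n) - (n - 1) / 2, np.arange(n) - (n - 1) / 2,
                       indexing="ij")
    disk = (x**2 + y**2) * vox**2 <= 100.0**2
    c = chang_first_order_factor(((n - 1) / 2, (n - 1) / 2), disk, vox, 0.11)
    assert c == pytest.approx(np.exp(1.1), rel=0.02)
    assert chang_first_order_factor(((n - 1) / 2, (n - 1) / 2), disk, vox, 0.0) \
        == pytest.approx(1.0, abs=1e-12)


def test_chang_factor_off_centre_matches_quadrature_oracle():
    """Off-centre point in a disk: compare with analytic chord lengths
    integrated over angle."""
    n, vox = 128, 2.0
    R = 100.0
    x, y = np.meshgrid(np.arange(n) - (n - 1) / 2, np.arange(n) - (n - 1) / 2,
                       indexing="ij")
    disk = (x**2 + y**2) * vox**2 <= R**2
    d = 50.0  # mm from centre
    point = ((n - 1) / 2 + d / vox, (n - 1) / 2)
    mu = 0.11
    angles = np.arange(0.0, 360.0, 1.0)
    # analytic exit-path length from an interior point to the circle
    th = np.deg2rad(angles)
    lengths_cm = (np.sqrt(R**2 - d**2 * np.sin(th) ** 2) - d * np.cos(th)) / 10.0
    oracle = 1.0 / np.mean(np.exp(-mu * lengths_cm))
    got = chang_first_order_factor(point, disk, vox, mu, angles_deg=angles)
    assert got == pytest.approx(oracle, rel=0.005)


def test_chang_factor_outside_support_rejected():
    disk = np.zeros((32, 32), dtype=bool)
    disk[8:24, 8:24] = True
    with pytest.raises(ValueError):
        chang_first_order_factor((2.0, 2.0), disk, 5.9, 0.11)
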