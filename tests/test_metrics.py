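import numpy as np
import pytest
from scipy import ndimage

from cryocn import (
    AcquisitionGeometry,
    Volume,
    directional_fsc,
    evaluate_volumes,
    fsc,
    normalize_volume,
    psnr,
    ssim,
    vif,
    wedge_masks,
    z_elongation,
)


# --- independent oracles -----------------------------------------------------

def reference_ssim_3d(a, b, data_range, sigma=1.5, K1=0.01, K2=0.03):
    """Hand-rolled 3D SSIM with Gaussian weights (no sample covariance),
    cropped to the valid interior, mirroring the standard formulation."""
    C1 = (K1 * data_range) ** 2
    C2 = (K2 * data_range) ** 2
    filt = lambda x: ndimage.gaussian_filter(x, sigma, truncate=3.5)
    mu1, mu2 = filt(a), filt(b)
    s1 = filt(a * a) - mu1 * mu1
    s2 = filt(b * b) - mu2 * mu2
    s12 = filt(a * b) - mu1 * mu2
    S = ((2 * mu1 * mu2 + C1) * (2 * s12 + C2)) / (
        (mu1**2 + mu2**2 + C1) * (s1 + s2 + C2)
    )
    pad = (2 * int(3.5 * sigma + 0.5) + 1 - 1) // 2
    return S[pad:-pad, pad:-pad, pad:-pad].mean()


def reference_vif_2d(ref, dist, n_scales=4, sigma_nsq=2.0, scale_weights=None):
    """Independent 2D pixel-domain multiscale VIF (classic formulation).

    ``scale_weights`` lets the caller mirror a separable 3D computation in
    which each dyadic scale s carries nz/2^(s-1) identical z-slices.
    """
    num = den = 0.0
    eps = 1e-10
    weights = scale_weights or [1.0] * n_scales
    r, d = ref.astype(float), dist.astype(float)
    for scale in range(1, n_scales + 1):
        N = 2.0 ** (n_scales - scale + 1) + 1
        sd = N / 5.0
        if scale > 1:
            r = ndimage.gaussian_filter(r, sd, truncate=3.5)[::2, ::2]
            d = ndimage.gaussian_filter(d, sd, truncate=3.5)[::2, ::2]
        filt = lambda x: ndimage.gaussian_filter(x, sd, truncate=3.5)
        mu1, mu2 = filt(r), filt(d)
        s1 = np.maximum(filt(r * r) - mu1 * mu1, 0)
        s2 = np.maximum(filt(d * d) - mu2 * mu2, 0)
        s12 = filt(r * d) - mu1 * mu2
        g = s12 / (s1 + eps)
        sv = s2 - g * s12
        g = np.where(s1 < eps, 0.0, g)
        sv = np.where(s1 < eps, s2, sv)
        sv = np.maximum(sv, 0)
        w = weights[scale - 1]
        num += w * np.sum(np.log10(1 + g * g * s1 / (sv + sigma_nsq)))
        den += w * np.sum(np.log10(1 + s1 / sigma_nsq))
    return num / den


# --- PSNR --------------------------------------------------------------------

class TestPSNR:
    def test_identity_is_infinite(self, rng):
        v = Volume(data=rng.random((8, 8, 8)))
        assert psnr(v, v) == float("inf")

    def test_closed_form_constant_offset(self):
        ref = Volume(data=np.zeros((8, 8, 8)))
        pred = Volume(data=np.full((8, 8, 8), 0.5))
        val = psnr(pred, ref, Im=1.0)
        assert np.isclose(val, 10 * np.log10(1 / 0.25))
        assert np.isclose(val, 6.0206, atol=1e-4)

    def test_joint_scale_invariance(self, rng):
        a = Volume(data=rng.random((8, 8, 8)))
        b = Volume(data=rng.random((8, 8, 8)))
        p1 = psnr(a, b, Im=1.0)
        p2 = psnr(Volume(data=3 * a.data), Volume(data=3 * b.data), Im=3.0)
        assert np.isclose(p1, p2)

    def test_dim_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            psnr(Volume(data=np.zeros((4, 4, 4))), Volume(data=np.ones((4, 4, 5))))


# --- SSIM --------------------------------------------------------------------

class TestSSIM:
    def test_identity_and_anticorrelation(self, rng):
        v = Volume(data=rng.random((16, 16, 16)))
        assert np.isclose(ssim(v, v), 1.0)
        zero_mean = rng.normal(size=(16, 16, 16))
        assert ssim(Volume(data=-zero_mean), Volume(data=zero_mean)) < 0

    def test_matches_independent_reference(self, rng):
        a = rng.random((16, 16, 16))
        b = np.clip(a + 0.1 * rng.normal(size=a.shape), 0, 1)
        ours = ssim(Volume(data=b), Volume(data=a))
        oracle = reference_ssim_3d(a, b, data_range=a.max() - a.min())
        assert np.isclose(ours, oracle, atol=1e-6)

    def test_window_larger_than_volume_rejected(self, rng):
        small = Volume(data=rng.random((8, 8, 8)))
        with pytest.raises(ValueError):
            ssim(small, small)


# --- VIF ---------------------------------------------------------------------

class TestVIF:
    def test_identity_is_one(self, rng):
        v = Volume(data=rng.random((32, 32, 32)))
        assert np.isclose(vif(v, v), 1.0, atol=1e-10)

    def test_blur_lands_in_unit_interval(self, rng):
        a = rng.random((32, 32, 32))
        blurred = ndimage.gaussian_filter(a, 2.0)
        score = vif(Volume(data=blurred), Volume(data=a))
        assert 0 < score < 1

    def test_constant_reference_rejected(self):
        flat = Volume(data=np.ones((16, 16, 16)))
        with pytest.raises(ValueError):
            vif(flat, flat)

    def test_matches_slicewise_reference_on_z_constant_texture(self, rng):
        # a texture broadcast along z makes the 3D computation separable, so
        # it must agree with an independent 2D implementation on the texture
        tex_a = rng.random((32, 32))
        tex_b = np.clip(tex_a + 0.2 * rng.normal(size=tex_a.shape), 0, 1)
        vol_a = Volume(data=np.repeat(tex_a[:, :, None], 32, axis=2))
        vol_b = Volume(data=np.repeat(tex_b[:, :, None], 32, axis=2))
        ours = vif(vol_b, vol_a)
        oracle = reference_vif_2d(tex_a, tex_b, scale_weights=[32, 16, 8, 4])
        assert np.isclose(ours, oracle, atol=1e-6)


# --- FSC ---------------------------------------------------------------------

class TestFSC:
    def test_identity_and_scale_invariance(self, rng):
        v = Volume(data=rng.random((16, 16, 16)))
        curve = fsc(v, v)
        assert np.allclose(curve.correlation, 1.0, atol=1e-12)
        doubled = fsc(v, Volume(data=2 * v.data))
        assert np.allclose(doubled.correlation, 1.0, atol=1e-12)
        assert curve.radii[0] == 1 and curve.radii[-1] == 8

    def test_independent_noise_within_sampling_bound(self):
        rng = np.random.default_rng(77)
        a = Volume(data=rng.normal(size=(32, 32, 32)))
        b = Volume(data=rng.normal(size=(32, 32, 32)))
        curve = fsc(a, b)
        for r, c, n in zip(curve.radii, curve.correlation, curve.counts):
            if n >= 100:
                assert abs(c) <= 3 / np.sqrt(n), (r, c, n)

    def test_magnitude_bounded(self, rng):
        a = Volume(data=rng.random((12, 12, 12)))
        b = Volume(data=rng.random((12, 12, 12)))
        assert np.all(np.abs(fsc(a, b).correlation) <= 1 + 1e-9)


# --- wedge masks -------------------------------------------------------------

class TestWedgeMasks:
    def test_full_range_fine_step_covers_everything(self):
        g = AcquisitionGeometry.from_step_range(step=1.0, tilt_range=90.0)
        m = wedge_masks((24, 8, 24), g)
        assert not np.any(m.missing)

    def test_partition_and_hermitian_symmetry(self, coarse_geometry):
        m = wedge_masks((16, 8, 12), coarse_geometry)
        assert not np.any(m.present & m.missing)
        assert np.all(m.present | m.missing)
        for mask in (m.present, m.missing):
            flipped = mask[::-1, ::-1, ::-1]
            # k -> -k on the fft grid is a flip plus roll by one
            assert np.array_equal(
                mask, np.roll(flipped, (1, 1, 1), axis=(0, 1, 2))
            )

    def test_missing_fraction_near_analytic_solid_angle(self):
        # +-60 deg tilting leaves a double wedge of azimuthal half-angle
        # 30 deg about z in the xz-plane: 4*30/360 = 1/3 of directions
        g = AcquisitionGeometry.from_step_range(step=2.0, tilt_range=60.0)
        m = wedge_masks((64, 64, 64), g)
        freqs = np.fft.fftfreq(64) * 64
        kx, ky, kz = np.meshgrid(freqs, freqs, freqs, indexing="ij")
        r = np.sqrt(kx**2 + ky**2 + kz**2)
        shell = (r >= 16) & (r <= 31)
        frac = m.missing[shell].mean()
        assert abs(frac - 1 / 3) / (1 / 3) < 0.15

    def test_widening_range_shrinks_missing_region(self):
        prev = None
        for beta in (30.0, 45.0, 60.0, 75.0):
            g = AcquisitionGeometry.from_step_range(step=3.0, tilt_range=beta)
            missing = wedge_masks((24, 8, 24), g).missing
            if prev is not None:
                assert np.all(missing <= prev)  # set containment
                assert missing.sum() < prev.sum()
            prev = missing


# --- directional FSC ---------------------------------------------------------

class TestDirectionalFSC:
    def test_identity_in_both_regions(self, rng, coarse_geometry):
        v = Volume(data=rng.random((16, 16, 16)))
        m = wedge_masks(v.dims, coarse_geometry)
        for region in ("present", "missing"):
            curve = directional_fsc(v, v, m, region)
            assert np.allclose(curve.correlation, 1.0, atol=1e-12)

    def test_constructed_corruption_zeroes_missing_region_only(self, rng,
                                                               coarse_geometry):
        v = Volume(data=rng.random((16, 16, 16)))
        m = wedge_masks(v.dims, coarse_geometry)
        F = np.fft.fftn(v.data)
        F[m.missing] = 0.0
        corrupted = Volume(data=np.real(np.fft.ifftn(F)))
        present = directional_fsc(v, corrupted, m, "present")
        missing = directional_fsc(v, corrupted, m, "missing")
        assert np.allclose(present.correlation, 1.0, atol=1e-6)
        wedge_shells = missing.counts >= 10
        assert np.all(np.abs(missing.correlation[wedge_shells]) < 1e-6)

    def test_region_counts_partition_full_counts(self, rng, coarse_geometry):
        a = Volume(data=rng.random((16, 16, 16)))
        b = Volume(data=rng.random((16, 16, 16)))
        m = wedge_masks(a.dims, coarse_geometry)
        full = fsc(a, b)
        pres = directional_fsc(a, b, m, "present")
        miss = directional_fsc(a, b, m, "missing")
        totals = dict(zip(full.radii, full.counts))
        combined = {}
        for curve in (pres, miss):
            for r, n in zip(curve.radii, curve.counts):
                combined[r] = combined.get(r, 0) + n
        assert combined == totals


# --- aggregate report + anisotropy -------------------------------------------

class TestReportAndElongation:
    def test_identity_report_is_perfect(self, rng, coarse_geometry):
        v = Volume(data=rng.random((16, 16, 16)))
        rep = evaluate_volumes(v, v, coarse_geometry)
        assert rep.psnr == float("inf")
        assert np.isclose(rep.ssim, 1.0)
        assert np.isclose(rep.vif, 1.0)
        for curve in (rep.fsc_full, rep.fsc_present, rep.fsc_missing):
            assert np.allclose(curve.correlation, 1.0, atol=1e-9)

    def test_sphere_is_isotropic(self):
        idx = np.indices((24, 24, 24))
        ball = (np.sqrt(((idx - 11.5) ** 2).sum(axis=0)) <= 8).astype(float)
        assert abs(z_elongation(Volume(data=ball)) - 1.0) < 0.05

    def test_normalize_volume_endpoints(self, rng):
        v = Volume(data=rng.uniform(-2, 3, size=(6, 6, 6)))
        n = normalize_volume(v)
        assert n.data.min() == 0.0 and n.data.max() == 1.0
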