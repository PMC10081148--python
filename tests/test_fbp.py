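import numpy as np
import pytest

import radialmri as rm
from radialmri.fourier import freq_axis
from tests.conftest import disk_image


class TestFilterTransfer:
    @pytest.mark.parametrize(
        "omega,beta,expected",
        [(0.0, 0.0, 0.0), (0.0, 5.0, 0.0), (1.0, 0.0, 1.0), (1.0, 1.0, 0.5)],
    )
    def test_values(self, omega, beta, expected):
        assert rm.filter_transfer(omega, beta) == expected

    def test_beta_zero_is_exact_ramp(self):
        w = np.abs(freq_axis(256))
        assert np.array_equal(rm.filter_transfer(w, 0.0), w)

    def test_negative_beta_rejected(self):
        with pytest.raises(ValueError):
            rm.filter_transfer(1.0, -0.5)

    def test_monotone_lowpass_in_beta(self):
        w = np.linspace(0.01, 0.5, 50)
        g0, g1, g2 = (rm.filter_transfer(w, b) for b in (0.0, 1.0, 2.0))
        assert np.all(g1 < g0) and np.all(g2 < g1)


class TestFilterLines:
    def _frame(self, lines):
        v, n = lines.shape
        return rm.RadialKSpaceFrame(sampling=rm.make_sampling(v, n), lines=lines)

    def test_zero_frame(self):
        f = self._frame(np.zeros((4, 16), dtype=complex))
        assert np.all(rm.filter_lines(f, rm.FbpConfig()).lines == 0)

    def test_dc_sample_zeroed(self, rng):
        lines = rng.standard_normal((4, 16)) + 1j
        out = rm.filter_lines(self._frame(lines), rm.FbpConfig(beta=1.5))
        assert np.all(out.lines[:, 8] == 0)

    def test_ones_frame_shows_ramp_pattern(self):
        f = self._frame(np.ones((3, 32), dtype=complex))
        out = rm.filter_lines(f, rm.FbpConfig())
        expected = np.abs((np.arange(32) - 16) / 32)
        assert np.allclose(out.lines.real, expected[None, :])
        assert np.all(out.lines.imag == 0)


class TestBackproject:
    def test_zero_projections(self):
        img = rm.backproject(np.zeros((5, 16)), np.arange(5) * 36.0, 16)
        assert np.all(img == 0)

    def test_linearity(self, rng):
        angles = np.arange(6) * 30.0
        a = rng.standard_normal((6, 16))
        b = rng.standard_normal((6, 16))
        lhs = rm.backproject(a + b, angles, 16)
        rhs = rm.backproject(a, angles, 16) + rm.backproject(b, angles, 16)
        assert np.abs(lhs - rhs).max() < 1e-9

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rm.backproject(np.zeros((4, 16)), np.zeros(5), 16)

    def test_adjoint_identity_explicit_matrices(self):
        """Backprojection is (π/V) times the transpose of the matched
        pixel-driven forward projector, verified as explicit matrices."""
        N, n_samples = 16, 16
        angles = np.arange(8) * 22.5
        P = np.zeros((8 * n_samples, N * N))
        for j in range(N * N):
            e = np.zeros(N * N)
            e[j] = 1.0
            P[:, j] = rm.project_image(e.reshape(N, N), angles, n_samples).ravel()
        B = np.zeros((N * N, 8 * n_samples))
        for j in range(8 * n_samples):
            e = np.zeros(8 * n_samples)
            e[j] = 1.0
            B[:, j] = rm.backproject(e.reshape(8, n_samples), angles, N).ravel()
        assert np.abs(B - (np.pi / 8) * P.T).max() < 1e-6


class TestFbpReconstruct:
    def test_zero_kspace(self):
        f = rm.RadialKSpaceFrame(
            sampling=rm.make_sampling(8, 32), lines=np.zeros((8, 32), dtype=complex)
        )
        assert np.all(rm.fbp_reconstruct(f, rm.FbpConfig(use_ramp=True)) == 0)

    def test_noiseless_disk_72_views(self):
        """Normalized RMSE of the ramp reconstruction of a unit disk stays
        below 10% of the disk amplitude at full 72-view sampling."""
        disk = disk_image(128)
        f = rm.simulate_acquisition(disk, rm.make_sampling(72, 128))
        img = rm.fbp_reconstruct(f, rm.FbpConfig(version="V4", use_ramp=True))
        assert np.sqrt(np.mean((img - disk) ** 2)) < 0.10

    def test_real_phantom_imaginary_channel_vanishes(self):
        """With zero phase the k-space is Hermitian and the imaginary-channel
        image vanishes, so the norm image reduces to |real-channel image|.
        An odd sample count is used so every signed radius has its conjugate
        partner (the even-n layout leaves the most-negative sample unpaired)."""
        spec = rm.default_spec(grid_size=64, n_frames=2, phase_amplitude=0.0)
        img = rm.generate_phantom(spec).frames[1]
        f = rm.simulate_acquisition(img, rm.make_sampling(48, 65))
        filtered = rm.filter_lines(f, rm.FbpConfig(use_ramp=True))
        from radialmri.fourier import centered_ifft1

        proj = centered_ifft1(filtered.lines, axis=-1)
        re = rm.backproject(proj.real, f.sampling.angles_deg, 64)
        im = rm.backproject(proj.imag, f.sampling.angles_deg, 64)
        assert np.abs(im).max() < 1e-9 * np.abs(re).max()
        out = rm.fbp_reconstruct(f, rm.FbpConfig(use_ramp=True, output_size=64))
        assert np.abs(out - np.abs(re)).max() < 1e-9 * np.abs(re).max()

    def test_monotone_view_benefit(self, disk64):
        errors = []
        for v in (12, 24, 48, 72):
            f = rm.simulate_acquisition(disk64, rm.make_sampling(v, 64))
            img = rm.fbp_reconstruct(f, rm.FbpConfig(use_ramp=True))
            errors.append(np.sqrt(np.mean((img - disk64) ** 2)))
        assert all(b < a for a, b in zip(errors, errors[1:]))

    def test_rotation_equivariance(self):
        """Reconstructing a rotated phantom ≈ rotating the reconstruction,
        within interpolation tolerance (5% relative)."""
        from scipy.ndimage import rotate

        n = 64
        ax = (np.arange(n) - n // 2) / (n / 2)
        y, x = np.meshgrid(ax, ax, indexing="ij")
        blob = np.exp(-(((x - 0.2) ** 2 + y**2) / 0.05)) + 0.5 * np.exp(
            -((x**2 + (y + 0.25) ** 2) / 0.02)
        )
        s = rm.make_sampling(36, n)  # one view spacing = 5 degrees
        step = 180.0 / 36
        cfg = rm.FbpConfig(use_ramp=True)
        rec = rm.fbp_reconstruct(rm.simulate_acquisition(blob, s), cfg)
        blob_rot = rotate(blob, step, reshape=False, order=3)
        rec_rot_phantom = rm.fbp_reconstruct(rm.simulate_acquisition(blob_rot, s), cfg)
        rec_rotated = rotate(rec, step, reshape=False, order=3)
        core = (x**2 + y**2) < 0.8**2
        num = np.sqrt(np.mean((rec_rot_phantom - rec_rotated)[core] ** 2))
        assert num / np.sqrt(np.mean(rec[core] ** 2)) < 0.05

    def test_noise_variance_non_increasing_in_beta(self):
        rng = np.random.default_rng(5)
        n = 64
        flat = np.zeros((n, n))
        flat[16:48, 16:48] = 1.0
        s = rm.make_sampling(48, n)
        f = rm.simulate_acquisition(flat, s, noise_sigma=1.0, rng=rng)
        variances = []
        for beta in (0.0, 1.0, 2.0):
            img = rm.fbp_reconstruct(f, rm.FbpConfig(beta=beta))
            variances.append(img[24:40, 24:40].var())
        assert variances[0] >= variances[1] >= variances[2]


class TestRunVersion:
    def _frames(self, seed=0):
        rng = np.random.default_rng(seed)
        img = rng.standard_normal((32, 32))
        f72 = rm.simulate_acquisition(img, rm.make_sampling(72, 32))
        return rm.undersample(f72, 3), f72

    def test_v3_equals_v2_beta_zero(self):
        f24, _ = self._frames()
        v3 = rm.run_version(f24, None, "V3")
        v2 = rm.run_version(f24, None, "V2", beta=0.0)
        assert np.array_equal(v3, v2)

    def test_v4_requires_full_frame(self):
        f24, f72 = self._frames()
        with pytest.raises(ValueError):
            rm.run_version(f24, None, "V4")
        with pytest.raises(ValueError):
            rm.run_version(None, f72, "V1")

    def test_v4_is_gold_standard_pipeline(self):
        _, f72 = self._frames()
        gold = rm.run_version(None, f72, "V4")
        direct = rm.fbp_reconstruct(f72, rm.FbpConfig(version="V4", use_ramp=True))
        assert np.array_equal(gold, direct)
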