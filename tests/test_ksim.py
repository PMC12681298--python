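import numpy as np
import pytest

from tofrecon import ksim
from tofrecon.errors import (
    DegenerateMaskError,
    InfeasibleMaskError,
    InvalidConfigError,
    InvalidPFError,
    NoThresholdError,
    ShapeError,
)
from tofrecon.ksim import (
    CoilSimConfig,
    PhaseSimConfig,
    SamplingMask,
    apply_bias_field,
    compose_multicoil_kspace,
    compute_head_mask,
    load_acquisition,
    make_pf_mask,
    make_poisson_mask,
    save_acquisition,
    simulate_acquisition,
    simulate_coil_maps,
    simulate_phase,
    undersample,
)
from tofrecon.mri_ops import fft3c, ifft3c, rss
from tofrecon.phantom_io import MagnitudeVolume


def _hermitian_error(k: np.ndarray) -> float:
    """Max |K(f) - conj(K(-f))| for a centered spectrum."""
    K = np.fft.ifftshift(k)
    Krev = K
    for ax in range(K.ndim):
        Krev = np.roll(np.flip(Krev, axis=ax), 1, axis=ax)
    return float(np.abs(K - np.conj(Krev)).max())


class TestHeadMask:
    def test_cube_oracle(self):
        # bright cube side 20 in a 40^3 zero field; after Otsu binarization,
        # 4 erosions and 9 dilations (6-connected) the mask is the set of
        # voxels within L1 distance 9 of the eroded cube [a+4, b-4]^3 --
        # closed-form oracle via the L1 distance to a box.
        vol = np.zeros((40, 40, 40))
        lo, hi = 10, 30  # cube [10, 29]
        vol[lo:hi, lo:hi, lo:hi] = 1.0
        head = compute_head_mask(MagnitudeVolume(data=vol))
        g = np.meshgrid(*[np.arange(40)] * 3, indexing="ij")
        l1 = sum(np.maximum(0, (lo + 4) - gi) + np.maximum(0, gi - (hi - 1 - 4)) for gi in g)
        expected = l1 <= 9
        np.testing.assert_array_equal(head.mask, expected)

    def test_constant_volume_errors(self):
        with pytest.raises(NoThresholdError):
            compute_head_mask(MagnitudeVolume(data=np.zeros((20, 20, 20))))

    def test_erosion_to_empty_errors(self):
        vol = np.zeros((20, 20, 20))
        vol[9:12, 9:12, 9:12] = 1.0  # 3^3 blob dies under 4 erosions
        with pytest.raises(DegenerateMaskError):
            compute_head_mask(MagnitudeVolume(data=vol))

    def test_boundary_on_surface(self, small_phantom):
        head = compute_head_mask(small_phantom)
        offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
        m = head.mask
        for y, x, z in head.boundary[:: max(1, len(head.boundary) // 200)]:
            assert m[y, x, z]
            has_bg = False
            for dy, dx, dz in offsets:
                yy, xx, zz = y + dy, x + dx, z + dz
                if not (0 <= yy < m.shape[0] and 0 <= xx < m.shape[1] and 0 <= zz < m.shape[2]):
                    has_bg = True  # volume edge counts as background
                elif not m[yy, xx, zz]:
                    has_bg = True
            assert has_bg


class TestPhaseSim:
    def test_zero_components_zero_phase(self, small_phantom):
        phi = simulate_phase(small_phantom, PhaseSimConfig(n_components=0, seed=0))
        support = small_phantom.data > 0
        assert np.all(phi[support] == 0.0)

    def test_codomain(self, small_phantom):
        phi = simulate_phase(small_phantom, PhaseSimConfig(seed=3))
        assert np.all(phi > -np.pi) and np.all(phi <= np.pi)

    def test_determinism(self, small_phantom):
        a = simulate_phase(small_phantom, PhaseSimConfig(seed=9))
        b = simulate_phase(small_phantom, PhaseSimConfig(seed=9))
        np.testing.assert_array_equal(a, b)

    def test_strong_noise_circular_mean(self, small_phantom):
        # with noise far above the signal the phase at a fixed voxel should be
        # near-uniform: circular mean ~ 0 within 3 SE, non-degenerate spread
        cfg_base = dict(n_components=2, sigma_noise_range=(50.0, 100.0))
        voxel = (16, 16, 8)
        phases = np.array(
            [
                simulate_phase(small_phantom, PhaseSimConfig(seed=s, **cfg_base))[voxel]
                for s in range(50)
            ]
        )
        z = np.mean(np.exp(1j * phases))
        se = 1.0 / np.sqrt(len(phases))
        assert abs(z) <= 3 * se * 2  # |mean resultant| consistent with uniformity
        assert np.std(phases) > 0.5


class TestCoilSim:
    def test_sos_normalization(self, small_phantom):
        head = compute_head_mask(small_phantom)
        coils = simulate_coil_maps(small_phantom, head, CoilSimConfig(n_coils=6, seed=1))
        np.testing.assert_allclose(coils.sos(), 1.0, atol=1e-5)

    def test_32_coils(self):
        vol = MagnitudeVolume(
            data=np.pad(np.ones((14, 14, 10)), ((6, 6), (6, 6), (4, 4))),
        )
        head = compute_head_mask(vol)
        coils = simulate_coil_maps(vol, head, CoilSimConfig(n_coils=32, seed=2))
        assert coils.n_coils == 32

    def test_noise_free_center_proximity(self, small_phantom):
        # with no noise components the peak of each normalized map stays
        # within 2 sigma (in voxels) of its Gaussian center
        head = compute_head_mask(small_phantom)
        cfg = CoilSimConfig(n_coils=4, n_components=0, seed=5)
        coils = simulate_coil_maps(small_phantom, head, cfg)
        # replay the center/sigma draws with the same generator protocol
        rng = np.random.default_rng(cfg.seed)
        axes = np.asarray(small_phantom.shape, dtype=float)
        for i in range(cfg.n_coils):
            c = head.boundary[rng.integers(len(head.boundary))]
            sigmas = np.array([rng.uniform(*r) for r in cfg.sigma_xyz_ranges]) * axes
            rng.uniform(0.0, np.pi)  # rotation draw
            peak = np.unravel_index(np.argmax(np.abs(coils.maps[i])), small_phantom.shape)
            dist = np.linalg.norm(np.asarray(peak) - np.asarray(c))
            assert dist <= 2.0 * float(np.max(sigmas))

    def test_empty_boundary_errors(self, small_phantom):
        head = ksim.HeadMask(mask=np.zeros(small_phantom.shape, bool), boundary=np.empty((0, 3), int))
        with pytest.raises(DegenerateMaskError):
            simulate_coil_maps(small_phantom, head, CoilSimConfig(n_coils=2, seed=0))

    def test_determinism(self, small_phantom):
        head = compute_head_mask(small_phantom)
        a = simulate_coil_maps(small_phantom, head, CoilSimConfig(n_coils=3, seed=4))
        b = simulate_coil_maps(small_phantom, head, CoilSimConfig(n_coils=3, seed=4))
        np.testing.assert_array_equal(a.maps, b.maps)


class TestBiasField:
    def test_zero_coefficient_identity(self, small_phantom):
        out = apply_bias_field(small_phantom, coefficient=0.0, order=3, seed=1)
        np.testing.assert_allclose(out.data, small_phantom.data, rtol=1e-12)

    def test_field_positive(self):
        vol = MagnitudeVolume(data=np.ones((16, 16, 16)))
        out = apply_bias_field(vol, coefficient=0.3, order=3, seed=2)
        assert np.all(out.data > 0)

    def test_log_field_is_degree3_polynomial(self):
        vol = MagnitudeVolume(data=np.ones((16, 16, 16)))
        out = apply_bias_field(vol, coefficient=0.3, order=3, seed=7)
        logf = np.log(out.data)
        coords = [np.linspace(-1, 1, 16)] * 3
        gx, gy, gz = np.meshgrid(*coords, indexing="ij")
        cols = [
            (gx**a * gy**b * gz**c).ravel()
            for a in range(4)
            for b in range(4 - a)
            for c in range(4 - a - b)
        ]
        design = np.stack(cols, axis=1)
        resid = np.linalg.lstsq(design, logf.ravel(), rcond=None)[1]
        rel = float(np.sqrt(resid[0]) / np.linalg.norm(logf)) if len(resid) else 0.0
        assert rel < 1e-6


class TestCompose:
    def test_rss_recovers_magnitude(self, small_acq, small_phantom):
        # bias field was applied inside simulate_acquisition; use |truth|
        recon = rss(ifft3c(small_acq.kspace))
        np.testing.assert_allclose(recon, np.abs(small_acq.truth_image), atol=1e-5 * np.abs(small_acq.truth_image).max())

    def test_parseval(self, small_acq):
        e_k = np.sum(np.abs(small_acq.kspace) ** 2)
        e_img = np.sum(np.abs(small_acq.truth_image) ** 2)
        np.testing.assert_allclose(e_k, e_img, rtol=1e-5)

    def test_coil_combined_phase_recovery(self, small_acq):
        comb = np.sum(np.conj(small_acq.truth_coils.maps) * ifft3c(small_acq.kspace), axis=0)
        mag = np.abs(small_acq.truth_image)
        sel = mag > 0.1 * mag.max()
        dphi = np.angle(comb * np.exp(-1j * small_acq.truth_phase))
        assert np.abs(dphi[sel]).max() < 1e-4

    def test_shape_mismatch(self, small_phantom):
        head = compute_head_mask(small_phantom)
        coils = simulate_coil_maps(small_phantom, head, CoilSimConfig(n_coils=2, seed=0))
        with pytest.raises(ShapeError):
            compose_multicoil_kspace(small_phantom, np.zeros((8, 8, 4)), coils)

    def test_hermitian_symmetry_broken_by_phase(self, small_phantom):
        # zero phase, single uniform coil -> conjugate-symmetric k-space;
        # the synthesized phase breaks the symmetry
        k_sym = fft3c(small_phantom.data.astype(complex))
        assert _hermitian_error(k_sym) < 1e-5 * np.abs(k_sym).max()
        phi = simulate_phase(small_phantom, PhaseSimConfig(seed=21))
        k_asym = fft3c(small_phantom.data * np.exp(1j * phi))
        assert _hermitian_error(k_asym) > 1e-2 * np.abs(k_asym).max()


class TestPFMask:
    def test_zero_fraction(self):
        np.testing.assert_array_equal(make_pf_mask(64, 0.0), np.ones(64, np.uint8))

    def test_paper_288_26pct(self):
        m = make_pf_mask(288, 0.26)
        assert int(m.sum()) == 213
        assert int((m == 0).sum()) == 75
        assert np.all(m[:75] == 0) and np.all(m[75:] == 1)

    def test_monotone(self):
        m = make_pf_mask(100, 0.3)
        d = np.diff(m.astype(int))
        assert np.all(d >= 0)

    def test_invalid_fraction(self):
        with pytest.raises(InvalidPFError):
            make_pf_mask(64, 0.5)


class TestPoissonMask:
    def test_calibration_block(self):
        m = make_poisson_mask(64, 24, R=8.0, calib=(12, 6), seed=0)
        cy, cz = (64 - 12) // 2, (24 - 6) // 2
        block = m[cy : cy + 12, cz : cz + 6]
        assert int(block.sum()) == 72

    def test_r1_all_ones(self):
        np.testing.assert_array_equal(make_poisson_mask(32, 16, 1.0), np.ones((32, 16), np.uint8))

    def test_local_radius_rule_brute_force(self):
        ny, nz, R, calib = 64, 24, 4.0, (12, 6)
        m = make_poisson_mask(ny, nz, R, calib=calib, seed=3)
        r0 = ksim._calibrate_r0(ny, nz, R, calib)
        cy, cz = (ny - 1) / 2.0, (nz - 1) / 2.0
        iy, iz = np.meshgrid(np.arange(ny), np.arange(nz), indexing="ij")
        dist = np.hypot(iy - cy, iz - cz)
        radius = r0 * (1.0 + ksim._VD_ALPHA * dist / dist.max())
        inside_calib = np.zeros((ny, nz), bool)
        ylo, zlo = (ny - 12) // 2, (nz - 6) // 2
        inside_calib[ylo : ylo + 12, zlo : zlo + 6] = True
        pts = np.argwhere(m.astype(bool) & ~inside_calib)
        rad = radius[pts[:, 0], pts[:, 1]]
        diff = pts[:, None, :] - pts[None, :, :]
        d = np.sqrt(np.sum(diff**2, axis=-1)).astype(float)
        lim = np.minimum(rad[:, None], rad[None, :])
        np.fill_diagonal(d, np.inf)
        assert np.all(d >= lim - 1e-9)

    @pytest.mark.parametrize("R", [4.0, 8.0])
    def test_empirical_acceleration(self, R):
        fracs = [make_poisson_mask(64, 24, R, seed=s).mean() for s in range(20)]
        rel = np.abs(np.asarray(fracs) - 1.0 / R) * R
        assert np.all(rel <= 0.10)

    def test_infeasible(self):
        with pytest.raises(InfeasibleMaskError):
            make_poisson_mask(16, 8, R=100.0, calib=(12, 6))

    def test_calib_too_big(self):
        with pytest.raises(InvalidConfigError):
            make_poisson_mask(8, 4, R=2.0, calib=(12, 6))

    def test_determinism(self):
        a = make_poisson_mask(48, 24, 4.0, seed=5)
        b = make_poisson_mask(48, 24, 4.0, seed=5)
        np.testing.assert_array_equal(a, b)


class TestUndersample:
    def test_all_ones_identity(self, small_acq):
        out = undersample(small_acq, small_acq.mask)
        np.testing.assert_array_equal(out.kspace, small_acq.kspace)

    def test_sampled_entries_unchanged(self, small_acq):
        nx, ny, nz = small_acq.shape
        mask = ksim.make_sampling_mask((nx, ny, nz), 4.0, pf_fraction=0.26, calib=(8, 4), seed=1)
        out = undersample(small_acq, mask)
        sel = np.broadcast_to(mask.combined().astype(bool)[None], out.kspace.shape)
        assert np.abs(out.kspace[sel] - small_acq.kspace[sel]).max() == 0.0
        assert np.all(out.kspace[~sel] == 0.0)

    def test_dim_mismatch(self, small_acq):
        bad = SamplingMask(
            pe_mask=np.ones((8, 8), np.uint8), pf_mask=np.ones(8, np.uint8), calib_extent=(2, 2)
        )
        with pytest.raises(ShapeError):
            undersample(small_acq, bad)

    def test_energy_retention_white_noise(self):
        # on white-noise k-space the retained energy fraction concentrates
        # around the sampled fraction
        rng = np.random.default_rng(0)
        ratios, fracs = [], []
        for s in range(20):
            mask = ksim.make_sampling_mask((16, 32, 16), 4.0, calib=(8, 4), seed=s)
            k = rng.standard_normal((2, 16, 32, 16)) + 1j * rng.standard_normal((2, 16, 32, 16))
            acq = ksim.SimulatedAcquisition(kspace=k, mask=mask)
            out = undersample(acq, mask)
            ratios.append(np.sum(np.abs(out.kspace) ** 2) / np.sum(np.abs(k) ** 2))
            fracs.append(mask.sampled_fraction)
        ratios, fracs = np.asarray(ratios), np.asarray(fracs)
        assert np.all(ratios <= 1.0)
        assert np.all(ratios >= 0.5 * fracs)
        assert abs(ratios.mean() - fracs.mean()) < 0.05


class TestPipelineAndIO:
    def test_simulation_determinism(self, small_phantom):
        a = simulate_acquisition(small_phantom, R=4.0, pf_fraction=0.26, calib=(8, 4), seed=3)
        b = simulate_acquisition(small_phantom, R=4.0, pf_fraction=0.26, calib=(8, 4), seed=3)
        np.testing.assert_array_equal(a.kspace, b.kspace)
        np.testing.assert_array_equal(a.mask.pe_mask, b.mask.pe_mask)

    def test_kspace_zero_off_mask(self, small_phantom):
        acq = simulate_acquisition(small_phantom, R=4.0, pf_fraction=0.26, calib=(8, 4), seed=3)
        sel = acq.mask.combined().astype(bool)[None]
        assert np.all(acq.kspace[~np.broadcast_to(sel, acq.kspace.shape)] == 0)

    def test_h5_roundtrip(self, tmp_path, small_acq):
        p = tmp_path / "acq.h5"
        save_acquisition(small_acq, p)
        back = load_acquisition(p)
        np.testing.assert_allclose(
            back.kspace, small_acq.kspace, atol=1e-5 * np.abs(small_acq.kspace).max()
        )
        np.testing.assert_array_equal(back.mask.pe_mask, small_acq.mask.pe_mask)
        np.testing.assert_array_equal(back.mask.pf_mask, small_acq.mask.pf_mask)
        assert back.mask.calib_extent == small_acq.mask.calib_extent
        assert back.truth_coils is not None and back.truth_image is not None

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_acquisition(tmp_path / "nope.h5")


class TestConfigValidation:
    def test_phase_cfg(self):
        with pytest.raises(InvalidConfigError):
            PhaseSimConfig(n_components=-1)
        with pytest.raises(InvalidConfigError):
            PhaseSimConfig(sigma_gauss_range=(0.5, 1.5))

    def test_coil_cfg(self):
        with pytest.raises(InvalidConfigError):
            CoilSimConfig(n_coils=0)
        with pytest.raises(InvalidConfigError):
            CoilSimConfig(sigma_noise_range=(-1.0, 1.0))
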