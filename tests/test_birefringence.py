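"""PS-OCT processing chain: averaging, local matrices, SNR, birefringence,
bias correction, DOAU, masked volume mean."""

import numpy as np
import pytest

from sclerheo import birefringence as bf
from sclerheo import jones as j
from sclerheo import synthetic as syn


def make_volume(data, **kw):
    return bf.JonesVolume(data=np.asarray(data, dtype=complex), **kw)


def constant_volume(shape, J, **kw):
    data = np.broadcast_to(J, tuple(shape) + (2, 2)).copy()
    return make_volume(data, **kw)


class TestMovingAverage:
    def test_constant_volume_unchanged(self):
        vol = constant_volume((6, 6, 2), j.make_linear_retarder(0.4, 0.1))
        out = bf.moving_average_jones(vol, (3, 3))
        assert np.allclose(out.data, vol.data)

    def test_kernel_one_is_identity(self):
        rng = np.random.default_rng(0)
        vol = make_volume(rng.normal(size=(4, 4, 1, 2, 2)) + 1j * rng.normal(size=(4, 4, 1, 2, 2)))
        out = bf.moving_average_jones(vol, (1, 1))
        assert np.array_equal(out.data, vol.data)

    def test_lateral_ramp_matches_brute_force_windowed_mean(self):
        # real-valued ramp in one element: phase alignment is a no-op and
        # the result must equal the direct 3-point truncated mean
        nx = 9
        data = np.zeros((1, nx, 1, 2, 2), dtype=complex)
        ramp = np.arange(nx, dtype=float)
        data[0, :, 0] = np.eye(2)
        data[0, :, 0, 0, 1] = 0.1 * ramp
        vol = make_volume(data)
        out = bf.moving_average_jones(vol, (1, 3))
        for x in range(nx):
            lo, hi = max(0, x - 1), min(nx, x + 2)
            assert np.allclose(out.data[0, x, 0, 0, 1], 0.1 * ramp[lo:hi].mean())

    def test_noise_floor_scaled_by_kernel_area(self):
        vol = constant_volume((6, 6, 1), np.eye(2, dtype=complex), noise_floor=9e-4)
        out = bf.moving_average_jones(vol, (3, 3))
        assert out.noise_floor == pytest.approx(1e-4)

    def test_kernel_larger_than_image_rejected(self):
        vol = constant_volume((4, 4, 1), np.eye(2, dtype=complex))
        with pytest.raises(ValueError):
            bf.moving_average_jones(vol, (5, 5))
        with pytest.raises(ValueError):
            bf.moving_average_jones(vol, (2, 3))  # even kernel

    def test_alignment_removes_per_pixel_global_phase(self):
        # same retarder, random global phases: aligned mean keeps retardance
        rng = np.random.default_rng(3)
        J = j.make_linear_retarder(0.8, 0.2)
        phases = np.exp(1j * rng.uniform(0, 2 * np.pi, size=(5, 5, 1)))
        vol = make_volume(J[None, None, None] * phases[..., None, None])
        out = bf.moving_average_jones(vol, (3, 3))
        ret, valid = j.lu_chipman_retardance_stack(j.jones_to_mueller(out.data))
        assert valid.all()
        assert np.allclose(ret, 0.8, atol=1e-9)


class TestLocalJones:
    def test_identity_volume_gives_identity_local(self):
        vol = constant_volume((12, 3, 1), np.eye(2, dtype=complex))
        loc = bf.local_jones(vol, 8)
        assert loc.shape == (4, 3, 1)
        assert np.allclose(loc.data, np.eye(2))
        assert loc.separation_depth_m == pytest.approx(8 * vol.axial_pitch_m)

    def test_homogeneous_retarder_rate(self):
        rho = 0.05  # rad per pixel round-trip
        z = 20
        data = np.stack([j.make_linear_retarder(rho * (k + 1), 0.3) for k in range(z)])
        vol = make_volume(data[:, None, None])
        loc = bf.local_jones(vol, 8)
        ret, valid = j.lu_chipman_retardance_stack(j.jones_to_mueller(loc.data))
        assert valid.all()
        assert np.allclose(ret, rho * 8, atol=1e-9)

    def test_two_layer_phantom_layers_and_boundary(self):
        # depth-layered axes: local matrices inside a layer match that
        # layer's retarder; the band straddling the interface is mixed
        z, sep = 30, 4
        dn = 1.5e-3
        axes = np.empty((z, 1, 1, 3))
        axes[:15] = [1.0, 0.0, 0.0]
        axes[15:] = [0.0, 1.0, 0.0]
        spec = syn.PhantomSpec(dims=(z, 1, 1), birefringence=dn, axis=axes, snr_db=None, rng_seed=0)
        vol = syn.simulate_jones_volume(spec)
        loc = bf.local_jones(vol, sep)
        s, valid = j.fast_axis_stokes_stack(loc.data)
        assert valid.all()
        assert np.allclose(s[: 15 - sep, 0, 0], [1.0, 0.0, 0.0], atol=1e-9)
        assert np.allclose(s[15:, 0, 0], [0.0, 1.0, 0.0], atol=1e-9)
        mid = s[15 - sep : 15, 0, 0]
        assert not np.allclose(mid, [1.0, 0.0, 0.0], atol=1e-3)

    def test_singular_pixels_flagged_not_raised(self):
        vol = constant_volume((12, 2, 1), np.eye(2, dtype=complex))
        vol.data[2, 0, 0] = 0.0
        loc = bf.local_jones(vol, 8)
        assert not loc.valid[2, 0, 0]
        assert loc.valid[2, 1, 0]


class TestEffectiveSnr:
    def test_zero_signal_masked_minus_inf(self):
        vol = constant_volume((3, 3, 1), np.zeros((2, 2)), noise_floor=1e-3)
        snr = bf.effective_snr(vol)
        assert not snr.mask.any()
        assert np.all(np.isneginf(snr.values))

    def test_signal_equal_noise_floor_is_zero_db(self):
        s = 0.01
        J = np.full((2, 2), np.sqrt(s), dtype=complex)
        vol = constant_volume((2, 2, 1), J, noise_floor=s)
        snr = bf.effective_snr(vol)
        assert np.allclose(snr.values, 0.0, atol=1e-12)

    def test_generated_phantom_hits_nominal_snr(self):
        spec = syn.PhantomSpec(dims=(32, 32, 2), birefringence=1e-3, snr_db=30.0, rng_seed=4)
        vol = syn.simulate_jones_volume(spec)
        snr = bf.effective_snr(vol)
        assert abs(np.mean(snr.values[snr.mask]) - 30.0) < 0.5


class TestLocalBirefringence:
    def test_closed_form_scaling(self):
        # R = pi/2 over 49 um at 1.31 um -> dn = 1.31/(8*49)
        data = j.make_linear_retarder(np.pi / 2, 0.0)
        loc = bf.JonesVolume(
            data=np.broadcast_to(data, (1, 1, 1, 2, 2)).copy(),
            separation_pixels=8,
        )
        dn = bf.local_birefringence(loc)
        assert dn.values[0, 0, 0] == pytest.approx(1.31 / (8 * 49), rel=1e-9)

    def test_zero_retardance_gives_zero(self):
        loc = bf.JonesVolume(
            data=np.broadcast_to(np.eye(2, dtype=complex), (1, 1, 1, 2, 2)).copy(),
            separation_pixels=8,
        )
        assert bf.local_birefringence(loc).values[0, 0, 0] == 0.0

    def test_noiseless_phantom_round_trip(self):
        spec = syn.PhantomSpec(dims=(30, 8, 1), birefringence=1.5e-3, snr_db=None, rng_seed=0)
        loc = bf.local_jones(syn.simulate_jones_volume(spec), 8)
        dn = bf.local_birefringence(loc)
        assert dn.mask.all()
        assert np.allclose(dn.values, 1.5e-3, atol=1e-6)

    def test_near_wrap_pixels_flagged(self):
        data = j.make_linear_retarder(np.pi * 0.999, 0.0)
        loc = bf.JonesVolume(
            data=np.broadcast_to(data, (1, 1, 1, 2, 2)).copy(),
            separation_pixels=8,
        )
        assert not bf.local_birefringence(loc, wrap_margin=0.02).mask[0, 0, 0]

    def test_requires_local_volume(self):
        vol = constant_volume((4, 1, 1), np.eye(2, dtype=complex))
        with pytest.raises(ValueError):
            bf.local_birefringence(vol)


class TestBiasTable:
    def test_high_snr_consistency(self, bias_table):
        k = int(np.argwhere(bias_table.snr_grid_db == 40.0)[0, 0])
        i = int(np.argmin(np.abs(bias_table.retardance_grid - 1.0)))
        true_r = bias_table.retardance_grid[i]
        assert abs(bias_table.mean_measured[k, i] - true_r) < 0.02

    def test_zero_retardance_positive_bias_at_low_snr(self, bias_table):
        assert np.all(bias_table.mean_measured[:, 0] > 0.0)

    def test_monotone_in_true_retardance(self, bias_table):
        for row in bias_table.mean_measured:
            assert np.all(np.diff(row) > -5e-3)

    def test_deterministic_given_seed(self):
        t1 = bf.build_bias_table(n_draws=1000, rng_seed=9)
        t2 = bf.build_bias_table(n_draws=1000, rng_seed=9)
        assert np.array_equal(t1.mean_measured, t2.mean_measured)

    def test_rejects_too_few_draws(self):
        with pytest.raises(ValueError):
            bf.build_bias_table(n_draws=10)


class TestBiasCorrection:
    def test_inverse_of_forward_identity(self, bias_table):
        # measured exactly on the table -> inversion returns the truth
        snr = 15.0
        k = int(np.argwhere(bias_table.snr_grid_db == snr)[0, 0])
        true_r = bias_table.retardance_grid[5:15]
        measured = bias_table.mean_measured[k, 5:15]
        rec = bias_table.invert(measured, np.full_like(measured, snr))
        assert np.allclose(rec, true_r, atol=0.02)

    def test_below_bias_floor_maps_to_zero(self, bias_table):
        out = bias_table.invert(np.array([1e-4]), np.array([10.0]))
        assert out[0] == 0.0

    def test_high_snr_near_identity(self, bias_table):
        wavelength, dz = 1.31e-6, 49e-6
        dn_val = 1.5e-3
        shape = (4, 4, 1)
        dn = bf.ScalarMap(np.full(shape, dn_val), np.ones(shape, bool))
        snr = bf.ScalarMap(np.full(shape, 40.0), np.ones(shape, bool))
        out = bf.apply_bias_correction(dn, snr, bias_table, wavelength, dz)
        assert np.allclose(out.values, dn_val, rtol=0.05)

    def test_corrected_closer_to_truth_at_15db(self, bias_table):
        truth = 1.0e-3
        err_u, err_c = [], []
        for seed in range(3):
            spec = syn.PhantomSpec(dims=(48, 48, 2), birefringence=truth, snr_db=15.0, rng_seed=seed)
            vol = syn.simulate_jones_volume(spec)
            ru = bf.process_volume(vol, bf.PipelineConfig(bias_correction=False))
            rc = bf.process_volume(vol, bf.PipelineConfig(), bias_table=bias_table)
            err_u.append(abs(ru["mean_birefringence"] - truth))
            err_c.append(abs(rc["mean_birefringence"] - truth))
        assert np.mean(err_c) < np.mean(err_u)


class TestDoau:
    def test_uniform_axes_give_unity(self):
        spec = syn.PhantomSpec(dims=(30, 30, 1), birefringence=1.5e-3, snr_db=None, rng_seed=0)
        loc = bf.local_jones(syn.simulate_jones_volume(spec), 8)
        d = bf.doau_map(loc, (5, 21))
        assert d.mask.all()
        assert np.all(np.abs(d.values - 1.0) < 1e-9)

    def test_random_axes_resultant_length(self):
        # i.i.d. axes uniform on the sphere, kernel of N=105 pixels:
        # E[DOAU^2] = 1/N so the mean is near 1/sqrt(105) ~ 0.098
        spec = syn.PhantomSpec(
            dims=(48, 64, 2), birefringence=1.5e-3, axis="random",
            snr_db=None, guard_separation_pixels=1, rng_seed=3,
        )
        loc = bf.local_jones(syn.simulate_jones_volume(spec), 1)
        d = bf.doau_map(loc, (5, 21))
        interior = d.values[2:-2, 10:-10]
        assert 0.06 < interior.mean() < 0.14

    def test_values_in_unit_interval(self):
        spec = syn.PhantomSpec(dims=(24, 24, 1), birefringence=1.5e-3, axis="random",
                               snr_db=20.0, guard_separation_pixels=1, rng_seed=7)
        loc = bf.local_jones(syn.simulate_jones_volume(spec), 1)
        d = bf.doau_map(loc, (5, 21))
        assert np.all(d.values >= 0.0) and np.all(d.values <= 1.0)

    def test_monotone_under_vmf_concentration(self):
        means = []
        for kappa in (0.0, 3.0, 10.0, 50.0):
            spec = syn.PhantomSpec(
                dims=(40, 40, 1), birefringence=1.5e-3,
                axis=("vmf", np.array([1.0, 0.0, 0.0]), kappa),
                snr_db=None, guard_separation_pixels=1, rng_seed=5,
            )
            loc = bf.local_jones(syn.simulate_jones_volume(spec), 1)
            d = bf.doau_map(loc, (5, 21))
            means.append(d.values[2:-2, 10:-10].mean())
        assert np.all(np.diff(means) > 0)

    def test_two_domain_boundary_dip(self):
        spec = syn.PhantomSpec(
            dims=(30, 40, 1), birefringence=1.5e-3,
            axis=("two_domain", [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], 20),
            snr_db=None, rng_seed=1,
        )
        loc = bf.local_jones(syn.simulate_jones_volume(spec), 8)
        d = bf.doau_map(loc, (5, 21))
        assert d.values[10, 3, 0] > 0.999
        assert d.values[10, 37, 0] > 0.999
        assert d.values[10, 20, 0] < 0.8


class TestMeanBirefringence:
    def _maps(self, shape, dn=1.5e-3, snr=30.0, doau=1.0):
        ones = np.ones(shape, bool)
        return (
            bf.ScalarMap(np.full(shape, dn), ones.copy()),
            bf.ScalarMap(np.full(shape, snr), ones.copy()),
            bf.ScalarMap(np.full(shape, doau), ones.copy()),
        )

    def test_all_pass_constant(self, default_config):
        dn, snr, doau = self._maps((4, 4, 1))
        mean, n = bf.mean_birefringence(dn, snr, doau, default_config)
        assert mean == pytest.approx(1.5e-3)
        assert n == 16

    def test_half_fail_snr_matches_brute_force(self, default_config):
        dn, snr, doau = self._maps((4, 4, 2))
        rng = np.random.default_rng(0)
        dn.values[:] = rng.uniform(1e-3, 2e-3, size=dn.values.shape)
        snr.values[:2] = 5.0  # below threshold
        mean, n = bf.mean_birefringence(dn, snr, doau, default_config)
        sel = snr.values > default_config.snr_threshold_db
        assert n == int(sel.sum())
        assert mean == pytest.approx(dn.values[sel].mean())

    def test_planted_low_snr_stripe_count(self, default_config):
        dn, snr, doau = self._maps((10, 10, 1))
        snr.values[:, 3:5] = 0.0  # 20-pixel stripe fails SNR
        _, n = bf.mean_birefringence(dn, snr, doau, default_config)
        assert n == 80

    def test_filters_commute(self, default_config):
        dn, snr, doau = self._maps((6, 6, 1))
        rng = np.random.default_rng(1)
        snr.values[:] = rng.uniform(0, 40, size=snr.values.shape)
        doau.values[:] = rng.uniform(0.5, 1.0, size=doau.values.shape)
        m1 = (snr.values > 10) & (doau.values > 0.9)
        m2 = (doau.values > 0.9) & (snr.values > 10)
        assert np.array_equal(m1, m2)
        mean, n = bf.mean_birefringence(dn, snr, doau, default_config)
        assert n == int(m1.sum())

    def test_no_survivors_raises_with_counts(self, default_config):
        dn, snr, doau = self._maps((3, 3, 1), snr=0.0)
        with pytest.raises(bf.MaskError) as exc:
            bf.mean_birefringence(dn, snr, doau, default_config)
        assert exc.value.counts["snr_pass"] == 0
        assert exc.value.counts["valid"] == 9


class TestEndToEnd:
    def test_separation_consistency_noiseless(self):
        spec = syn.PhantomSpec(dims=(48, 16, 1), birefringence=1.5e-3, snr_db=None, rng_seed=0)
        vol = syn.simulate_jones_volume(spec)
        means = []
        for sep in (8, 16):
            cfg = bf.PipelineConfig(separation_pixels=sep, bias_correction=False)
            means.append(bf.process_volume(vol, cfg)["mean_birefringence"])
        assert abs(means[0] - means[1]) < 1e-5

    def test_homogeneous_recovery_within_5pct(self, bias_table, default_config):
        for truth in (1.0e-3, 3.0e-3):
            spec = syn.PhantomSpec(dims=(48, 48, 2), birefringence=truth, snr_db=30.0, rng_seed=11)
            vol = syn.simulate_jones_volume(spec)
            res = bf.process_volume(vol, default_config, bias_table=bias_table)
            assert abs(res["mean_birefringence"] - truth) / truth < 0.05
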