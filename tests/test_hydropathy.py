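"""Hydropathic moments, ± decomposition, slopes, couplings, and envelopes."""

import numpy as np
import pytest
from scipy.integrate import cumulative_trapezoid

from porescale.hydropathy import (EnvelopeFit, MomentProfile,
                                  coupling_and_susceptibility, decompose,
                                  fit_wavepacket_envelope, log_slopes,
                                  moments, scaling_exponents)
from porescale.packing_model import (PackingFit, PackingParameters,
                                     epsilon, fit_packing, FitConfig)
from porescale.pore_geometry import build_scale_grid, radial_profile
from porescale.structure_io import MolecularStructure


def _cloud(coords, weights):
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    w = np.asarray(weights, dtype=float)
    return MolecularStructure(
        serial=np.arange(1, n + 1),
        name=np.where(w > 0, "O", "C").astype("U6"),
        res_name=np.where(w > 0, "PHI", "PHO").astype("U5"),
        chain=np.full(n, "A", dtype="U4"), res_seq=np.arange(1, n + 1),
        coords=coords, weight=w)


def _analytic_profile(l_values, plus, minus, order=2):
    """A decomposed profile carrying constructed smooth ± traces."""
    prof = MomentProfile(order=order,
                         parity="even" if order % 2 == 0 else "odd",
                         trace=plus + minus, philic_trace=plus,
                         phobic_trace=minus)
    prof.plus_trace, prof.minus_trace = plus, minus
    prof.valid = np.ones(len(l_values), dtype=bool)
    prof.l_cutoff = float(l_values[0])
    prof.case_label = "A"
    prof.decomposable = True
    return prof


class TestMoments:
    def test_single_atom_values(self):
        s = _cloud([[2.0, 0.0, 0.0]], [-0.5])
        mset = moments(s, np.zeros(3), np.array([1.0, 3.0]), sigma_iota=0.0)
        assert mset[0].trace.tolist() == [0.0, -0.5]
        assert mset[2].trace.tolist() == [0.0, -2.0]
        assert mset.counts.tolist() == [0, 1]

    def test_antipodal_pair_cancels_dipole(self):
        s = _cloud([[0, 0, 4.0], [0, 0, -4.0]], [0.5, 0.5])
        mset = moments(s, np.zeros(3), np.array([5.0]), sigma_iota=0.0)
        assert np.allclose(mset[1].trace, 0.0)
        assert np.allclose(mset[1].trace_para, 0.0)
        # even moment adds up instead
        assert np.isclose(mset[0].trace[0], 1.0)

    def test_incremental_matches_brute_force(self):
        rng = np.random.default_rng(3)
        coords = rng.uniform(-15, 15, (1000, 3))
        weights = rng.choice([-0.5, 0.5], 1000)
        s = _cloud(coords, weights)
        p = np.array([0.3, -0.2, 0.1])
        l_values = np.linspace(1.0, 30.0, 40)
        sigma = 1e-3
        mset = moments(s, p, l_values, sigma_iota=sigma, seed=9)
        # replicate the per-atom noise draw (one ι per atom, radius order)
        rel = coords - p
        r = np.linalg.norm(rel, axis=1)
        order = np.argsort(r, kind="stable")
        w_noisy = weights[order] + \
            np.random.default_rng(9).normal(0, sigma, 1000)
        rs, rels = r[order], rel[order]
        for j in (0, 2, 4):
            brute = np.array([(rs[rs < l] ** j * w_noisy[rs < l]).sum()
                              for l in l_values])
            np.testing.assert_allclose(mset[j].trace, brute, rtol=1e-10)
        for j in (1, 3):
            brute = np.array([(rs[rs < l] ** (j - 1) * rels[rs < l, 2]
                               * w_noisy[rs < l]).sum() for l in l_values])
            np.testing.assert_allclose(mset[j].trace, brute, rtol=1e-10,
                                       atol=1e-12)

    def test_empty_ball_yields_zeros(self):
        s = _cloud([[5.0, 0.0, 0.0]], [0.5])
        mset = moments(s, np.zeros(3), np.array([1.0, 2.0]), sigma_iota=0.0)
        assert np.allclose(mset[3].trace, 0.0)

    def test_requires_weights(self, small_cloud):
        s = small_cloud[0].copy()
        s.weight = np.full(s.n_total, np.nan)
        with pytest.raises(ValueError, match="weights"):
            moments(s, np.zeros(3), np.array([5.0]))

    def test_magnitude_bound(self):
        rng = np.random.default_rng(4)
        coords = rng.uniform(-10, 10, (500, 3))
        weights = rng.choice([-0.5, 0.5], 500)
        s = _cloud(coords, weights)
        l_values = np.linspace(1.0, 20.0, 30)
        mset = moments(s, np.zeros(3), l_values, sigma_iota=1e-3, seed=0)
        r = np.sort(np.linalg.norm(coords, axis=1))
        for j in (0, 2, 5):
            bound = np.array([(r[r < l] ** j * 0.51).sum()
                              for l in l_values])
            assert np.all(np.abs(mset[j].trace) <= bound + 1e-12)

    def test_noise_robustness_of_h0(self):
        rng = np.random.default_rng(5)
        coords = rng.uniform(-10, 10, (2000, 3))
        weights = rng.choice([-0.5, 0.5], 2000)
        s = _cloud(coords, weights)
        l_values = np.array([25.0])
        clean = moments(s, np.zeros(3), l_values, sigma_iota=0.0)
        for seed in range(5):
            noisy = moments(s, np.zeros(3), l_values, sigma_iota=1e-3,
                            seed=seed)
            assert abs(noisy[0].trace[0] - clean[0].trace[0]) \
                <= 3 * 1e-3 * np.sqrt(2000)


class TestDecompose:
    def test_even_orders_split_exactly_without_noise(self):
        rng = np.random.default_rng(6)
        coords = rng.uniform(-10, 10, (400, 3))
        weights = rng.choice([-0.5, 0.5], 400)
        s = _cloud(coords, weights)
        l_values = np.linspace(1.0, 20.0, 50)
        mset = decompose(moments(s, np.zeros(3), l_values, sigma_iota=0.0))
        for j in (0, 2, 4):
            prof = mset[j]
            assert prof.case_label == "A"
            np.testing.assert_allclose(
                prof.trace, prof.plus_trace + prof.minus_trace,
                rtol=1e-12, atol=1e-10)

    def test_single_sign_cloud_flagged_degenerate(self):
        s = _cloud([[1.0, 0, 0], [2.0, 0, 0]], [-0.5, -0.5])
        mset = decompose(moments(s, np.zeros(3), np.array([3.0]),
                                 sigma_iota=0.0))
        assert not mset[0].decomposable
        assert mset[0].case_label == "degenerate"

    def test_core_shell_cloud_is_case_a_beyond_core(self):
        rng = np.random.default_rng(7)
        # hydrophobic core and hydrophilic shell, both displaced toward +z
        def shell(n, r_lo, r_hi):
            d = rng.normal(size=(n, 3))
            d[:, 2] = np.abs(d[:, 2]) + 0.5     # +z bias
            d /= np.linalg.norm(d, axis=1, keepdims=True)
            return d * rng.uniform(r_lo, r_hi, n)[:, None]
        coords = np.vstack([shell(200, 1.0, 5.0), shell(200, 8.0, 12.0)])
        weights = np.r_[np.full(200, -0.5), np.full(200, 0.5)]
        s = _cloud(coords, weights)
        l_values = np.linspace(0.5, 13.0, 100)
        mset = decompose(moments(s, np.zeros(3), l_values, sigma_iota=0.0))
        prof = mset[1]
        assert prof.decomposable
        assert prof.case_label == "A"
        assert prof.l_cutoff >= 5.0  # not before the philic shell begins


class TestLogSlopes:
    def test_power_law_slope_is_exact(self):
        l = np.linspace(1.0, 10.0, 400)
        prof = _analytic_profile(l, 2.0 * l ** 3, -0.7 * l ** 3)
        psi_p, psi_m = log_slopes(prof, l, smooth_window=0)
        assert np.allclose(psi_p, 3.0, atol=1e-9)
        assert np.allclose(psi_m, 3.0, atol=1e-9)

    def test_constant_trace_has_zero_slope(self):
        l = np.linspace(1.0, 10.0, 100)
        prof = _analytic_profile(l, np.full(100, 2.0), np.full(100, -1.0))
        psi_p, psi_m = log_slopes(prof, l, smooth_window=0)
        assert np.allclose(psi_p, 0.0, atol=1e-12)
        assert np.allclose(psi_m, 0.0, atol=1e-12)

    def test_oscillatory_perturbation_stays_near_base_slope(self):
        # a 1% multiplicative ripple perturbs the log-slope by ~0.01·l·cos l
        l = np.linspace(2.0, 5.0, 800)
        prof = _analytic_profile(l, l ** 2.5 * (1 + 0.01 * np.sin(l)),
                                 -l ** 1.0)
        psi_p, _ = log_slopes(prof, l, smooth_window=5)
        assert np.all(np.abs(psi_p - 2.5) < 0.05)

    def test_sign_violation_rejected(self):
        l = np.linspace(1.0, 10.0, 50)
        plus = l.copy()
        plus[20] = -1.0
        prof = _analytic_profile(l, plus, -l)
        with pytest.raises(ValueError, match="sign violation"):
            log_slopes(prof, l)


class TestCouplingAndSusceptibility:
    def test_balanced_components_have_zero_susceptibility(self):
        l = np.linspace(1.0, 10.0, 200)
        h = 1.3 * l ** 2
        prof = _analytic_profile(l, h, -h)
        log_slopes(prof, l, smooth_window=0)
        I, chi, phi = coupling_and_susceptibility(prof, l)
        assert np.allclose(phi, 0.0, atol=1e-12)
        assert np.allclose(chi, 1.0)
        assert np.allclose(I, 0.0, atol=1e-9)

    def test_closed_form_powers(self):
        l = np.linspace(1.0, 20.0, 400)
        prof = _analytic_profile(l, l ** 2, -l)
        log_slopes(prof, l, smooth_window=0)
        I, chi, phi = coupling_and_susceptibility(prof, l)
        assert np.allclose(prof.delta_psi, 1.0, atol=1e-9)
        assert np.allclose(I, 1.0 / l, atol=1e-9)
        assert np.allclose(phi, np.log(l))

    def test_integral_matches_endpoint_difference(self):
        l = np.linspace(2.0, 30.0, 800)
        prof = _analytic_profile(l, 3.0 * l ** 2.2,
                                 -0.5 * l ** 1.3 * (1 + 0.1 * np.sin(l)))
        log_slopes(prof, l, smooth_window=0)
        I, _, phi = coupling_and_susceptibility(prof, l)
        integral = cumulative_trapezoid(I, l, initial=0.0)
        assert np.max(np.abs((phi - phi[0]) - integral)) < 1e-3


class TestScalingExponents:
    @staticmethod
    def _fit_covering(l_values):
        params = PackingParameters(zeta=5.0, xi=10.0, capacity=1000.0,
                                   n0=10.0, l0=float(l_values[0]) - 0.01)
        mid = float(l_values[len(l_values) // 2])
        return PackingFit(params=params, l_i=mid, l_ib=mid, l_gt=float(
            l_values[-1]), eps_i=1.0, mae=0.0, converged=True)

    def test_pure_power_law(self):
        l = np.linspace(1.0, 20.0, 500)
        fit = self._fit_covering(l)
        se = scaling_exponents(l ** 3, fit, l)
        assert np.isclose(se.eta_lt, 3.0)
        assert np.isclose(se.eta_gt, 3.0)
        assert np.isclose(se.pearson_lt, 1.0)

    def test_sign_alternating_trace_uses_magnitude(self):
        l = np.linspace(1.0, 20.0, 500)
        fit = self._fit_covering(l)
        trace = l ** 2 * np.sign(np.sin(7 * l))
        trace[3] = 0.0  # zeros masked
        se = scaling_exponents(trace, fit, l)
        assert np.isclose(se.eta_lt, 2.0, atol=1e-6)

    def test_too_few_points_yield_nan(self):
        l = np.linspace(1.0, 20.0, 500)
        fit = self._fit_covering(l)
        trace = np.zeros(500)
        trace[:3] = 1.0
        with pytest.warns(UserWarning, match="exponent undefined"):
            se = scaling_exponents(trace, fit, l)
        assert np.isnan(se.eta_gt)

    def test_aligned_dipole_scales_with_high_correlation(self):
        rng = np.random.default_rng(8)
        n = 4000
        d = rng.normal(size=(n, 3))
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        radii = rng.uniform(1.0, 40.0, n) ** 1.0
        coords = d * radii[:, None]
        # radially aligned hydropathic dipoles: sign follows the z side
        weights = np.where(coords[:, 2] > 0, 0.5, -0.5)
        s = _cloud(coords, weights)
        prof = radial_profile(s, np.zeros(3))
        grid = build_scale_grid(prof, 400)
        fit = fit_packing(prof, grid, FitConfig(seed=0))
        mset = moments(s, np.zeros(3), grid, sigma_iota=0.0)
        se = scaling_exponents(np.abs(mset[1].trace), fit, grid)
        assert se.eta_lt > 0
        assert se.pearson_lt > 0.9


class TestWavepacketEnvelope:
    @staticmethod
    def _setup(kappa, s=10.0, order=0):
        l = np.linspace(2.0, 30.0, 800)
        params = PackingParameters(zeta=5.0, xi=10.0, capacity=1000.0,
                                   n0=10.0, l0=1.0)
        fit = PackingFit(params=params, l_i=15.0, l_ib=15.0, l_gt=25.0,
                         eps_i=1.0, mae=0.0, converged=True)
        counts = np.full(len(l), 100.0)
        amp = (1 + kappa * params.xi / s) * epsilon(params, l) / l ** order
        trace = counts * amp * np.cos(np.pi * l / 5.0)
        return l, fit, counts, trace

    def test_recovers_adsorption_correction(self):
        l, fit, counts, trace = self._setup(kappa=0.2)
        env = fit_wavepacket_envelope(trace, counts, fit, l, order=0, s=10.0)
        assert env.kappa is not None
        assert abs(env.kappa - 0.2) / 0.2 < 0.10

    def test_zero_correction_bounded_by_energy(self):
        l, fit, counts, trace = self._setup(kappa=0.0)
        assert np.all(np.abs(trace) / counts
                      <= epsilon(fit.params, l) + 1e-12)

    def test_large_system_amplitude_approaches_energy(self):
        # s → ∞ removes the finite-size correction: A_0 → ε
        l, fit, counts, trace = self._setup(kappa=0.2, s=1e12)
        env = fit_wavepacket_envelope(trace, counts, fit, l, order=0,
                                      s=1e12)
        assert np.allclose(env.amplitude_trace, epsilon(fit.params, l),
                           rtol=0.05)

    def test_too_few_peaks_leave_kappa_undefined(self):
        l = np.linspace(2.0, 30.0, 800)
        _, fit, counts, _ = self._setup(kappa=0.1)
        trace = counts * epsilon(fit.params, l)  # monotone: no peaks
        env = fit_wavepacket_envelope(trace, counts, fit, l, order=0)
        assert env.kappa is None
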