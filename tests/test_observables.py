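"""Estimator correctness on synthetic data with independent oracles."""

import numpy as np
import pytest

from plectosim.constraint_dynamics import JointSet
from plectosim.model_state import InvalidParameterError, make_free_chain
from plectosim import observables as obs


class TestCountDof:
    def test_single_free_body(self):
        assert obs.count_dof(JointSet.empty(), 1) == 6

    def test_free_chain(self):
        st = make_free_chain(10, radius=0.3)
        js = JointSet.serial_chain(st)
        assert obs.count_dof(js, 10) == 3 * 10 + 3

    def test_anchored_four_chain_enumeration(self):
        # 4 bodies, 4 ball joints (incl. anchor): 24 - 12 = 12
        st = make_free_chain(4, radius=0.3, origin=(0, 0, 1))
        js = JointSet.serial_chain(st, anchor="ball")
        assert obs.count_dof(js, 4) == 12


class TestKineticEnergyStats:
    def test_exact_gamma_samples_pass(self, rng):
        ndof = 60
        e = rng.gamma(ndof / 2, scale=1.0, size=4000)
        ks = obs.kinetic_energy_stats(e, ndof)
        assert ks.p_value > 0.01
        assert ks.mean_ratio == pytest.approx(1.0, rel=0.03)

    def test_wrong_dof_detected(self, rng):
        # sensitivity control: n_dof off by 3 shifts the mean ratio
        ndof = 30
        e = rng.gamma(ndof / 2, scale=1.0, size=20000)
        ks = obs.kinetic_energy_stats(e, ndof - 3)
        assert abs(ks.mean_ratio - 1.0) > 0.02

    def test_short_series_rejected(self):
        with pytest.raises(InvalidParameterError):
            obs.kinetic_energy_stats(np.ones(5), 10)


class TestAutocorrelation:
    def test_constant_series(self):
        c = obs.autocorrelation(np.full(100, 2.5), 10)
        np.testing.assert_allclose(c, 1.0)
        np.testing.assert_allclose(1.0 - c, 0.0)

    def test_white_noise_uncorrelated(self, rng):
        x = rng.standard_normal(20000)
        c = obs.autocorrelation(x, 50)
        assert c[0] == pytest.approx(1.0)
        assert np.max(np.abs(c[1:])) < 5 / np.sqrt(20000)

    def test_ou_relaxation_time_recovered(self, rng):
        # synthetic OU process with known correlation time
        tau, dt, n = 20.0, 1.0, 400000
        a = np.exp(-dt / tau)
        x = np.empty(n)
        x[0] = 0.0
        noise = rng.standard_normal(n) * np.sqrt(1 - a * a)
        for i in range(1, n):
            x[i] = a * x[i - 1] + noise[i]
        c = obs.autocorrelation(x, 200)
        fit = obs.fit_relaxation_time(c, dt_lag=dt)
        assert fit.tau == pytest.approx(tau, rel=0.1)

    def test_mean_with_autocorr_se_white_noise(self, rng):
        x = rng.standard_normal(10000)
        m, se, neff = obs.mean_with_autocorr_se(x)
        # neff ~ n for white noise
        assert neff > 2500
        assert se == pytest.approx(1 / np.sqrt(neff), rel=0.2)


class TestTangentCorrelation:
    def test_rigid_rod(self):
        t = np.tile([0.0, 0.0, 1.0], (3, 20, 1))
        c = obs.tangent_correlation(t)
        np.testing.assert_allclose(c, 1.0)

    def test_s_zero_is_one(self, rng):
        t = rng.standard_normal((5, 30, 3))
        t /= np.linalg.norm(t, axis=2, keepdims=True)
        assert obs.tangent_correlation(t)[0] == 1.0

    def test_boltzmann_sampler_recovers_lp(self):
        # frames drawn from the discrete chain Boltzmann weight at known g_b
        from plectosim.dna_elasticity import calibrate_rigidity
        from plectosim.tweezers import _sample_vmf

        local = np.random.default_rng(88)
        lp = 10.0
        g = calibrate_rigidity(lp)
        frames = []
        for _ in range(1200):
            t = np.array([0.0, 0.0, 1.0])
            chain = [t]
            for _ in range(39):
                t = _sample_vmf(chain[-1], g, local)
                chain.append(t)
            frames.append(chain)
        corr = obs.tangent_correlation(np.asarray(frames))
        got = obs.fit_persistence_length(corr)
        assert got == pytest.approx(lp, rel=0.05)


class TestTwistWrithe:
    def test_planar_untwisted_chain(self):
        st = make_free_chain(10, radius=0.3)
        tw, wr = obs.twist_writhe(st, np.zeros(9))
        assert tw == 0.0
        assert abs(wr) < 1e-9

    def test_overtwist_arithmetic(self):
        assert obs.overtwist(15.0, 300.0) == pytest.approx(0.05)
        with pytest.raises(InvalidParameterError):
            obs.overtwist(1.0, 0.0)

    def test_writhe_of_circular_helix_against_quadrature(self):
        # closed circular curve with a superimposed wobble: writhe from the
        # segment-pair formula vs direct numerical Gauss double integral
        n = 200
        s = np.linspace(0, 2 * np.pi, n, endpoint=False)
        R0, amp, k = 5.0, 0.8, 4
        curve = np.column_stack([
            (R0 + amp * np.cos(k * s)) * np.cos(s),
            (R0 + amp * np.cos(k * s)) * np.sin(s),
            amp * np.sin(k * s)])
        closed = np.vstack([curve, curve[:1]])
        got = obs.writhe_polyline(closed, closure="none")
        # oracle: discrete Gauss double integral over tangent samples
        dr = np.diff(closed, axis=0)
        mid = 0.5 * (closed[:-1] + closed[1:])
        acc = 0.0
        for i in range(n):
            d = mid[i] - mid
            r3 = np.linalg.norm(d, axis=1) ** 3
            cr = np.cross(dr[i], dr)
            contrib = np.einsum("ij,ij->i", cr, d)
            mask = r3 > 1e-12
            acc += np.sum(contrib[mask] / r3[mask])
        oracle = acc / (4 * np.pi)
        assert got == pytest.approx(oracle, abs=0.02)

    def test_open_curve_requires_closure(self):
        v = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0.0]])
        with pytest.raises(InvalidParameterError):
            obs.writhe_polyline(v, closure="none")


class TestReferenceCurves:
    def test_langevin_value_at_three(self):
        assert obs.fjc_extension(3.0) == pytest.approx(
            1 / np.tanh(3.0) - 1 / 3.0, rel=1e-12)
        assert obs.fjc_extension(3.0) == pytest.approx(0.6716, abs=5e-4)

    def test_zero_force_zero_extension(self):
        assert obs.fjc_extension(0.0) == 0.0

    def test_wlc_low_force_limit(self):
        # f ~ (3 kBT / 2 l_p) z for z < 0.1
        lp = 20.0
        for z in (0.02, 0.05, 0.1):
            f = obs.wlc_interpolation_force(z, lp)
            assert f == pytest.approx(1.5 * z / lp, rel=0.05)

    def test_wlc_domain_error(self):
        with pytest.raises(InvalidParameterError):
            obs.wlc_interpolation_force(1.0, 10.0)

    def test_wlc_inverse_round_trip(self):
        lp = 14.7
        for f in (0.2, 1.0, 4.0):
            z = obs.wlc_extension(f, lp)
            assert obs.wlc_interpolation_force(z, lp) == pytest.approx(
                f, rel=1e-9)


class TestHatCurveAnalysis:
    def test_noiseless_line_recovered_exactly(self):
        n = np.array([0.0, 1, 2, 3, 4, 5, 6])
        z = 10.0 - 0.5 * n
        assert obs.hat_curve_slope(n, z) == pytest.approx(-0.5, rel=1e-12)

    def test_no_linear_region_raises(self):
        with pytest.raises(InvalidParameterError):
            obs.hat_curve_slope([0.0, 1.0], [1.0, 1.0])

    def test_supercoil_relation_round_trip(self):
        R, alpha = 1.6, 0.9
        q = obs.supercoil_relation(R, alpha, rel_ext=0.8)
        R2, _ = obs.invert_supercoil_relation(q, alpha=alpha, rel_ext=0.8)
        assert R2 == pytest.approx(R, rel=1e-6)
        _, a2 = obs.invert_supercoil_relation(q, R=R, rel_ext=0.8)
        assert a2 == pytest.approx(alpha, rel=1e-6) or \
            a2 == pytest.approx(np.pi / 2 - alpha, rel=1e-6)

    def test_plectoneme_geometry_on_synthetic_superhelix(self):
        # two interwound helices with known radius and helical angle
        from plectosim.tweezers import chain_from_vertices
        from plectosim.model_state import ChainState

        Rsh, alpha = 1.5, 0.55
        pitch_rate = Rsh / np.tan(alpha)  # dz/dphi for helix angle alpha
        npts = 60
        phis = np.arange(npts) * 0.35
        up = np.column_stack([Rsh * np.cos(phis), Rsh * np.sin(phis),
                              pitch_rate * phis])
        down = np.column_stack([-Rsh * np.cos(phis), -Rsh * np.sin(phis),
                                pitch_rate * phis])[::-1]
        verts = np.vstack([up, down])
        # resample to equal-length segments
        seg = np.linalg.norm(np.diff(verts, axis=0), axis=1)
        t = np.concatenate([[0], np.cumsum(seg)])
        L = t[-1]
        m = int(L)
        tt = np.linspace(0, t[-1], m + 1)
        res = np.column_stack([np.interp(tt, t, verts[:, k])
                               for k in range(3)])
        seg2 = np.linalg.norm(np.diff(res, axis=0), axis=1)
        res_scaled = res / np.mean(seg2)
        # force exactly equal segment lengths by walking the polyline
        state = chain_from_vertices(
            _equalize(res_scaled), radius=0.55)
        geo = obs.estimate_plectoneme_geometry(state)
        assert geo.n_pairs > 5
        assert geo.R == pytest.approx(Rsh / np.mean(seg2), rel=0.25)
        assert geo.alpha == pytest.approx(alpha, abs=0.2)


def _equalize(verts, step=1.0):
    """Resample a polyline at exactly unit arc steps (chord stepping)."""
    out = [verts[0]]
    i = 0
    p = verts[0].copy()
    while i < len(verts) - 1:
        d = verts[i + 1] - p
        dist = np.linalg.norm(d)
        if dist >= step:
            p = p + d / dist * step
            out.append(p.copy())
        else:
            i += 1
    return np.asarray(out)


class TestBucklingAnalysis:
    def test_telegraph_process_dwell_fractions(self, rng):
        # two-state telegraph + noise: recover dwell fractions within 5%
        n = 20000
        state = np.zeros(n, dtype=int)
        p01, p10 = 0.01, 0.02  # stationary occupancy of state 1: 1/3
        s = 0
        for i in range(n):
            if s == 0 and rng.random() < p01:
                s = 1
            elif s == 1 and rng.random() < p10:
                s = 0
            state[i] = s
        z = np.where(state == 1, 0.2, 0.8) + 0.03 * rng.standard_normal(n)
        sig = np.where(state == 1, 0.05, 0.01) + 0.003 * rng.standard_normal(n)
        st = obs.buckling_analysis(z, sig)
        assert st.bimodal
        frac_high_z = st.dwell_fractions[1]  # state 0 has high z
        assert frac_high_z == pytest.approx(np.mean(state == 0), abs=0.05)
        assert st.correlation_z_sigma < 0

    def test_affine_law_noiseless(self):
        sigma = np.linspace(0.02, 0.1, 9)
        xi_p, sigma_star = 6.2, 0.013
        torque = 2 * np.pi * xi_p * (sigma - sigma_star)  # pitch = 1, kBT = 1
        got_xi, got_ss = obs.fit_affine_torque_law(sigma, torque)
        assert got_xi == pytest.approx(xi_p, rel=1e-9)
        assert got_ss == pytest.approx(sigma_star, rel=1e-9)

    def test_critical_torque_from_variance_peak(self):
        g = np.array([2.0, 4.0, 6.0, 8.0, 10.0])
        v = np.array([0.1, 0.4, 1.0, 0.5, 0.2])
        gc, err = obs.estimate_critical_torque(g, v)
        assert gc == pytest.approx(6.0, abs=1.0)

    def test_unimodal_flagged(self):
        with pytest.warns(UserWarning):
            obs.estimate_critical_torque([1.0, 2.0, 3.0], [0.1, 0.2, 0.3])


class TestObservableSeries:
    def test_validation(self):
        with pytest.raises(InvalidParameterError):
            obs.ObservableSeries("x", np.array([0.0, 1.0]), np.zeros(3))
        with pytest.raises(InvalidParameterError):
            obs.ObservableSeries("x", np.array([0.0, 0.0]), np.zeros(2))
        s = obs.ObservableSeries("ok", np.array([0.0, 1.0]),
                                 np.array([1.0, 2.0]))
        assert s.name == "ok"
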