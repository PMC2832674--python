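"""Diffusion analysis: MSD, anomality exponents, fits, viscosities."""

import numpy as np
import pytest
from scipy.special import exp1

import crowdbd as c
from crowdbd.diffusion import (AlphaFit, DiffusionSeries,
                               LiteratureViscosityParams, alpha_model,
                               anomality_exponent, default_interval_schedule,
                               dtrans_vs_interval,
                               extrapolate_long_time_dtrans, fit_alpha_model,
                               fit_rotational_model, literature_hsa_viscosity,
                               log_midpoints, msd, rotational_acf,
                               rotational_model, viscosity_ratios)
from crowdbd.trajio import Trajectory


def _traj_from_positions(times, positions, label="x", box=1e6):
    T, M, _ = positions.shape
    rots = np.tile(np.eye(3), (T, M, 1, 1))
    return Trajectory(np.asarray(times, float), positions, rots,
                      [label] * M, box)


# --------------------------------------------------------------------- MSD

class TestMsd:
    def test_static_zero(self):
        pos = np.zeros((10, 3, 3))
        traj = _traj_from_positions(100.0 * np.arange(10), pos)
        for dt in (100.0, 500.0):
            assert msd(traj, "x", dt) == 0.0

    def test_ballistic_closed_form(self):
        v = 0.013
        t = 100.0 * np.arange(20)
        pos = np.zeros((20, 1, 3))
        pos[:, 0, 0] = v * t
        traj = _traj_from_positions(t, pos)
        for dt in (100.0, 300.0, 700.0):
            assert msd(traj, "x", dt) == pytest.approx(v ** 2 * dt ** 2)

    def test_free_bd_einstein(self, free_sphere_trajectory):
        traj, tmpl = free_sphere_trajectory
        ratio = msd(traj, "sphere", 300.0) / (6 * tmpl.d0_trans * 300.0)
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_bad_dt_errors(self):
        traj = _traj_from_positions(100.0 * np.arange(5),
                                    np.zeros((5, 1, 3)))
        with pytest.raises(ValueError):
            msd(traj, "x", 150.0)
        with pytest.raises(ValueError):
            msd(traj, "x", 10000.0)


class TestDtransSeries:
    def test_arithmetic(self):
        # engineered so MSD(1000 ps) = 6 Å² -> D = 0.001 Å²/ps
        t = np.array([0.0, 1000.0])
        pos = np.zeros((2, 1, 3))
        pos[1, 0, 0] = np.sqrt(6.0)
        traj = _traj_from_positions(t, pos)
        s = dtrans_vs_interval(traj, "x", schedule=[1000.0])
        assert s.d_trans[0] == pytest.approx(0.001)

    def test_subdiffusive_fixture_decreasing(self):
        """Time-rescaled Brownian motion (MSD growing as t^0.8) yields a
        decreasing D(δt)."""
        rng = np.random.default_rng(6)
        t = 100.0 * np.arange(200)
        tau = (t / 100.0) ** 0.8
        inc_var = np.diff(tau)
        pos = np.zeros((200, 400, 3))
        steps = rng.normal(size=(199, 400, 3)) * np.sqrt(inc_var)[:, None, None]
        pos[1:] = np.cumsum(steps, axis=0)
        traj = _traj_from_positions(t, pos)
        s = dtrans_vs_interval(traj, "x",
                               schedule=[100, 200, 300, 600, 1000, 2000])
        assert np.all(np.diff(s.d_trans) < 0)

    def test_replicate_sd(self, free_sphere_trajectory):
        traj, _ = free_sphere_trajectory
        s = dtrans_vs_interval([traj, traj], "sphere", schedule=[100, 200])
        np.testing.assert_allclose(s.replicate_sd, 0.0, atol=1e-15)


class TestLogMidpoints:
    def test_printed_series(self):
        """The 100/200/300/600/1000 ps ladder has midpoints 141, 245,
        424, 775 ps."""
        mids = log_midpoints([100, 200, 300, 600, 1000])
        np.testing.assert_array_equal(mids, [141, 245, 424, 775])

    def test_degenerate(self):
        assert log_midpoints([50, 50])[0] == 50

    def test_schedule_generator(self):
        sched = default_interval_schedule(25000.0)
        np.testing.assert_array_equal(
            sched, [100, 200, 300, 600, 1000, 2000, 3000, 6000, 10000])


class TestAnomalityExponent:
    def test_constant_d_alpha_one(self):
        s = DiffusionSeries("x", [100, 200, 300, 600], [0.01] * 4)
        _, alpha, _ = anomality_exponent(s)
        np.testing.assert_allclose(alpha, 1.0, atol=1e-14)

    def test_exact_power_law_machine_precision(self):
        """D(δt) = c δt^(α0-1) reproduces α0 to ~machine precision."""
        alpha0 = 0.63
        dts = np.array([100.0, 200, 300, 600, 1000, 2000])
        s = DiffusionSeries("x", dts, 0.01 * dts ** (alpha0 - 1.0))
        _, alpha, _ = anomality_exponent(s)
        np.testing.assert_allclose(alpha, alpha0, atol=1e-10)

    def test_sqrt_msd_gives_half(self):
        # MSD ∝ δt^0.5 → D ∝ δt^-0.5 → α = 0.5
        dts = np.array([100.0, 200, 400, 800])
        s = DiffusionSeries("x", dts, dts ** -0.5)
        _, alpha, _ = anomality_exponent(s)
        np.testing.assert_allclose(alpha, 0.5, atol=1e-12)

    def test_nonpositive_d_errors(self):
        s = DiffusionSeries("x", [100, 200], [0.01, -0.01])
        with pytest.raises(ValueError):
            anomality_exponent(s)


class TestAlphaFit:
    GEN = dict(alpha0=1.0, a=0.3, b=0.25, tau_short=1e3, tau_long=1e6)

    def test_noiseless_parameter_recovery(self):
        """Generating parameters recovered (well within 10%) from
        noiseless data."""
        dt = np.geomspace(100, 3e6, 60)
        fit = fit_alpha_model(dt, alpha_model(dt, **self.GEN))
        for key, val in self.GEN.items():
            assert getattr(fit, key) == pytest.approx(val, rel=0.10)
        assert fit.residual < 1e-8

    def test_noisy_parameter_recovery(self):
        """With 1% noise the dominant parameters stay within 10%;
        tau_short (effective amplitude a − b = 0.05, comparable to the
        noise) is the sloppy direction and only localizes to ~35%."""
        dt = np.geomspace(100, 3e6, 100)
        rng = np.random.default_rng(8)
        y = alpha_model(dt, **self.GEN) * (1 + 0.01 * rng.normal(size=dt.size))
        fit = fit_alpha_model(dt, y)
        assert fit.alpha0 == pytest.approx(self.GEN["alpha0"], rel=0.10)
        assert fit.a == pytest.approx(self.GEN["a"], rel=0.10)
        assert fit.b == pytest.approx(self.GEN["b"], rel=0.10)
        assert fit.tau_long == pytest.approx(self.GEN["tau_long"], rel=0.10)
        assert fit.tau_short == pytest.approx(self.GEN["tau_short"], rel=0.35)

    def test_flat_alpha_gives_zero_amplitudes(self):
        dt = np.geomspace(100, 1e6, 20)
        fit = fit_alpha_model(dt, np.ones_like(dt))
        assert fit.a == pytest.approx(0.0, abs=0.02)
        assert fit.b == pytest.approx(0.0, abs=0.02)
        # and the fitted curve is flat at 1 regardless
        np.testing.assert_allclose(fit(dt), 1.0, atol=1e-3)

    def test_truncation_at_25pct_error(self):
        dt = np.geomspace(100, 1e6, 12)
        y = alpha_model(dt, 1.0, 0.3, 0.2, 1e3, 1e5)
        sd = np.full(dt.size, 0.01)
        sd[7:] = 10.0  # >25% error from here on
        fit = fit_alpha_model(dt, y, alpha_sd=sd)
        assert fit.residual < 1e-6  # fitted only the clean prefix
        with pytest.raises(ValueError):  # too few surviving points
            fit_alpha_model(dt, y, alpha_sd=np.full(dt.size, 10.0))


class TestExtrapolation:
    def _series(self, d100=0.01):
        dts = np.array([100.0, 200, 300])
        return DiffusionSeries("x", dts, np.full(3, d100))

    def test_alpha_identically_one(self):
        fit = AlphaFit(1.0, 0.0, 0.0, 1e3, 1e6, 0.0)
        d = extrapolate_long_time_dtrans(self._series(0.0123), fit)
        assert d == pytest.approx(0.0123, rel=1e-9)

    def test_single_exponential_closed_form(self):
        """α(δt) = 1 − a e^{−δt/τ}: ln D_L − ln D(100) = −a E1(100/τ)."""
        a_amp, tau = 0.2, 5e4
        fit = AlphaFit(1.0, a_amp, 0.0, tau, tau * (1 + 1e-9), 0.0)
        d = extrapolate_long_time_dtrans(self._series(0.01), fit)
        expected = 0.01 * np.exp(-a_amp * exp1(100.0 / tau))
        assert d == pytest.approx(expected, rel=1e-6)

    def test_subdiffusive_long_time_smaller(self):
        fit = AlphaFit(1.0, 0.3, 0.1, 1e3, 1e5, 0.0)
        d = extrapolate_long_time_dtrans(self._series(0.01), fit)
        assert d < 0.01


# -------------------------------------------------------------- rotational

class TestRotationalAcf:
    def test_no_rotation_is_one(self):
        rots = np.tile(np.eye(3), (10, 2, 1, 1))
        traj = Trajectory(100.0 * np.arange(10), np.zeros((10, 2, 3)),
                          rots, ["x", "x"], 1e6)
        _, theta = rotational_acf(traj, "x")
        np.testing.assert_allclose(theta, 1.0, atol=1e-14)

    def test_uniform_rotation_closed_form(self):
        """Uniform rotation about z: axis-averaged θ(δt) = (1+2cos ωδt)/3."""
        omega = 2e-3  # rad/ps
        t = 100.0 * np.arange(30)
        rots = np.empty((30, 1, 3, 3))
        for k, tk in enumerate(t):
            a = omega * tk
            rots[k, 0] = [[np.cos(a), -np.sin(a), 0],
                          [np.sin(a), np.cos(a), 0], [0, 0, 1]]
        traj = Trajectory(t, np.zeros((30, 1, 3)), rots, ["x"], 1e6)
        dts, theta = rotational_acf(traj, "x")
        np.testing.assert_allclose(theta, (1 + 2 * np.cos(omega * dts)) / 3,
                                   atol=1e-12)

    def test_free_rotor_exponential(self, free_rotor_trajectory):
        """Free Brownian rotor: θ(δt) = exp(−2 D0_rot δt) within 3 SE."""
        traj, tmpl = free_rotor_trajectory
        dts, theta = rotational_acf(traj, "sphere", max_lag=300.0)
        expected = np.exp(-2 * tmpl.d0_rot * dts)
        n_eff = traj.n_molecules  # independent molecules dominate the SE
        se = (1 - expected ** 2 + 1e-12) / np.sqrt(3 * n_eff)
        assert np.all(np.abs(theta - expected) <= 3 * se + 5e-3)


class TestRotationalFit:
    def test_pure_exponential(self):
        dts = np.linspace(0, 1e6, 200)
        theta = np.exp(-dts / 5e5)
        fit = fit_rotational_model(dts, theta)
        assert fit.tau_rot == pytest.approx(5e5, rel=1e-4)
        # a and tau_rel are degenerate for a pure exponential; what must
        # vanish is the short-time excess rate a/tau_rel
        assert fit.a / fit.tau_rel == pytest.approx(0.0, abs=1e-8)
        assert fit.d_rot_short == pytest.approx(fit.d_rot_long, rel=1e-4)

    def test_parameter_recovery(self):
        """Synthetic transiently anomalous rotor (τ_rot = 500 ns, a = 0.5,
        τ_rel = 5 ns) recovered within 10%."""
        gen = dict(a=0.5, tau_rot=5e5, tau_rel=5e3)
        dts = np.geomspace(1, 1e6, 300)
        dts = np.concatenate([[0.0], dts])
        theta = rotational_model(dts, **gen)
        fit = fit_rotational_model(dts, theta)
        assert fit.a == pytest.approx(0.5, rel=0.10)
        assert fit.tau_rot == pytest.approx(5e5, rel=0.10)
        assert fit.tau_rel == pytest.approx(5e3, rel=0.10)
        assert fit.residual < 1e-6

    def test_short_ge_long(self):
        dts = np.linspace(0, 1e6, 100)
        theta = rotational_model(dts, 0.8, 2e5, 1e3)
        fit = fit_rotational_model(dts, theta)
        assert fit.d_rot_short >= fit.d_rot_long


# -------------------------------------------------------------- viscosity

class TestViscosity:
    def test_unity(self):
        r = viscosity_ratios(1.0, 1.0, 2.0, 2.0)
        assert r.ratio == 1.0

    def test_in_cell_ratio(self):
        """η_T = 3.2, η_R = 1.5 (GFP in CHO cells) → ratio 2.1."""
        r = viscosity_ratios(3.2, 1.0, 1.5, 1.0)
        assert round(r.ratio, 1) == 2.1

    def test_in_vitro_ratio(self):
        r = viscosity_ratios(4.35, 1.0, 1.66, 1.0)
        assert round(r.ratio, 1) == 2.6

    def test_hsa_closed_form(self):
        """exp(Ac/(1−Bc)) with the HSA constants at 275 mg/ml ≈ 3.16,
        with powers 1.28 / 0.44 giving 4.35 / 1.66 and ratio 2.6."""
        out = literature_hsa_viscosity()
        assert out["eta_m_rel"] == pytest.approx(3.155, rel=0.01)
        assert out["eta_T"] == pytest.approx(4.35, rel=0.01)
        assert out["eta_R"] == pytest.approx(1.66, rel=0.01)
        assert out["ratio"] == pytest.approx(2.6, rel=0.02)

    def test_zero_concentration(self):
        out = literature_hsa_viscosity(LiteratureViscosityParams(c=0.0))
        assert out["eta_m_rel"] == 1.0 and out["ratio"] == 1.0

    def test_equal_exponents_unit_ratio(self):
        out = literature_hsa_viscosity(
            LiteratureViscosityParams(exponent_T=0.7, exponent_R=0.7))
        assert out["ratio"] == pytest.approx(1.0)

    def test_bc_validation(self):
        with pytest.raises(ValueError):
            LiteratureViscosityParams(B=1.0, c=2.0)
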