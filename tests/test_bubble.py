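"""Rayleigh-Plesset integration: closed-form oracles and invariants."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from knucklecrack import (
    BubbleParams,
    BubbleTrajectory,
    DomainError,
    FluidProperties,
    InceptionError,
    NondimScales,
    initial_gas_pressure,
    integrate_rayleigh_plesset,
    nondimensional_coefficients,
    wall_acceleration,
)


class TestInitialGasPressure:
    def test_vapor_only_bubble(self):
        fluid = FluidProperties(surface_tension=1e-30)
        assert initial_gas_pressure(6500.0, fluid, 200e-6) == pytest.approx(
            0.0, abs=1e-20
        )

    def test_surface_tension_term(self):
        # at p0 = P_v the gas pressure is exactly the Laplace term 2S/R0
        fluid = FluidProperties()
        assert initial_gas_pressure(6500.0, fluid, 200e-6) == pytest.approx(467.0)

    def test_atmospheric_anchor(self):
        fluid = FluidProperties()
        assert initial_gas_pressure(101325.0, fluid, 200e-6) == pytest.approx(
            95292.0
        )

    def test_inception_error_below_vapor(self):
        fluid = FluidProperties()
        with pytest.raises(InceptionError):
            initial_gas_pressure(1000.0, fluid, 200e-6)


class TestNondimCoefficients:
    def test_default_scales_direct_arithmetic(self):
        c = nondimensional_coefficients(FluidProperties(), NondimScales())
        assert c["C_press"] == pytest.approx(100.0 * 1e-4 / (1015.0 * 1e-12))
        assert c["C_visc"] == pytest.approx(4.0 * (0.4 / 1015.0) * 1e-2 / 1e-6)
        assert c["C_surf"] == pytest.approx(2.0 * 0.0467 * 1e-4 / (1015.0 * 1e-9))

    def test_unit_viscous_coefficient(self):
        s = NondimScales()
        nu = s.l**2 / (4.0 * s.tau)
        fluid = FluidProperties(rho=1000.0, mu=nu * 1000.0)
        assert nondimensional_coefficients(fluid, s)["C_visc"] == pytest.approx(1.0)

    def test_time_scale_power_laws(self):
        fluid = FluidProperties()
        c1 = nondimensional_coefficients(fluid, NondimScales(tau=0.01))
        c2 = nondimensional_coefficients(fluid, NondimScales(tau=0.02))
        assert c2["C_press"] == pytest.approx(4.0 * c1["C_press"])
        assert c2["C_surf"] == pytest.approx(4.0 * c1["C_surf"])
        assert c2["C_visc"] == pytest.approx(2.0 * c1["C_visc"])


class TestEquilibriumAndOracles:
    def test_constant_pressure_equilibrium_holds(self):
        """With p_G0 from the surface-tension balance the bubble is steady."""
        fluid = FluidProperties()
        bubble = BubbleParams.at_equilibrium(101325.0, fluid, r0=200e-6)
        res = integrate_rayleigh_plesset(
            lambda t: 101325.0, fluid, bubble, t_end=0.01
        )
        assert res.converged
        assert np.max(np.abs(res.trajectory.r - 200e-6)) < 1e-6 * 200e-6

    def test_rayleigh_collapse_time(self):
        """Empty-cavity collapse vs the classical closed form and an
        independent energy-equation quadrature."""
        rho, dp, r0 = 1000.0, 1e5, 200e-6
        fluid = FluidProperties(
            rho=rho, mu=1e-12, surface_tension=1e-12,
            vapor_pressure=1e-9, polytropic_index=1.4,
        )
        bubble = BubbleParams(r0=r0, p_go=0.0, p0=dp)
        res = integrate_rayleigh_plesset(
            lambda t: dp, fluid, bubble, t_end=5e-5,
            rtol=1e-9, atol=1e-9, max_step_fraction=1e-3,
        )
        assert not res.converged  # full collapse is the expected outcome
        t_num = res.trajectory.t[-1]

        # oracle 1: Rayleigh's prefactor
        t_ref = 0.915 * r0 * math.sqrt(rho / dp)
        # oracle 2: quadrature of the energy equation
        #   Rdot = -sqrt(2 dp / (3 rho) ((r0/R)^3 - 1))
        speed = lambda x: math.sqrt(2.0 * dp / (3.0 * rho) * (x**-3 - 1.0))
        t_quad = r0 * quad(lambda x: 1.0 / speed(x), 1e-4, 1.0 - 1e-12)[0]

        assert t_quad == pytest.approx(t_ref, rel=1e-3)
        assert t_num == pytest.approx(t_ref, rel=0.01)

    def test_minnaert_frequency(self):
        """Small oscillations about equilibrium vs the linearized frequency."""
        fluid = FluidProperties(
            rho=998.0, mu=1e-3, surface_tension=0.0728,
            vapor_pressure=2339.0, polytropic_index=1.4,
        )
        r0, p0 = 200e-6, 101325.0
        bubble = BubbleParams.at_equilibrium(p0, fluid, r0=r0)
        res = integrate_rayleigh_plesset(
            lambda t: p0 * 1.002, fluid, bubble, t_end=1e-3,
            rtol=1e-9, atol=1e-9, max_step_fraction=1e-3,
        )
        traj = res.trajectory
        x = traj.r - np.mean(traj.r[len(traj.r) // 2:])
        cross = np.flatnonzero(np.diff(np.sign(x)) != 0)
        t_cross = traj.t[cross]
        f_num = 0.5 * (len(t_cross) - 1) / (t_cross[-1] - t_cross[0])
        k, s = 1.4, 0.0728
        p_go = p0 - 2339.0 + 2 * s / r0
        f_ref = (1.0 / (2.0 * math.pi * r0)) * math.sqrt(
            (3.0 * k * p_go + (3.0 * k - 1.0) * 2.0 * s / r0) / 998.0
        )
        assert f_num == pytest.approx(f_ref, rel=0.02)

    def test_dimensional_and_nondimensional_forms_agree(self):
        fluid = FluidProperties()
        bubble = BubbleParams.at_equilibrium(50000.0, fluid, r0=200e-6)
        forcing = lambda t: 50000.0 + 4e6 * t  # gentle compression ramp
        t_eval = np.linspace(1e-4, 9.9e-3, 200)
        r = {}
        for dim in (False, True):
            res = integrate_rayleigh_plesset(
                forcing, fluid, bubble, t_end=0.01,
                rtol=1e-9, atol=1e-12 if dim else 1e-9,
                dimensional=dim, dense=True,
            )
            assert res.converged
            r[dim] = res.dense(t_eval)[0]
        assert np.max(np.abs(r[True] - r[False]) / r[False]) < 1e-6


class TestDivergenceClassification:
    def test_runaway_growth_is_divergence(self):
        fluid = FluidProperties()
        bubble = BubbleParams.at_equilibrium(101325.0, fluid, r0=200e-6)
        res = integrate_rayleigh_plesset(
            lambda t: -2e5, fluid, bubble, t_end=0.01
        )
        assert not res.converged
        assert "growth" in res.reason

    def test_violent_collapse_is_divergence(self):
        fluid = FluidProperties(mu=1e-3)
        bubble = BubbleParams(r0=200e-6, p_go=0.0, p0=101325.0)
        res = integrate_rayleigh_plesset(
            lambda t: 5e6, fluid, bubble, t_end=0.01
        )
        assert not res.converged

    def test_baseline_partial_collapse(self, baseline_result):
        """The cracking-joint bubble collapses only partially and persists."""
        traj = baseline_result.trajectory
        r0 = traj.r[0]
        assert traj.rdot[0] == 0.0
        assert traj.r.min() > 0.0
        assert traj.r[-1] < r0
        # collapse phase: no early expansion
        early = traj.t < 1e-3
        assert np.all(traj.rdot[early] <= 1e-12)


class TestWallAcceleration:
    def test_linear_velocity_exact(self):
        t = np.linspace(0.0, 1.0, 11)
        traj = BubbleTrajectory(t=t, r=np.ones_like(t), rdot=3.0 * t + 1.0)
        rddot = wall_acceleration(traj)
        np.testing.assert_allclose(rddot, 3.0, rtol=1e-12)

    def test_constant_velocity_zero(self):
        t = np.linspace(0.0, 1.0, 11)
        traj = BubbleTrajectory(t=t, r=np.ones_like(t), rdot=np.full_like(t, 2.0))
        np.testing.assert_allclose(wall_acceleration(traj), 0.0, atol=1e-14)

    def test_first_point_copies_second(self):
        t = np.array([0.0, 0.1, 0.3])
        traj = BubbleTrajectory(t=t, r=np.ones(3), rdot=np.array([0.0, 1.0, 4.0]))
        rddot = wall_acceleration(traj)
        assert rddot[0] == rddot[1]

    def test_sinusoid_first_order_error_bound(self):
        omega = 2.0 * math.pi * 100.0
        dt = 1e-5
        t = np.arange(0.0, 5e-3, dt)
        traj = BubbleTrajectory(t=t, r=np.ones_like(t), rdot=np.sin(omega * t))
        rddot = wall_acceleration(traj)
        err = np.abs(rddot[1:] - omega * np.cos(omega * t[1:]))
        # backward difference is first order: error ~ (dt/2) * omega^2
        assert err.max() < 0.6 * omega**2 * dt

    def test_too_few_points(self):
        traj = BubbleTrajectory(t=[0.0, 1.0], r=[1.0, 1.0], rdot=[0.0, 0.0])
        with pytest.raises(DomainError):
            wall_acceleration(traj)


class TestToleranceRobustness:
    def test_halved_tolerance_preserves_dominant_frequency(self, baseline_config,
                                                           baseline_result):
        from knucklecrack import simulate

        cfg = baseline_config.replace_value("solver", "rtol", 5e-8)
        cfg = cfg.replace_value("solver", "atol", 5e-8)
        f_tight = simulate(cfg).summary["f_dominant_hz"]
        f_base = baseline_result.summary["f_dominant_hz"]
        assert abs(f_tight - f_base) / f_base < 0.01
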