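import math

import numpy as np
import pytest
from scipy.linalg import expm

from swingfree.core_dynamics import (DEFAULT_STEP, ImpedanceParams, ModeSpec,
                                     State, SystemParams,
                                     coupled_linear_matrix,
                                     mechanical_energy, modal_decomposition,
                                     pendulum_mode, simulate_coupled,
                                     simulate_linearized, simulate_nonlinear)
from swingfree.errors import DegenerateModeError, IntegrationError

ZERO_FORCE = lambda t: np.zeros_like(t)  # noqa: E731

# closed form 2*pi*sqrt(l*m_c/(g*(m_c+m_p))) for the free linearized system
FREE_PERIOD = 1.1288767796774165
# sqrt(g*(m_c+m_p)/(l*m_c))
FREE_OMEGA = 5.565873459612701


class TestSystemParams:
    def test_defaults_match_experiment(self, params):
        assert (params.m_c, params.m_p, params.l, params.g) == \
            (1.9, 1.1, 0.5, 9.81)

    @pytest.mark.parametrize("field", ["m_c", "m_p", "l", "g"])
    def test_positivity_enforced(self, field):
        kwargs = {field: 0.0}
        with pytest.raises(ValueError):
            SystemParams(**kwargs)

    def test_impedance_nonnegative(self):
        with pytest.raises(ValueError):
            ImpedanceParams(K=-1.0, B=0.0)


class TestModeSpec:
    def test_td_computed(self):
        m = ModeSpec(omega_n=2.0, zeta=0.0)
        assert m.T_d == pytest.approx(math.pi, rel=1e-12)

    def test_td_consistency_checked(self):
        with pytest.raises(ValueError):
            ModeSpec(omega_n=2.0, zeta=0.0, T_d=1.0)

    def test_overdamped_rejected(self):
        with pytest.raises(DegenerateModeError):
            ModeSpec(omega_n=2.0, zeta=1.0)

    def test_pendulum_mode(self, params):
        m = pendulum_mode(params)
        assert m.omega_n == pytest.approx(math.sqrt(9.81 / 0.5), rel=1e-12)
        assert m.zeta == 0.0
        assert m.T_n == pytest.approx(1.4185033534428875, rel=1e-12)


class TestSimulateNonlinear:
    def test_equilibrium_stays_zero(self, params):
        traj = simulate_nonlinear(params, ZERO_FORCE, State(), duration=1.0)
        for arr in (traj.x, traj.x_dot, traj.phi, traj.phi_dot, traj.F_ball):
            assert np.all(arr == 0.0)

    def test_free_oscillation_period(self, params):
        # small-amplitude free oscillation matches the linearized closed form
        traj = simulate_nonlinear(params, ZERO_FORCE,
                                  State(phi=0.05), duration=6.0)
        sign = np.sign(traj.phi)
        downward = np.flatnonzero((sign[:-1] > 0) & (sign[1:] <= 0))
        periods = np.diff(traj.t[downward])
        assert np.mean(periods) == pytest.approx(FREE_PERIOD, rel=5e-4)

    def test_momentum_conservation_no_coupling(self, params):
        traj = simulate_nonlinear(params, ZERO_FORCE,
                                  State(x_dot=0.1), duration=2.0)
        assert np.allclose(traj.x, 0.1 * traj.t, atol=1e-12)
        assert np.all(traj.phi == 0.0)

    def test_blowup_signalled(self, params):
        with pytest.raises(IntegrationError):
            simulate_nonlinear(params, lambda t: np.full_like(t, 1e300),
                               State(), duration=0.1)

    def test_energy_conserved(self, params):
        traj = simulate_nonlinear(params, ZERO_FORCE,
                                  State(phi=0.3, x_dot=0.2),
                                  duration=10.0, step=1e-3)
        E = mechanical_energy(params, traj)
        assert np.max(np.abs(E - E[0])) / E[0] < 1e-6

    def test_step_refinement_stable(self, params):
        end = []
        for step in (DEFAULT_STEP, DEFAULT_STEP / 2):
            traj = simulate_nonlinear(params, ZERO_FORCE,
                                      State(phi=0.2, x_dot=0.1),
                                      duration=2.0, step=step)
            end.append(traj.final_state.as_array())
        assert np.max(np.abs(end[0] - end[1])) < 1e-8


class TestSimulateLinearized:
    def test_zero_initial_zero_trajectory(self, params):
        traj = simulate_linearized(params, ZERO_FORCE, State(), duration=0.5)
        assert np.all(traj.phi == 0.0) and np.all(traj.x == 0.0)

    def test_matches_nonlinear_for_small_angles(self, params):
        lin = simulate_linearized(params, ZERO_FORCE, State(phi=0.01),
                                  duration=FREE_PERIOD)
        non = simulate_nonlinear(params, ZERO_FORCE, State(phi=0.01),
                                 duration=FREE_PERIOD)
        assert np.max(np.abs(lin.phi - non.phi)) < 1e-3

    def test_cubic_convergence_of_linearization(self, params):
        # max |phi_lin - phi_nonlin| over one period shrinks ~ phi0^3
        errs = []
        amps = [0.04, 0.02, 0.01]
        for a in amps:
            lin = simulate_linearized(params, ZERO_FORCE, State(phi=a),
                                      duration=FREE_PERIOD)
            non = simulate_nonlinear(params, ZERO_FORCE, State(phi=a),
                                     duration=FREE_PERIOD)
            errs.append(np.max(np.abs(lin.phi - non.phi)))
        ratios = [errs[i] / errs[i + 1] for i in range(2)]
        for r in ratios:
            assert 5.5 < r < 10.5  # 2^3 = 8 within tolerance

    def test_constant_force_initial_acceleration(self, params):
        # algebraic elimination gives m_c*xdd = m_p*g*phi + F; at phi=0,
        # xdd(0+) = F/m_c
        traj = simulate_linearized(params, lambda t: np.full_like(t, 3.0),
                                   State(), duration=0.2)
        assert traj.x_ddot[0] == pytest.approx(3.0 / params.m_c, rel=1e-12)


class TestSimulateCoupled:
    def test_zero_command_zero_trajectory(self, params, imp):
        cmd = (lambda t: np.zeros_like(t), lambda t: np.zeros_like(t))
        traj = simulate_coupled(params, imp, cmd, None, duration=1.0)
        assert np.all(traj.x == 0.0) and np.all(traj.phi == 0.0)

    def test_step_command_converges_to_target(self, params):
        imp = ImpedanceParams(K=100.0, B=10.0)
        cmd = (lambda t: np.full_like(t, 0.25), lambda t: np.zeros_like(t))
        traj = simulate_coupled(params, imp, cmd, None, duration=40.0)
        assert traj.x[-1] == pytest.approx(0.25, abs=1e-4)
        assert abs(traj.phi[-1]) < 1e-3

    def test_matches_matrix_exponential(self, params, imp):
        # constant input (x0 = 0.25, x0d = 0, Fff = 0) over 0.5 s
        A, Bmap = coupled_linear_matrix(params, imp)
        u = np.array([0.25, 0.0, 0.0])
        cmd = (lambda t: np.full_like(t, 0.25), lambda t: np.zeros_like(t))
        traj = simulate_coupled(params, imp, cmd, None, linear=True,
                                duration=0.5)
        rhs = Bmap @ u
        for i in [100, 250, len(traj.t) - 1]:
            t = traj.t[i]
            y = np.linalg.solve(A, (expm(A * t) - np.eye(4)) @ rhs)
            sim = np.array([traj.x[i], traj.x_dot[i],
                            traj.phi[i], traj.phi_dot[i]])
            assert np.max(np.abs(sim - y)) < 1e-6


class TestCoupledLinearMatrix:
    def test_free_system_roots(self, params):
        A, _ = coupled_linear_matrix(params, ImpedanceParams(K=0.0, B=0.0))
        eig = np.sort_complex(np.linalg.eigvals(A))
        imag = sorted(abs(lam.imag) for lam in eig)
        assert imag[0] == pytest.approx(0.0, abs=1e-9)
        assert imag[1] == pytest.approx(0.0, abs=1e-9)
        assert imag[2] == pytest.approx(FREE_OMEGA, rel=1e-12)
        assert imag[3] == pytest.approx(FREE_OMEGA, rel=1e-12)

    def test_phidd_row_algebra(self, params, imp):
        mc, mp_, l, g = params.m_c, params.m_p, params.l, params.g
        A, Bmap = coupled_linear_matrix(params, imp)
        expected = np.array([imp.K / (l * mc), imp.B / (l * mc),
                             -(g / l + g * mp_ / (l * mc)), 0.0])
        assert np.allclose(A[3], expected, rtol=1e-14)
        assert np.allclose(Bmap[3], [-imp.K / (l * mc), -imp.B / (l * mc),
                                     -1.0 / (l * mc)], rtol=1e-14)


class TestModalDecomposition:
    def test_ordering_contract(self, params, imp):
        slow, fast = modal_decomposition(coupled_linear_matrix(params, imp)[0])
        assert slow.omega_n < fast.omega_n
        assert 0 < slow.zeta < 1 and 0 < fast.zeta < 1

    def test_decoupled_fixture_exact_recovery(self):
        # two independent mass-spring-dampers with known (omega, zeta)
        def block(omega, zeta):
            return np.array([[0.0, 1.0],
                             [-omega ** 2, -2.0 * zeta * omega]])
        A = np.zeros((4, 4))
        A[:2, :2] = block(2.0, 0.1)
        A[2:, 2:] = block(7.0, 0.3)
        slow, fast = modal_decomposition(A)
        assert slow.omega_n == pytest.approx(2.0, rel=1e-12)
        assert slow.zeta == pytest.approx(0.1, rel=1e-12)
        assert fast.omega_n == pytest.approx(7.0, rel=1e-12)
        assert fast.zeta == pytest.approx(0.3, rel=1e-12)

    def test_no_dissipation_zero_zeta(self, params):
        slow, fast = modal_decomposition(
            coupled_linear_matrix(params, ImpedanceParams(K=100.0, B=0.0))[0])
        assert slow.zeta == pytest.approx(0.0, abs=1e-12)
        assert fast.zeta == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_signalled(self, params):
        with pytest.raises(DegenerateModeError):
            modal_decomposition(
                coupled_linear_matrix(params, ImpedanceParams(0.0, 0.0))[0])

    def test_large_k_pendulum_mode_limit(self, params):
        # with the cart pinned by a stiff hand spring, one mode approaches
        # the clamped-cart pendulum frequency sqrt(g/l), monotonically
        target = math.sqrt(params.g / params.l)
        freqs = []
        for K in [100.0, 300.0, 1000.0, 3000.0, 10000.0]:
            slow, fast = modal_decomposition(
                coupled_linear_matrix(params, ImpedanceParams(K, 10.0))[0])
            pend = min(slow.omega_n, fast.omega_n,
                       key=lambda w: abs(w - target))
            freqs.append(pend)
        errors = [abs(f - target) for f in freqs]
        assert all(e1 > e2 for e1, e2 in zip(errors, errors[1:]))
        assert errors[-1] < 0.02 * target


class TestTrajectoryContract:
    def test_fball_consistent_with_newton(self, params):
        traj = simulate_nonlinear(params, lambda t: np.sin(5.0 * t),
                                  State(phi=0.1), duration=1.0)
        mc, mp_ = params.m_c, params.m_p
        resid = (mc + mp_) * traj.x_ddot - traj.F_ball - traj.F
        assert np.max(np.abs(resid)) < 1e-9

    def test_length_mismatch_rejected(self, params):
        traj = simulate_nonlinear(params, ZERO_FORCE, State(), duration=0.1)
        from swingfree.core_dynamics import StateTrajectory
        with pytest.raises(ValueError):
            StateTrajectory(t=traj.t, x=traj.x[:-1], x_dot=traj.x_dot,
                            x_ddot=traj.x_ddot, phi=traj.phi,
                            phi_dot=traj.phi_dot, phi_ddot=traj.phi_ddot,
                            F=traj.F, F_ball=traj.F_ball)
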