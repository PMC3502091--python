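import numpy as np
import pytest
from hypothesis import given, strategies as st

import gaswash as gw
from gaswash.model import Phase, simulate_phases

pressures = st.floats(min_value=0.0, max_value=20.0)


def storage(body, agent, f_i, f_a, f_vrg, f_mus, f_fat):
    """Agent amount (vol%*L) computed directly from the parameters."""
    return (body.v_circuit * f_i + body.frc * f_a
            + body.v_vrg * agent.lambda_vrg * f_vrg
            + body.v_mus * agent.lambda_mus * f_mus
            + body.v_fat * agent.lambda_fat * f_fat)


class TestMixedVenous:
    def test_uniform_pressure_is_identity(self, body):
        s = gw.SimState(f_vrg=0.7, f_mus=0.7, f_fat=0.7)
        assert gw.mixed_venous(s, body) == pytest.approx(0.7)

    def test_flow_weighting(self, body):
        # only the VRG carries agent: 0.758*1.2/0.998
        s = gw.SimState(f_vrg=1.2)
        assert gw.mixed_venous(s, body) == pytest.approx(0.9114, abs=5e-5)

    def test_zero_state(self, body):
        assert gw.mixed_venous(gw.SimState(), body) == 0.0

    @given(fv=pressures, fm=pressures, ff=pressures)
    def test_bounded_by_tissue_pressures(self, body, fv, fm, ff):
        s = gw.SimState(f_vrg=fv, f_mus=fm, f_fat=ff)
        fmv = gw.mixed_venous(s, body)
        assert min(fv, fm, ff) - 1e-12 <= fmv <= max(fv, fm, ff) + 1e-12


class TestDerivative:
    def test_global_equilibrium_is_stationary(self, iso, body):
        s = gw.SimState(f_i=1.2, f_a=1.2, f_vrg=1.2, f_mus=1.2, f_fat=1.2)
        vent = gw.VentSettings(f_d=1.2, fgf=1, v_a=5)
        r = gw.derivative(s, vent, iso, body)
        for v in (r.f_i, r.f_a, r.f_vrg, r.f_mus, r.f_fat):
            assert v == pytest.approx(0.0, abs=1e-14)

    def test_vrg_uptake_rate(self, iso, body):
        # lam_bg*Q_vrg*(F_A - F_VRG)/(V_vrg*lam_vrg)
        #   = 1.3*3.79*1.2/(6*2.1) = 0.469238...
        s = gw.SimState(f_a=1.2, f_vrg=0.0)
        r = gw.derivative(s, gw.VentSettings(f_d=0, fgf=1, v_a=5), iso, body)
        assert r.f_vrg == pytest.approx(0.46924, abs=1e-5)

    @given(fi=pressures, fa=pressures, fv=pressures, fm=pressures,
           ff=pressures, fd=pressures,
           fgf=st.floats(min_value=0.0, max_value=15.0),
           va=st.floats(min_value=0.0, max_value=15.0))
    def test_amount_balance_identity(self, iso, body, fi, fa, fv, fm, ff,
                                     fd, fgf, va):
        """Total stored-amount rate equals fresh-gas inflow minus circuit
        overflow, exactly, for any state and settings."""
        s = gw.SimState(f_i=fi, f_a=fa, f_vrg=fv, f_mus=fm, f_fat=ff)
        r = gw.derivative(s, gw.VentSettings(f_d=fd, fgf=fgf, v_a=va),
                          iso, body)
        lhs = (body.v_circuit * r.f_i + body.frc * r.f_a
               + body.v_vrg * iso.lambda_vrg * r.f_vrg
               + body.v_mus * iso.lambda_mus * r.f_mus
               + body.v_fat * iso.lambda_fat * r.f_fat)
        rhs = fgf * (fd - fi)
        assert lhs == pytest.approx(rhs, abs=1e-9 + 1e-9 * abs(rhs))


class TestIntegrate:
    def test_zero_delivery_zero_state_stays_zero(self, iso, body):
        ts = gw.integrate(gw.SimState.zero(),
                          [(10.0, gw.VentSettings(f_d=0, fgf=5, v_a=5))],
                          iso, body)
        for col in ("f_i", "f_a", "f_vrg", "f_mus", "f_fat"):
            assert np.all(ts.column(col) == 0.0)

    def test_equilibrium_limit_high_fgf(self, body):
        """Constant delivery at FGF >> V_A drives every compartment to
        the delivered pressure (fast agent so fat equilibrates too)."""
        fast = gw.AgentParams(name="fast", mac=2.0, lambda_blood=0.5,
                              lambda_vrg=0.1, lambda_mus=0.1,
                              lambda_fat=0.2)
        vent = gw.VentSettings(f_d=2.0, fgf=30, v_a=5)
        ts = gw.integrate(gw.SimState.zero(), [(180.0, vent)], fast, body,
                          reporting_dt_s=60)
        end = ts.final_state()
        for v in end.pressures():
            assert v == pytest.approx(2.0, rel=1e-3)

    def test_single_tissue_exponential_time_constant(self, iso, body):
        """With F_A held at a constant level the muscle group washes in
        as c*(1 - exp(-t/tau)), tau = V*lam_mus/(lam_bg*Q_mus) = 126.9 min."""
        c = 1.2
        phase = Phase(name="hold", clamp_fa=c, duration=100.0,
                      vent=gw.VentSettings(f_d=c, fgf=1, v_a=5))
        ts = simulate_phases(gw.SimState(f_a=c), [phase], iso, body,
                             reporting_dt_s=30)
        tau = body.v_mus * iso.lambda_mus / (iso.lambda_blood * body.q_mus)
        assert tau == pytest.approx(126.92, abs=0.01)
        t = ts.t
        expected = c * (1.0 - np.exp(-t / tau))
        assert np.max(np.abs(ts.f_mus - expected)) < 1e-9

    def test_biexponential_two_compartment_oracle(self, iso, body):
        """Degenerate lung+VRG system (other tissue flows ~0, no
        ventilation) matches the analytic bi-exponential solution."""
        tiny = gw.BodyCircuitParams(f_vrg=0.758, f_mus=1e-12, f_fat=1e-12)
        vent = gw.VentSettings(f_d=0, fgf=0, v_a=0)
        fa0 = 1.0
        ts = gw.integrate(gw.SimState(f_a=fa0), [(30.0, vent)], iso, tiny)
        a = iso.lambda_blood * tiny.q_perfused / tiny.frc
        k = iso.lambda_blood * tiny.q_vrg / (tiny.v_vrg * iso.lambda_vrg)
        A = np.array([[-a, a * tiny.q_vrg / tiny.q_perfused], [k, -k]])
        lam, V = np.linalg.eig(A)
        coef = np.linalg.solve(V, np.array([fa0, 0.0]))
        t = ts.t
        sol = (V @ (coef[:, None] * np.exp(np.outer(lam, t)))).real
        assert np.max(np.abs(ts.f_a - sol[0])) < 1e-4
        assert np.max(np.abs(ts.f_vrg - sol[1])) < 1e-4

    def test_matrix_exponential_oracle_full_system(self, sevo, body):
        """RK4 trajectory of the full five-compartment affine system
        agrees with the scipy matrix-exponential solution."""
        from scipy.linalg import expm

        vent = gw.VentSettings(f_d=3.0, fgf=2.0, v_a=4.0)
        x0 = np.array([0.2, 0.1, 0.0, 0.5, 0.05])
        init = gw.SimState(f_i=x0[0], f_a=x0[1], f_vrg=x0[2],
                           f_mus=x0[3], f_fat=x0[4])
        ts = gw.integrate(init, [(20.0, vent)], sevo, body,
                          reporting_dt_s=60)
        q = np.array([body.q_vrg, body.q_mus, body.q_fat])
        qp = q.sum()
        lqp = sevo.lambda_blood * qp
        caps = np.array([body.v_vrg * sevo.lambda_vrg,
                         body.v_mus * sevo.lambda_mus,
                         body.v_fat * sevo.lambda_fat])
        ks = sevo.lambda_blood * q / caps
        A = np.zeros((5, 5))
        A[0, 0] = -(vent.fgf + vent.v_a) / body.v_circuit
        A[0, 1] = vent.v_a / body.v_circuit
        A[1, 0] = vent.v_a / body.frc
        A[1, 1] = -(vent.v_a + lqp) / body.frc
        A[1, 2:] = lqp * (q / qp) / body.frc
        for i in range(3):
            A[2 + i, 1] = ks[i]
            A[2 + i, 2 + i] = -ks[i]
        b = np.zeros(5)
        b[0] = vent.fgf * vent.f_d / body.v_circuit
        M = np.zeros((6, 6))
        M[:5, :5] = A
        M[:5, 5] = b
        for t_probe in (5.0, 20.0):
            z = expm(M * t_probe) @ np.append(x0, 1.0)
            row = int(np.argmin(np.abs(ts.t - t_probe)))
            got = np.array([ts.f_i[row], ts.f_a[row], ts.f_vrg[row],
                            ts.f_mus[row], ts.f_fat[row]])
            assert np.max(np.abs(got - z[:5])) < 1e-6

    def test_step_halving_convergence(self, iso, body):
        """Halving the integrator step changes reported pressures by
        less than 1e-6 vol%."""
        init = gw.SimState(f_i=1.3, f_a=1.2, f_vrg=1.2, f_mus=1.1,
                           f_fat=0.2)
        sched = [(15.0, gw.VentSettings(f_d=0, fgf=10, v_a=5))]
        a = gw.integrate(init, sched, iso, body, dt_s=0.25)
        b = gw.integrate(init, sched, iso, body, dt_s=0.125)
        assert np.allclose(a.t, b.t, atol=1e-12)
        for col in ("f_i", "f_a", "f_vrg", "f_mus", "f_fat"):
            assert np.max(np.abs(a.column(col) - b.column(col))) < 1e-6

    def test_mass_conservation(self, iso, body):
        """Stored amount change equals fresh-gas inflow minus circuit
        overflow over a multi-segment schedule, to 1e-6 relative."""
        init = gw.SimState.zero()
        sched = [(20.0, gw.VentSettings(f_d=3.0, fgf=1, v_a=5)),
                 (10.0, gw.VentSettings(f_d=0.0, fgf=10, v_a=10))]
        ts = gw.integrate(init, sched, iso, body)
        end = ts.final_state()
        delta = storage(body, iso, end.f_i, end.f_a, end.f_vrg,
                        end.f_mus, end.f_fat)
        net = ts.net_input - ts.net_output
        assert delta == pytest.approx(net, rel=1e-6)

    def test_non_negative_and_bounded(self, sevo, body):
        """Pressures stay within [0, max(F_D, initial)] throughout."""
        sched = [(30.0, gw.VentSettings(f_d=5.0, fgf=1, v_a=5)),
                 (30.0, gw.VentSettings(f_d=0.0, fgf=10, v_a=5))]
        ts = gw.integrate(gw.SimState.zero(), sched, sevo, body)
        for col in ("f_i", "f_a", "f_vrg", "f_mus", "f_fat"):
            v = ts.column(col)
            assert np.min(v) >= 0.0
            assert np.max(v) <= 5.0 + 1e-9

    def test_monotone_washout(self, iso, body):
        """With no delivery and all compartments equal, F_VRG never
        increases."""
        init = gw.SimState(f_i=1.2, f_a=1.2, f_vrg=1.2, f_mus=1.2,
                           f_fat=1.2)
        ts = gw.integrate(init, [(60.0, gw.VentSettings(f_d=0, fgf=10,
                                                        v_a=5))],
                          iso, body)
        assert np.all(np.diff(ts.f_vrg) <= 1e-12)

    def test_rejects_bad_schedule(self, iso, body):
        with pytest.raises(ValueError):
            gw.integrate(gw.SimState.zero(), [], iso, body)
        with pytest.raises(ValueError):
            gw.integrate(gw.SimState.zero(),
                         [(-1.0, gw.VentSettings(f_d=0, fgf=1, v_a=5))],
                         iso, body)


class TestTimeSeries:
    def test_strictly_increasing_time_enforced(self):
        t = np.array([0.0, 1.0, 1.0])
        z = np.zeros(3)
        with pytest.raises(ValueError, match="strictly increasing"):
            gw.TimeSeries(t=t, f_d=z, fgf=z, v_a=z, f_i=z, f_a=z,
                          f_vrg=z, f_mus=z, f_fat=z, f_mv=z)

    def test_empty_rejected(self):
        e = np.array([])
        with pytest.raises(ValueError, match="empty"):
            gw.TimeSeries(t=e, f_d=e, fgf=e, v_a=e, f_i=e, f_a=e,
                          f_vrg=e, f_mus=e, f_fat=e, f_mv=e)

    def test_reporting_grid_constant_within_phase(self, iso, body):
        ts = gw.integrate(gw.SimState.zero(),
                          [(2.0, gw.VentSettings(f_d=1, fgf=1, v_a=5))],
                          iso, body, reporting_dt_s=1.0)
        assert np.allclose(np.diff(ts.t), 1.0 / 60.0)
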