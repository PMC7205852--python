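import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from cranioflow import (
    DomainError,
    ModelParameters,
    ModelState,
    PeriodicWaveform,
    arterial_pv,
    arteriovenous_resistance,
    compensatory_rate,
    craniospinal_elastance,
    csf_channel_coeffs,
    equilibrium_state,
    rhs,
    venous_outflow_resistance,
    venous_pv,
)

# ---------------------------------------------------------------------------
# arterial compartment
# ---------------------------------------------------------------------------


class TestArterialPV:
    def test_zero_at_unstressed_volume(self, mean_params):
        assert arterial_pv(mean_params.V_an, mean_params) == 0.0

    def test_linear_limit_slope(self, mean_params):
        p = mean_params.replace(k_ea=0.0)
        assert arterial_pv(p.V_an + 1.0, p) == pytest.approx(3.33, abs=1e-12)

    @given(st.floats(1.0, 60.0), st.floats(0.1, 10.0))
    def test_strictly_increasing(self, v, dv):
        p = ModelParameters()
        assert arterial_pv(v + dv, p) > arterial_pv(v, p)

    def test_rejects_nonpositive_volume(self, mean_params):
        with pytest.raises(DomainError):
            arterial_pv(0.0, mean_params)
        with pytest.raises(DomainError):
            arterial_pv(-3.0, mean_params)


class TestArteriovenousResistance:
    def test_baseline_at_unstressed_volume(self, mean_params):
        # collapse factor is ~exp(-n_Rav/2) there: negligible
        r = arteriovenous_resistance(mean_params.V_an, mean_params)
        assert r == pytest.approx(12.54, rel=1e-6)

    def test_poiseuille_quarter_at_double_volume(self, mean_params):
        p = mean_params.replace(c_collapse=0.0)  # collapse factor off
        r = arteriovenous_resistance(2.0 * p.V_an, p)
        assert r == pytest.approx(12.54 / 4.0, rel=1e-12)

    @given(st.floats(2.0, 80.0), st.floats(0.1, 10.0))
    def test_strictly_decreasing(self, v, dv):
        p = ModelParameters()
        assert arteriovenous_resistance(v + dv, p) < arteriovenous_resistance(v, p)


# ---------------------------------------------------------------------------
# venous compartment
# ---------------------------------------------------------------------------


class TestVenousPV:
    def test_zero_at_unstressed_volume(self, mean_params):
        assert venous_pv(mean_params.V_vn, mean_params) == 0.0

    def test_distension_branch(self, mean_params):
        p = mean_params.replace(e_v1=1.0, m_ev1=2.0)
        assert venous_pv(p.V_vn + 1.0, p) == pytest.approx(1.0, abs=1e-12)

    def test_collapse_branch(self, mean_params):
        p = mean_params.replace(e_v2=1.48, m_ev2=2.0)
        assert venous_pv(p.V_vn - 1.0, p) == pytest.approx(-1.48, abs=1e-12)

    @given(st.floats(30.0, 110.0), st.floats(0.05, 5.0))
    def test_monotone_and_continuous(self, v, dv):
        p = ModelParameters()
        assert venous_pv(v + dv, p) > venous_pv(v, p)

    def test_continuity_at_unstressed_volume(self, mean_params):
        eps = 1e-9
        below = venous_pv(mean_params.V_vn - eps, mean_params)
        above = venous_pv(mean_params.V_vn + eps, mean_params)
        assert abs(above - below) < 1e-6


class TestVenousOutflowResistance:
    """Compression narrows the venous lumen and raises the resistance; the
    dependence on (p_v, p_ic) runs through the transmural pressure."""

    def test_exponent_zero_gives_baseline(self, mean_params):
        p = mean_params.replace(m_Rv=0.0)
        for p_v, p_ic in [(10, 9), (30, 5), (6, 20)]:
            assert venous_outflow_resistance(p_v, p_ic, p) == pytest.approx(0.54)

    def test_baseline_when_compression_absent(self, mean_params):
        # zero transmural pressure: veins at their unstressed volume
        r = venous_outflow_resistance(12.0, 12.0, mean_params)
        assert r == pytest.approx(mean_params.R_v0, rel=1e-12)

    def test_distended_vein_arithmetic(self, mean_params):
        # transmural +1 mmHg with e_v1=1, m_ev1=1.89 -> v_v = 71 ml
        p = mean_params.replace(m_Rv=2.0)
        r = venous_outflow_resistance(10.0, 9.0, p)
        assert r == pytest.approx(0.54 * (70.0 / 71.0) ** 2, rel=1e-12)

    def test_rises_under_compression_up_to_cap(self, mean_params):
        r_mild = venous_outflow_resistance(10.0, 15.0, mean_params)
        r_severe = venous_outflow_resistance(10.0, 60.0, mean_params)
        assert mean_params.R_v0 < r_mild < r_severe
        assert r_severe <= mean_params.r_v_cap * mean_params.R_v0 * (1 + 1e-12)


# ---------------------------------------------------------------------------
# CSF channel and elastances
# ---------------------------------------------------------------------------


class TestCsfChannel:
    def test_outflow_branch_patient_h(self, h_params):
        r_eff, l_eff = csf_channel_coeffs(+1.0, h_params)
        assert r_eff == pytest.approx(0.45 * 1.6, abs=1e-15)
        assert l_eff == pytest.approx(0.08 * 1.015, abs=1e-15)

    def test_inflow_branch_patient_h(self, h_params):
        r_eff, l_eff = csf_channel_coeffs(-1.0, h_params)
        assert r_eff == pytest.approx(0.45, abs=1e-15)
        assert l_eff == pytest.approx(0.08, abs=1e-15)

    def test_symmetric_when_asymmetry_off(self, mean_params):
        p = mean_params.replace(a_Rs=0.0, b_Ls=0.0)
        for q in (-3.0, -0.01, 0.0, 0.01, 3.0):
            assert csf_channel_coeffs(q, p) == (p.R_cs, p.L_cs)

    def test_switch_is_continuous(self, mean_params):
        qs = np.linspace(-2 * mean_params.eps_q, 2 * mean_params.eps_q, 401)
        r = np.array([csf_channel_coeffs(q, mean_params)[0] for q in qs])
        assert np.max(np.abs(np.diff(r))) < 0.02 * (r.max() - r.min()) + 1e-12


class TestCraniospinalElastance:
    def test_reference_point(self, mean_params):
        assert craniospinal_elastance(mean_params.p_0, mean_params) == pytest.approx(
            mean_params.e_c0
        )

    def test_linear_when_coefficient_zero(self, mean_params):
        p = mean_params.replace(k_ec=0.0)
        for pic in (0.0, 10.0, 40.0):
            assert craniospinal_elastance(pic, p) == p.e_c0

    def test_doubles_at_double_pressure_with_unit_coefficient(self, mean_params):
        p = mean_params.replace(k_ec=1.0)
        assert craniospinal_elastance(2 * p.p_0, p) == pytest.approx(2 * p.e_c0)

    def test_floor_at_low_pressure(self, mean_params):
        assert craniospinal_elastance(-100.0, mean_params) == pytest.approx(
            0.1 * mean_params.e_c0
        )


class TestCompensatoryRate:
    def test_equilibrium_is_stationary(self, mean_params):
        p_ic = 20.0
        v_eq = mean_params.G_comp * (p_ic - mean_params.p_0)
        assert compensatory_rate(p_ic, v_eq, mean_params) == 0.0
        assert compensatory_rate(mean_params.p_0, 0.0, mean_params) == 0.0

    def test_first_order_step_response(self, mean_params):
        """A pressure step relaxes v_comp as 1 - exp(-t/tau_reg)."""
        p_ic = mean_params.p_0 + 10.0
        target = mean_params.G_comp * 10.0
        sol = solve_ivp(
            lambda t, v: [compensatory_rate(p_ic, v[0], mean_params)],
            (0.0, 3.0), [0.0], rtol=1e-10, atol=1e-12, dense_output=True,
        )
        for t in (0.5, 1.31, 2.5):
            expected = target * (1.0 - np.exp(-t / 1.31))
            assert sol.sol(t)[0] == pytest.approx(expected, rel=1e-6)


# ---------------------------------------------------------------------------
# right-hand side and equilibrium
# ---------------------------------------------------------------------------


class TestRhs:
    def test_rest_state_is_stationary_when_p0_matches_outflow_pressure(self):
        """With p_0 = p_out the unstressed rest state is a global equilibrium."""
        p = ModelParameters(p_0=5.0)  # equals p_out
        rest = ModelState(
            v_a=p.V_an, v_v=p.V_vn, v_s=p.V_sn, p_ic=p.p_0,
            q_v=0.0, q_s=0.0, v_comp=0.0,
        )
        inflow = PeriodicWaveform.constant(0.0)
        assert np.abs(rhs(0.0, rest, p, inflow)).max() < 1e-12

    def test_equilibrium_is_a_root(self, mean_params):
        q = 10.8
        eq = equilibrium_state(mean_params, q)
        inflow = PeriodicWaveform.constant(q)
        assert np.abs(rhs(0.0, eq, mean_params, inflow)).max() < 1e-9

    def test_drive_term_identity(self, mean_params, notched_inflow):
        """The ICP equation's drive is exactly q_a - q_v - q_s - dv_comp/dt."""
        state = equilibrium_state(mean_params, notched_inflow.mean).to_array()
        state[4] -= 1.7  # perturb off equilibrium
        state[5] += 0.9
        t = 0.234
        dy = rhs(t, state, mean_params, notched_inflow)
        q_a = notched_inflow(t)
        e_c = craniospinal_elastance(state[3], mean_params)
        expected = e_c * (q_a - state[4] - state[5] - dy[6])
        assert dy[3] == pytest.approx(expected, rel=1e-13)

    def test_continuous_across_csf_direction_switch(self, mean_params, notched_inflow):
        eps = mean_params.eps_q
        base = equilibrium_state(mean_params, notched_inflow.mean).to_array()
        qs_grid = np.linspace(-2 * eps, 2 * eps, 801)
        outs = []
        for q_s in qs_grid:
            y = base.copy()
            y[5] = q_s
            outs.append(rhs(0.0, y, mean_params, notched_inflow))
        outs = np.array(outs)
        jumps = np.max(np.abs(np.diff(outs, axis=0)), axis=0)
        spans = np.ptp(outs, axis=0) + 1e-12
        assert np.all(jumps < 0.05 * spans + 1e-9)

    def test_invalid_state_rejected(self, mean_params, notched_inflow):
        bad = np.array([-1.0, 70.0, 30.0, 13.0, 10.0, 0.0, 0.0])
        with pytest.raises(DomainError):
            rhs(0.0, bad, mean_params, notched_inflow)


class TestEquilibriumState:
    def test_zero_inflow_rest_state_when_p0_matches_outflow(self):
        p = ModelParameters(p_0=5.0)
        eq = equilibrium_state(p, 0.0)
        assert eq.v_a == pytest.approx(p.V_an, abs=1e-9)
        assert eq.v_v == pytest.approx(p.V_vn, abs=1e-9)
        assert eq.v_s == pytest.approx(p.V_sn, abs=1e-9)
        assert eq.p_ic == pytest.approx(p.p_0)

    def test_steady_mass_balance(self, mean_params):
        eq = equilibrium_state(mean_params, 10.8)
        assert eq.q_v == pytest.approx(10.8)
        assert eq.q_s == 0.0

    def test_negative_inflow_rejected(self, mean_params):
        with pytest.raises(DomainError):
            equilibrium_state(mean_params, -1.0)

    def test_residual_for_random_parameter_draws(self, rng):
        """Root-finding stays tight across +/-50% parameter perturbations."""
        base = ModelParameters()
        for _ in range(10):
            factors = rng.uniform(0.5, 1.5, size=24)
            draws = {
                name: getattr(base, name) * f
                for name, f in zip(
                    ("e_a0", "R_av0", "R_v0", "e_c0", "e_s", "L_cs", "R_cs",
                     "rho_l", "p_0", "b_Ls", "a_Rs", "L_v", "tau_reg", "k_ea",
                     "n_ea", "m_ea", "n_Rav", "m_Rav", "e_v1", "e_v2",
                     "m_ev1", "m_ev2", "m_Rv", "k_ec"),
                    factors,
                )
            }
            p = base.replace(**draws)
            eq = equilibrium_state(p, 10.8)
            inflow = PeriodicWaveform.constant(10.8)
            assert np.abs(rhs(0.0, eq, p, inflow)).max() < 1e-9
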