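"""Closed-form scaling theory: regime exponents, boundaries, relations."""

import math

import numpy as np
import pytest
from hypothesis import HealthCheck, assume, given, settings
from hypothesis import strategies as st

from poretrans.analysis import least_squares_exponent
from poretrans.data import (DERIVED_EXPONENTS_REPORTED, OBSERVED_EXPONENTS,
                            SALT_CASES)
from poretrans.errors import (AnalysisError, SingularParameterError)
from poretrans.theory import (TheoryParameters, boundary_exponents,
                              boundary_slopes, check_inequalities,
                              derived_relations, invert_observed,
                              pulled_chain_zp, regime_exponents,
                              round_half_up, solve_tension_ode, theory_curve)

# illustration parameter set: nu_s=0.4, z_p(1-gamma_p)=1.4, p_z(1-q)=1.67,
# q=0.25 (one concrete (gamma_p, z_p, p_z) realisation of the products)
ILLUSTRATION = TheoryParameters(nu_s=0.4, gamma_p=0.5, z_p=2.8,
                                q=0.25, p_z=1.67 / 0.75)


class TestRegimeExponents:
    def test_unbiased_alpha(self):
        alpha, delta = regime_exponents(ILLUSTRATION, "UB")
        assert alpha == pytest.approx(2.56)
        assert delta == 0.0

    def test_trumpet_alpha_matches_monovalent_fit(self):
        tp = TheoryParameters(nu_s=0.35, q=0.86, p_z=1.65 / 0.14)
        alpha, delta = regime_exponents(tp, "SD_T")
        assert round_half_up(alpha) == 1.05
        assert round_half_up(delta) == 1.65

    def test_isoflux_alpha_divalent(self):
        alpha, delta = regime_exponents(TheoryParameters(nu_s=0.50), "SD_I")
        assert alpha == pytest.approx(1.50)
        assert delta == 1.0

    def test_missing_parameter_named(self):
        with pytest.raises(AnalysisError, match="nu_s"):
            regime_exponents(TheoryParameters(), "SD_I")


class TestBoundaries:
    def test_f1_exponent_is_minus_one(self):
        b = boundary_exponents(ILLUSTRATION)
        assert b["f1"] == -1.0

    def test_f2_from_monovalent_values(self):
        tp = TheoryParameters(nu_s=0.35, rho=1.50, eta=1.32)
        b = boundary_exponents(tp)
        assert b["f2"] == pytest.approx(-0.525)
        assert b["N2"] == pytest.approx(-1.0 / 0.525)

    def test_reciprocity(self):
        b = boundary_exponents(ILLUSTRATION)
        for k in ("1", "2", "3"):
            assert b[f"N{k}"] * b[f"f{k}"] == pytest.approx(1.0)

    def test_singular_when_pz_one_minus_q_is_one(self):
        tp = TheoryParameters(nu_s=0.4, gamma_p=0.5, z_p=2.8, q=0.5, p_z=2.0)
        with pytest.raises(SingularParameterError):
            boundary_exponents(tp)


class TestDerivedRelations:
    def test_q_from_blob_exponent(self):
        tp, _ = derived_relations(nu_b=0.68)
        assert round_half_up(tp.q) == 0.19
        tp2, _ = derived_relations(nu_b=0.55)
        assert round_half_up(tp2.q) == 0.29

    def test_zp_from_gamma_relation(self):
        tp, _ = derived_relations(nu_s=0.35, gamma_p=0.78)
        assert round_half_up(tp.z_p) == 4.95
        tp2, _ = derived_relations(nu_s=0.50, gamma_p=0.75)
        assert round_half_up(tp2.z_p) == 4.00

    def test_rod_limit(self):
        tp, _ = derived_relations(nu_b=1.0)
        assert tp.q == pytest.approx(0.0)
        assert tp.z == pytest.approx(3.0)

    def test_overdetermined_reports_residuals(self):
        tp, resid = derived_relations(nu_b=0.68, q=0.20)
        assert "q" in resid
        assert tp.q == pytest.approx(0.20)  # given value is not overwritten
        assert resid["q"] == pytest.approx(0.20 - 0.32 / 1.68)

    def test_inconsistent_closure_raises(self):
        with pytest.raises(AnalysisError, match="residual"):
            derived_relations(nu_b=0.68, q=0.60)


class TestInversion:
    @pytest.mark.parametrize("salt", SALT_CASES)
    def test_inversion_chain_reproduces_reported_values(self, salt):
        obs = OBSERVED_EXPONENTS[salt]
        inv = invert_observed(obs["alpha_UB"], obs["alpha_SDT"],
                              obs["alpha_SDI"], obs["delta_SDT"],
                              obs["gamma_p"])
        assert inv.rounded() == DERIVED_EXPONENTS_REPORTED[salt]

    def test_stretched_limit(self):
        inv = invert_observed(3.5, 2.0, 2.0, 1.5, 0.5)
        assert inv.nu_s == pytest.approx(1.0)
        assert inv.q == pytest.approx(0.0)

    def test_singularities(self):
        with pytest.raises(SingularParameterError):
            invert_observed(2.4, 1.05, 1.35, 1.0, 0.78)
        with pytest.raises(SingularParameterError):
            invert_observed(2.4, 1.05, 1.35, 1.65, 1.0)

    @pytest.mark.parametrize("salt", SALT_CASES)
    def test_roundtrip_through_relations_is_idempotent(self, salt):
        obs = OBSERVED_EXPONENTS[salt]
        inv = invert_observed(obs["alpha_UB"], obs["alpha_SDT"],
                              obs["alpha_SDI"], obs["delta_SDT"],
                              obs["gamma_p"])
        tp = inv.to_theory_params()
        closed, resid = derived_relations(nu_s=tp.nu_s, q=tp.q, p_z=tp.p_z,
                                          z_p=tp.z_p, gamma_p=None)
        # gamma_p re-derived from (nu_s, z_p) differs from the measured one
        # only by the closure of the consistency relation
        assert closed.gamma_p == pytest.approx(
            (1 + tp.nu_s) / (tp.z_p * tp.nu_s))
        assert not resid


class TestInequalitiesAndPulledChain:
    @pytest.mark.parametrize("salt", SALT_CASES)
    def test_reported_exponents_satisfy_all_inequalities(self, salt):
        obs = OBSERVED_EXPONENTS[salt]
        inv = invert_observed(obs["alpha_UB"], obs["alpha_SDT"],
                              obs["alpha_SDI"], obs["delta_SDT"],
                              obs["gamma_p"])
        report = check_inequalities(inv.to_theory_params())
        assert all(ok for ok, _ in report.values())

    def test_constructed_violation_has_negative_margin(self):
        tp = TheoryParameters(nu_s=1.0, z_p=3.0, gamma_p=1.0, q=0.25,
                              p_z=1.67 / 0.75)
        report = check_inequalities(tp)
        ok, margin = report["nu_s*z_p*gamma_p < 2"]
        assert not ok
        assert margin == pytest.approx(-1.0)

    def test_pulled_chain_zp(self):
        assert round_half_up(pulled_chain_zp(0.71)) == 2.82
        assert round_half_up(pulled_chain_zp(0.57)) == 3.51
        assert pulled_chain_zp(1.0) == 2.0
        with pytest.raises(SingularParameterError):
            pulled_chain_zp(0.0)


class TestTheoryCurve:
    def test_continuity_at_boundaries(self):
        tp = ILLUSTRATION
        b = boundary_exponents(tp)
        N = 64.0
        for key in ("f1", "f2", "f3"):
            edge = N ** b[key]
            grid = np.array([edge * (1 - 1e-9), edge * (1 + 1e-9)])
            _, tau, _ = theory_curve(tp, grid, "tau_vs_f", N=N)
            assert abs(math.log(tau[1] / tau[0])) < 1e-6

    def test_trumpet_slope_matches_illustration(self):
        tp = ILLUSTRATION
        b = boundary_exponents(tp)
        N = 1e4
        f2, f3 = N ** b["f2"], N ** b["f3"]
        grid = np.geomspace(f2 * 1.01, f3 * 0.99, 10)
        _, tau, regimes = theory_curve(tp, grid, "tau_vs_f", N=N)
        assert all(r == "SD_T" for r in regimes)
        slope = least_squares_exponent(list(zip(grid, tau))).value
        assert slope == pytest.approx(-1.67, abs=1e-9)

    def test_isoflux_slope_vs_N(self):
        tp = ILLUSTRATION
        b = boundary_exponents(tp)
        f = 0.5
        N3 = f ** b["N3"]
        grid = np.geomspace(N3 * 1.01, N3 * 100, 8)
        _, tau, regimes = theory_curve(tp, grid, "tau_vs_N", f=f)
        assert all(r == "SD_I" for r in regimes)
        slope = least_squares_exponent(list(zip(grid, tau))).value
        assert slope == pytest.approx(1 + tp.nu_s, abs=1e-9)


class TestTensionOde:
    def test_dropping_subleading_term_negligible_at_large_force(self):
        tp = TheoryParameters(nu_s=0.35, q=0.86, p_z=1.65 / 0.14)
        full = solve_tension_ode(tp, 1e4, 2 ** 14)
        dropped = solve_tension_ode(tp, 1e4, 2 ** 14,
                                    include_subleading=False)
        assert abs(full - dropped) / full < 0.01

    def test_isoflux_variant_matches_closed_form(self):
        tp = TheoryParameters(nu_s=0.35)
        Ns = [2 ** k for k in range(10, 21, 2)]
        taus = [solve_tension_ode(tp, 50.0, N, variant="isoflux") for N in Ns]
        slope = least_squares_exponent(list(zip(Ns, taus))).value
        assert slope == pytest.approx(1 + 0.35, abs=0.02)
        # and tau ~ f^-1 at fixed N
        assert (solve_tension_ode(tp, 100.0, 2 ** 16, variant="isoflux")
                / solve_tension_ode(tp, 200.0, 2 ** 16, variant="isoflux")
                == pytest.approx(2.0, rel=1e-6))


@settings(suppress_health_check=[HealthCheck.filter_too_much,
                                 HealthCheck.too_slow],
          derandomize=True, max_examples=80, deadline=None)
@given(nu_s=st.floats(0.2, 0.8), A=st.floats(1.05, 3.0),
       B=st.floats(1.05, 3.0), q=st.floats(0.05, 0.95),
       gamma_p=st.floats(0.3, 0.9))
def test_slope_ordering_follows_from_inequalities(nu_s, A, B, q, gamma_p):
    """Whenever the five consistency inequalities hold, the demarcation
    slopes order as X1 < X2 < X3 and Y1 > Y2 > Y3.

    A = z_p(1-gamma_p) and B = p_z(1-q) parameterise the feasible set
    directly.
    """
    tp = TheoryParameters(nu_s=nu_s, gamma_p=gamma_p,
                          z_p=A / (1.0 - gamma_p), q=q,
                          p_z=B / (1.0 - q))
    report = check_inequalities(tp)
    assume(all(ok for ok, _ in report.values()))
    (X1, X2, X3), (Y1, Y2, Y3) = boundary_slopes(tp)
    assert X1 < X2 < X3
    assert Y1 > Y2 > Y3
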