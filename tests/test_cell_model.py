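import numpy as np
import pytest

import tcell_calcium as tc
from tcell_calcium.cell_model import (CellParams, ClosureError,
                                      CompiledModel, resting_state, rhs,
                                      steady_state_closure)
from tcell_calcium.protocols import Segment, build_protocol


@pytest.fixture()
def fresh_params():
    return tc.default_params()


class TestClosure:
    def test_derived_parameters_match_reference(self, params):
        """The four steady-state-derived values, to 4 significant figures."""
        assert params.ip3.gamma_P == pytest.approx(0.01149, abs=5e-6)
        assert params.pmca.rho == pytest.approx(68.57, abs=5e-3)
        assert params.ip3r.rho == pytest.approx(11.35, abs=5e-3)
        assert params.crac.rho_minus == pytest.approx(0.5115, abs=5e-5)

    def test_idempotent(self, fresh_params):
        first = steady_state_closure(fresh_params)
        second = steady_state_closure(fresh_params)
        assert first == second

    def test_rejects_zero_denominator(self, fresh_params):
        # vanishing resting IP3R current makes rho_IP3R diverge
        fresh_params.ip3r.g_bar = 0.0
        with pytest.raises(ClosureError):
            steady_state_closure(fresh_params)


class TestRestingState:
    def test_gates(self, params):
        s = resting_state(params)
        assert s.g_PMCA == pytest.approx(0.2, rel=1e-12)
        assert s.g_IP3R == pytest.approx(0.1590, abs=2e-4)
        assert s.h_IP3R == pytest.approx(0.0525, abs=2e-4)
        assert s.rho_CRAC == params.crac.rho0

    def test_is_fixed_point(self, params):
        """All 7 derivatives vanish at the closed resting state."""
        proto = build_protocol([Segment(0.0)], 100.0, params)
        d = rhs(resting_state(params), 0.0, proto, params)
        scale = np.abs(resting_state(params).as_array())
        assert np.all(np.abs(d) <= 1e-10 * scale + 1e-14)

    def test_requires_closure(self):
        p = CellParams()  # gamma_P still NaN
        with pytest.raises(ValueError, match="closure"):
            resting_state(p)


class TestRhs:
    def test_ip3_production_under_stimulus(self, params):
        """dP/dt at rest with T = 1.6 is +0.06 nM/s."""
        proto = build_protocol([Segment(0.0, T=1.6)], 100.0, params)
        d = rhs(resting_state(params), 0.0, proto, params)
        assert d[2] == pytest.approx(6e-5, rel=1e-3)  # μM/s

    def test_pmca_block_unbalances_rest(self, params):
        """Blocking PMCA at rest leaves the raw CRAC influx unbalanced."""
        proto = build_protocol(
            [Segment(0.0, pmca_blocked=True)], 100.0, params)
        d = rhs(resting_state(params), 0.0, proto, params)
        cm = CompiledModel(params)
        g = params.derived_geometry()
        I_crac = -2.2858e-16  # resting single-channel CRAC current, A
        expected = -(g.xi * params.crac.rho0 * I_crac) * cm.flux \
            / (1.0 + 250.0)
        assert d[0] > 0
        assert d[0] == pytest.approx(expected, rel=1e-3)

    def test_flux_conversion_factor(self, params):
        """ξρI → μM/s conversion pinned by the worked CRAC example:
        ρ = 3.9/μm², ξ = 0.385/μm, I = −2e-16 A gives ≈ +1.56 μM/s raw."""
        cm = CompiledModel(params)
        raw = -(0.385 * 3.9 * (-2e-16)) * cm.flux
        assert raw == pytest.approx(1.556, abs=2e-3)

    def test_sign_conventions_term_by_term(self, params):
        """SERCA lowers C and raises C_ER; IP3R/CRAC (negative I) raise C."""
        cm = CompiledModel(params)
        s = resting_state(params)
        y = s.as_array()
        base = cm(0.0, y, 1.0, 2000.0, False, False, False)
        only_serca = cm(0.0, y, 1.0, 2000.0, False, True, True)
        # with PMCA and CRAC blocked, remaining PM flux is zero and the
        # ER pair still balances at rest
        assert only_serca[0] == pytest.approx(0.0, abs=1e-12)
        # doubling SERCA density: C falls, C_ER rises
        q = params.copy()
        steady_state_closure(q)
        q.serca.rho *= 2.0
        cm2 = CompiledModel(q)
        d = cm2(0.0, y, 1.0, 2000.0, False, False, False)
        assert d[0] < base[0]
        assert d[1] > base[1]

    def test_compiled_vector_rhs_matches_python(self, params):
        """The numba core and the reference Python RHS agree."""
        from tcell_calcium._integrator import _rhs
        from tcell_calcium.cell_model import CONC_FLOOR
        cm = CompiledModel(params)
        pv = cm.as_vector()
        rng = np.random.default_rng(0)
        for _ in range(25):
            y = np.array([
                10 ** rng.uniform(-2, 0.7), 10 ** rng.uniform(0.5, 2.8),
                10 ** rng.uniform(-3, -0.5), rng.uniform(0.52, 3.9),
                rng.uniform(0, 0.81), rng.uniform(0, 1), rng.uniform(0, 1),
            ])
            T = rng.uniform(1.0, 2.0)
            c_ext = 10 ** rng.uniform(-0.5, 3.5)
            blocks = tuple(bool(b) for b in rng.integers(0, 2, 3))
            ref = cm(0.0, y, T, c_ext, *blocks)
            out = np.empty(7)
            _rhs(0.0, y, pv, T, c_ext, blocks[0], blocks[1], blocks[2],
                 CONC_FLOOR, out)
            np.testing.assert_allclose(out, ref, rtol=1e-12, atol=1e-22)


class TestConservation:
    def test_total_calcium_conserved_without_pm_transport(self, params):
        """With PMCA and CRAC blocked only ER↔cytosol exchange remains;
        volume-weighted total calcium (free + buffered) is conserved."""
        proto = build_protocol(
            [Segment(0.0, T=1.6, pmca_blocked=True, crac_blocked=True)],
            600.0, params, name="pm-blocked")
        y0 = resting_state(params).as_array()
        y0[0] = 0.3  # kick the cytosol so fluxes are non-trivial
        tr = tc.integrate(params, proto, y0=y0)
        g = params.derived_geometry()
        b = params.buffers
        C, CER = tr["C"], tr["C_ER"]
        total = (g.V_cyt * (C + b.b0 * C / (C + b.K_b))
                 + g.V_ER * (CER + b.b_ER0 * CER / (CER + b.K_ERb)))
        drift = np.max(np.abs(total - total[0])) / total[0]
        assert drift < 1e-4  # < 0.01%
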