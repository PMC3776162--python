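import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tcell_calcium.biophysics import ElectroParams
from tcell_calcium.transmembrane import (CracParams, Ip3rParams, PmcaParams,
                                         SercaParams, crac_current,
                                         crac_target_density, ip3r_current,
                                         ip3r_gates_inf, pmca_current,
                                         pmca_gate_inf, serca_current)

EP = ElectroParams()
CRAC = CracParams()
IP3R = Ip3rParams()
PMCA = PmcaParams()
SERCA = SercaParams()


class TestCrac:
    def test_resting_current(self):
        """2 fS at 114.3 mV driving force → ≈ −2.29e-16 A inward."""
        I = crac_current(-60.0, 0.1, 2000.0, CRAC, EP)
        assert I == pytest.approx(-2.286e-16, rel=1e-3)

    def test_zero_at_reversal(self):
        from tcell_calcium.biophysics import reversal_potential
        vbar = reversal_potential(2000.0, 0.1, EP.dV_C, EP)
        assert crac_current(vbar, 0.1, 2000.0, CRAC, EP) == 0.0

    def test_outward_current_possible(self):
        """At surrogate zero-calcium, raised cytosolic calcium drives an
        outward (positive) CRAC current — deliberately not clamped."""
        I = crac_current(-60.0, 1.0, 0.385, CRAC, EP)
        assert I > 0.0

    def test_target_density_limits_and_rest(self):
        assert crac_target_density(0.0, CRAC) == pytest.approx(3.9)
        assert crac_target_density(1e9, CRAC) == pytest.approx(
            CRAC.rho_minus, rel=1e-6)
        # at the resting ER calcium the target equals the resting density
        assert crac_target_density(400.0, CRAC) == pytest.approx(0.6,
                                                                 abs=2e-4)

    @given(st.floats(0.0, 2000.0))
    def test_target_density_bounded_and_monotone(self, C_ER):
        rho = crac_target_density(C_ER, CRAC)
        assert CRAC.rho_minus <= rho <= CRAC.rho_plus
        assert crac_target_density(C_ER + 10.0, CRAC) <= rho

    def test_density_invariant_enforced(self):
        with pytest.raises(ValueError):
            CracParams(rho0=0.2, rho_minus=0.5, rho_plus=3.9)


class TestIp3r:
    def test_resting_gates(self):
        g, h = ip3r_gates_inf(0.1, 0.0087, IP3R)
        assert g == pytest.approx(0.1590, abs=2e-4)
        assert h == pytest.approx(0.0525, abs=2e-4)

    def test_no_calcium_no_activation(self):
        g, _ = ip3r_gates_inf(0.0, 0.1, IP3R)
        assert g == 0.0

    def test_open_probability_bell_shape(self):
        """g·h has a single interior maximum as calcium varies."""
        C = np.logspace(-3, 2, 200)
        po = np.array([np.prod(ip3r_gates_inf(c, 0.05, IP3R)) for c in C])
        imax = po.argmax()
        assert 0 < imax < len(C) - 1
        assert np.all(np.diff(po[:imax + 1]) >= -1e-15)
        assert np.all(np.diff(po[imax:]) <= 1e-15)

    @pytest.mark.parametrize("C", [0.1, 0.5, 2.0])
    def test_ip3_relieves_inhibition(self, C):
        """h_inf rises with IP3 at fixed calcium (10 → 33 → 100 nM)."""
        hs = [ip3r_gates_inf(C, P, IP3R)[1] for P in (0.010, 0.033, 0.100)]
        assert hs[0] < hs[1] < hs[2]

    def test_resting_current(self):
        g, h = ip3r_gates_inf(0.1, 0.0087, IP3R)
        I = ip3r_current(g, h, -60.0, -60.0, 0.1, 400.0, IP3R, EP)
        assert I == pytest.approx(-2.552e-17, rel=2e-3)

    def test_rectification(self):
        """Reverse (ER-uptake) flux is clamped to zero."""
        # inverted gradient: cytosol far above ER calcium
        I = ip3r_current(0.5, 0.5, -60.0, -60.0, 500.0, 1.0, IP3R, EP)
        assert I == 0.0

    def test_zero_gate_zero_current(self):
        assert ip3r_current(0.0, 0.5, -60, -60, 0.1, 400, IP3R, EP) == 0.0


class TestPumps:
    def test_pmca_rest(self):
        g = pmca_gate_inf(0.1, PMCA)
        assert g == pytest.approx(0.2, rel=1e-12)
        assert pmca_current(g, PMCA) == pytest.approx(2e-18, rel=1e-12)

    def test_serca_values(self):
        assert serca_current(0.0, SERCA) == 0.0
        assert serca_current(0.25, SERCA) == pytest.approx(1.5e-18,
                                                           rel=1e-12)
        assert serca_current(0.1, SERCA) == pytest.approx(4.138e-19,
                                                          rel=1e-3)

    @given(st.floats(0.0, 100.0))
    def test_pump_currents_nonnegative(self, C):
        assert serca_current(C, SERCA) >= 0.0
        assert pmca_current(pmca_gate_inf(C, PMCA), PMCA) >= 0.0
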