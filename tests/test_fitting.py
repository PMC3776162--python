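import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import tcell_calcium as tc
from tcell_calcium import fitting
from tcell_calcium.fitting import (FitProblem, fit_parameters, get_param,
                                   quality_index, sensitivity_scan,
                                   simulate_at)


@pytest.fixture(scope="module")
def problem(params, noiseless_target):
    proto = tc.preset("fig3", params)
    return FitProblem(params=params, protocol=proto,
                      target_t=noiseless_target["t"].to_numpy(),
                      target_E=noiseless_target["C"].to_numpy())


class TestQualityIndex:
    @pytest.mark.parametrize("X, E, expected", [
        ([1.0, 2.0], [1.0, 2.0], 0.0),
        ([1.1], [1.0], 0.01),
        ([0.5, 1.5], [1.0, 1.0], 0.25),
    ])
    def test_values(self, X, E, expected):
        assert quality_index(X, E) == pytest.approx(expected, abs=1e-14)

    @given(st.floats(0.1, 10.0))
    def test_scale_invariant(self, scale):
        X = np.array([0.5, 1.0, 2.0])
        E = np.array([0.6, 1.1, 1.9])
        assert quality_index(scale * X, scale * E) == pytest.approx(
            quality_index(X, E), rel=1e-12)

    def test_rejects_nonpositive_target(self):
        with pytest.raises(ValueError):
            quality_index([1.0], [0.0])
        with pytest.raises(ValueError):
            quality_index([1.0, 2.0], [1.0])


class TestFitProblem:
    def test_candidate_recloses_steady_state(self, problem, params):
        vals = [get_param(params, n) for n in problem.variable]
        vals[problem.variable.index("rho_CRAC0")] = 0.9
        q = problem.candidate(vals)
        # rho_minus must track the new resting density:
        # rho_minus = (rho0 - rho_plus (1 - H0)) / H0
        from tcell_calcium.biophysics import hill
        H0 = hill(400.0, 169.0, 4.2)
        assert q.crac.rho_minus == pytest.approx(
            (0.9 - 3.9 * (1.0 - H0)) / H0, rel=1e-9)
        assert q.crac.rho0 == 0.9

    def test_objective_zero_at_truth(self, problem, params):
        truth = [get_param(params, n) for n in problem.variable]
        assert problem.objective(truth) < 1e-10

    def test_objective_penalty_on_failure(self, problem):
        # rho_plus below rho0 violates the density ordering → penalty
        bad = dict(zip(problem.variable,
                       [63.0, 0.0087, 0.0006, 700.0, 0.6, 3.9]))
        bad["rho_CRAC_plus"] = 0.1
        assert problem.objective([bad[n] for n in problem.variable]) \
            == problem.penalty_qi

    def test_crac_fold_bound_enforced(self, params, noiseless_target):
        proto = tc.preset("fig3", params)
        with pytest.raises(ValueError, match="10-fold"):
            FitProblem(params=params, protocol=proto,
                       target_t=noiseless_target["t"].to_numpy(),
                       target_E=noiseless_target["C"].to_numpy(),
                       bounds={"rho_CRAC0": (0.3, 0.6),
                               "rho_CRAC_plus": (2.0, 12.0)})

    def test_target_outside_span_rejected(self, params):
        proto = tc.preset("fig3", params)
        with pytest.raises(ValueError, match="span"):
            FitProblem(params=params, protocol=proto,
                       target_t=np.array([10.0, 500.0]),
                       target_E=np.array([0.1, 0.1]))


class TestSimulateAt:
    def test_resting_protocol_returns_baseline(self, params):
        from tcell_calcium.protocols import Segment, build_protocol
        proto = build_protocol([Segment(0.0)], 100.0, params)
        X = simulate_at(params, proto, [10.0, 50.0, 99.0])
        np.testing.assert_allclose(X, params.rest.C0, atol=1e-6)


class TestFitParameters:
    def test_degenerate_empty_variable_set(self, problem):
        fp = FitProblem(params=problem.params, protocol=problem.protocol,
                        target_t=problem.target_t,
                        target_E=problem.target_E, variable=())
        res = fit_parameters(fp, seed=0)
        assert res.params == {}
        assert res.qi < 1e-10

    def test_seed_reproducible(self, params, noiseless_target):
        proto = tc.preset("fig3", params)
        fp = FitProblem(params=params, protocol=proto,
                        target_t=noiseless_target["t"].to_numpy(),
                        target_E=noiseless_target["C"].to_numpy(),
                        variable=("P0", "beta_P"))
        kw = dict(popsize=4, maxiter=3, polish=False)
        a = fit_parameters(fp, seed=5, **kw)
        b = fit_parameters(fp, seed=5, **kw)
        assert a.params == b.params
        assert a.qi == b.qi

    def test_two_step_refinement_never_worse(self, problem):
        """Coarse fit, then fine fit seeded from it: QI cannot rise."""
        coarse = fit_parameters(problem, seed=2, popsize=4, maxiter=3,
                                polish=False)
        x0 = [coarse.params[n] for n in problem.variable]
        fine = fit_parameters(problem, seed=3, popsize=4, maxiter=5,
                              polish=True, polish_maxfev=300, x0=x0)
        assert fine.qi <= coarse.qi


class TestSensitivityScan:
    def test_deterministic_and_excludes_derived(self, params,
                                                noiseless_target):
        tgt = tc.generate_target(
            tc.TargetSpec(params, noise_sd=0.05, seed=1))
        proto = tc.preset("fig3", params)
        fp = FitProblem(params=params, protocol=proto,
                        target_t=tgt["t"].to_numpy(),
                        target_E=tgt["C"].to_numpy())
        a = sensitivity_scan(params, fp)
        b = sensitivity_scan(params, fp)
        assert (a["delta_qi_pct"] == b["delta_qi_pct"]).all()
        # steady-state-derived parameters are not scanned directly
        for derived in ("gamma_P", "rho_PMCA", "rho_IP3R",
                        "rho_CRAC_minus"):
            assert derived not in set(a["parameter"])
        assert a["ok"].all()

    def test_zero_baseline_rejected(self, problem, params):
        with pytest.raises(ValueError, match="baseline QI is zero"):
            sensitivity_scan(params, problem)
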