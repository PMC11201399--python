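import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from ckdtraj import multistate as ms
from ckdtraj.eventlog import EventLog
from ckdtraj.simulate import make_preset, simulate_panel


def two_state_p11(a, b, t):
    """Closed-form occupancy of state 1 for intensities a (1->2), b (2->1)."""
    return (b + a * np.exp(-(a + b) * t)) / (a + b)


def _model(log_q0, beta, transitions=ms.DEFAULT_TRANSITIONS, covs=("exposure",)):
    st_ = ms.TransitionStructure(transitions=transitions)
    return ms.IntensityModel(structure=st_, covariate_names=covs,
                             log_q0=np.asarray(log_q0, float),
                             beta=np.asarray(beta, float))


class TestGenerator:
    def test_zero_beta_generator_independent_of_x(self):
        m = _model(np.log([0.1, 0.2, 0.05, 0.3]), np.zeros((4, 1)))
        assert np.allclose(m.generator([0.0]), m.generator([1.0]))

    def test_log2_effect_doubles_single_intensity(self):
        beta = np.zeros((4, 1))
        beta[2, 0] = np.log(2)  # G3 -> G4/5
        m = _model(np.log([0.1, 0.2, 0.05, 0.3]), beta)
        q0 = m.intensities([0.0])
        q1 = m.intensities([1.0])
        assert q1[2] == pytest.approx(2 * q0[2])
        assert np.allclose(q1[[0, 1, 3]], q0[[0, 1, 3]])

    @given(rates=st.lists(st.floats(1e-4, 5.0), min_size=4, max_size=4),
           x=st.sampled_from([0.0, 1.0]))
    def test_rows_sum_to_zero_offdiag_nonnegative(self, rates, x):
        m = _model(np.log(rates), np.full((4, 1), 0.3))
        Q = m.generator([x])
        assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12)
        off = Q - np.diag(np.diag(Q))
        assert (off >= 0).all()
        # disallowed direct jump between extreme states
        assert Q[0, 2] == 0 and Q[2, 0] == 0


class TestTransitionProbability:
    def test_identity_at_time_zero(self):
        Q = np.array([[-0.3, 0.3], [0.7, -0.7]])
        assert np.allclose(ms.transition_probability(Q, 0.0), np.eye(2))

    @pytest.mark.parametrize("a,b,t", [(0.3, 0.7, 2.5), (1.2, 0.05, 0.4), (0.01, 0.01, 30.0)])
    def test_two_state_closed_form(self, a, b, t):
        Q = np.array([[-a, a], [b, -b]])
        P = ms.transition_probability(Q, t)
        assert P[0, 0] == pytest.approx(two_state_p11(a, b, t), abs=1e-10)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)
        assert ((P >= 0) & (P <= 1)).all()

    def test_negative_time_rejected(self):
        Q = np.array([[-0.3, 0.3], [0.7, -0.7]])
        with pytest.raises(ValueError):
            ms.transition_probability(Q, -1.0)

    def test_non_generator_rejected(self):
        with pytest.raises(ValueError):
            ms.transition_probability(np.array([[0.1, 0.2], [0.3, 0.4]]), 1.0)

    def test_three_state_against_gillespie(self):
        from ckdtraj.simulate import sample_ctmc_path, state_at
        q = {("G1/2", "G3"): 0.4, ("G3", "G1/2"): 0.2,
             ("G3", "G4/5"): 0.3, ("G4/5", "G3"): 0.5}
        struct = ms.TransitionStructure()
        Q = ms._generator_from_q(np.array([0.4, 0.2, 0.3, 0.5]), struct)
        t = 1.5
        P = ms.transition_probability(Q, t)
        n = 20000
        rng = np.random.default_rng(42)
        end_states = np.empty(n, dtype=object)
        for i in range(n):
            jt, js = sample_ctmc_path(q, "G3", t + 1.0, rng)
            end_states[i] = state_at(jt, js, t)[0]
        for j, s in enumerate(struct.states):
            phat = np.mean(end_states == s)
            p = P[1, j]
            se = np.sqrt(p * (1 - p) / n)
            assert abs(phat - p) < 3 * se + 1e-12


def _single_pair_log(dt, s0="G1/2", s1="G1/2"):
    ev = pd.DataFrame({"patient_id": ["p", "p"], "time_months": [0.0, dt],
                       "stage": [s0, s1]})
    cz = pd.DataFrame({"patient_id": ["p"], "censor_months": [dt + 1]})
    return EventLog(events=ev, censoring=cz, stage_space="merged")


class TestLogLikelihood:
    def test_single_event_patient_contributes_zero(self):
        ev = pd.DataFrame({"patient_id": ["p"], "time_months": [0.0], "stage": ["G3"]})
        cz = pd.DataFrame({"patient_id": ["p"], "censor_months": [1.0]})
        log = EventLog(events=ev, censoring=cz, stage_space="merged")
        m = _model(np.log([0.1, 0.2, 0.05, 0.3]), np.zeros((4, 0)), covs=())
        assert ms.log_likelihood(m, log) == 0.0

    def test_single_pair_matches_two_state_closed_form(self):
        # only G1/2 <-> G3 active: states G4/5 unreachable, so the
        # 3-state chain restricted to {G1/2, G3} is the 2-state chain
        a, b, dt = 0.25, 0.6, 1.7
        m = _model(np.log([a, b, 1e-12, 1e-12]), np.zeros((4, 0)), covs=())
        ll = ms.log_likelihood(m, _single_pair_log(dt))
        assert ll == pytest.approx(np.log(two_state_p11(a, b, dt)), abs=1e-6)

    def test_invariant_under_patient_reordering(self):
        cfg = make_preset("recovery-benchmark", seed=5, n_patients=50)
        log, cov, _ = simulate_panel(cfg)
        m = _model(np.log([0.1, 0.07, 0.05, 0.12]), np.full((4, 1), 0.1))
        ll1 = ms.log_likelihood(m, log, cov)
        shuffled = EventLog(
            events=log.events.sort_values(["patient_id", "time_months"],
                                          ascending=[False, True], ignore_index=True)
            .sort_values(["patient_id", "time_months"], ignore_index=True),
            censoring=log.censoring.sample(frac=1, random_state=0),
            stage_space="merged")
        ll2 = ms.log_likelihood(m, shuffled, cov.sample(frac=1, random_state=1))
        assert ll1 == pytest.approx(ll2, rel=1e-12)


def test_expm_fallback_matches_eigen_path():
    """The defective-generator fallback (expm/expm_frechet) agrees with
    the eigendecomposition route on a well-conditioned problem."""
    cfg = make_preset("recovery-benchmark", seed=8, n_patients=60)
    log, cov, _ = simulate_panel(cfg)
    panel = ms.make_panel(log, cov)
    theta = np.concatenate([np.log([0.1, 0.08, 0.06, 0.1]), [0.2, -0.1, 0.5, 0.05]])
    k, p = 4, panel.X.shape[1]
    log_q0, beta = theta[:k], theta[k:].reshape(k, p)
    q = np.exp(log_q0[None, :] + panel.X @ beta.T)
    Q = ms._generator_from_q(q, panel.structure)
    P_eig, dP_eig, _ = ms._pair_probabilities(theta, panel, want_grad=True)
    P_ref, dP_ref, _ = ms._pair_probabilities_expm(q, Q, panel, want_grad=True)
    assert np.allclose(P_eig, P_ref, atol=1e-10)
    assert np.allclose(dP_eig, dP_ref, atol=1e-8)


class TestGradient:
    def test_analytic_gradient_matches_finite_differences(self):
        cfg = make_preset("recovery-benchmark", seed=3, n_patients=150)
        log, cov, _ = simulate_panel(cfg)
        panel = ms.make_panel(log, cov)
        theta = np.concatenate([np.log([0.1, 0.08, 0.06, 0.1]),
                                [0.2, -0.1, 0.5, 0.05]])
        _, g = ms._loglik_grad(theta, panel)
        for j in range(len(theta)):
            h = 1e-6
            tp, tm = theta.copy(), theta.copy()
            tp[j] += h
            tm[j] -= h
            num = (ms._loglik_grad(tp, panel, want_grad=False)[0]
                   - ms._loglik_grad(tm, panel, want_grad=False)[0]) / (2 * h)
            assert g[j] == pytest.approx(num, rel=1e-4, abs=1e-6)


@pytest.fixture(scope="module")
def fitted():
    cfg = make_preset("recovery-benchmark", seed=17)
    log, cov, truth = simulate_panel(cfg)
    return ms.fit(log, cov), log, cov, truth


class TestFit:
    def test_converges_and_improves_on_crude_start(self, fitted):
        res, log, cov, _ = fitted
        assert res.converged
        panel = ms.make_panel(log, cov)
        rates, counts = ms.crude_rates(panel)
        theta0 = np.concatenate([np.log(rates), np.zeros(4)])
        ll0, _ = ms._loglik_grad(theta0, panel, want_grad=False)
        assert res.loglik >= ll0

    def test_ci_brackets_point_estimate(self, fitted):
        res, *_ = fitted
        ci = res.hr_ci
        hr = res.hazard_ratios
        assert (ci[:, 0] < hr).all() and (hr < ci[:, 1]).all()
        assert (hr > 0).all()

    def test_parameter_recovery_without_covariates(self):
        cfg = make_preset("recovery-benchmark", seed=29, n_patients=2000,
                          log_hr_exposure={})
        log, cov, truth = simulate_panel(cfg)
        res = ms.fit(log, covariate_cols=())
        q_hat = np.exp(res.model.log_q0)
        q_true = np.array([truth["q0"][f"{r}->{s}"]
                           for r, s in res.model.structure.transitions])
        # within 3 SEs of truth (delta method on the log scale)
        z = np.abs(res.model.log_q0 - np.log(q_true)) / res.se_log_q0
        assert (z < 3).all(), (q_hat, q_true, z)

    def test_covariate_model_never_decreases_likelihood(self, fitted):
        res, log, cov, _ = fitted
        res0 = ms.fit(log, cov, covariate_cols=())
        assert res.loglik >= res0.loglik - 1e-6

    def test_unobserved_transition_flagged_unidentified(self):
        # two patients bouncing between G1/2 and G3; G4/5 never seen
        ev = pd.DataFrame({
            "patient_id": ["a"] * 3 + ["b"] * 3,
            "time_months": [0.0, 1.0, 2.0] * 2,
            "stage": ["G1/2", "G3", "G1/2", "G3", "G1/2", "G3"],
        })
        cz = pd.DataFrame({"patient_id": ["a", "b"], "censor_months": [3.0, 3.0]})
        log = EventLog(events=ev, censoring=cz, stage_space="merged")
        with pytest.warns(UserWarning, match="unidentified"):
            res = ms.fit(log, covariate_cols=())
        assert ("G3", "G4/5") in res.unidentified
        assert np.isnan(res.se_log_q0[2])

    def test_fit_deterministic(self):
        cfg = make_preset("recovery-benchmark", seed=21, n_patients=300)
        log, cov, _ = simulate_panel(cfg)
        r1 = ms.fit(log, cov)
        r2 = ms.fit(log, cov)
        assert np.array_equal(r1.model.log_q0, r2.model.log_q0)
        assert np.array_equal(r1.model.beta, r2.model.beta)


class TestStructure:
    def test_default_is_tridiagonal(self):
        s = ms.TransitionStructure()
        assert ("G1/2", "G4/5") not in s.transitions
        assert ("G4/5", "G1/2") not in s.transitions
        assert len(s.transitions) == 4

    def test_invalid_structures_rejected(self):
        with pytest.raises(ValueError):
            ms.TransitionStructure(transitions=(("G3", "G3"),))
        with pytest.raises(ValueError):
            ms.TransitionStructure(transitions=(("G3", "XX"),))
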