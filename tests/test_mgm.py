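import numpy as np
import pytest
from sklearn.linear_model import Lasso

from coxmgm import cox
from coxmgm.citest import expand_conditioning_set
from coxmgm.datamodel import MixedDataset
from coxmgm.mgm import (MGMParams, PenaltyVector, fit_coxmgm,
                        negative_log_pseudolikelihood, params_to_graph,
                        penalized_objective, prepare_model_data)


def _duplicate(ds: MixedDataset) -> MixedDataset:
    idx = np.concatenate([np.arange(ds.n), np.arange(ds.n)])
    return ds.subset(idx)


@pytest.fixture(scope="module")
def mixed_md(sim_11_module):
    ds, _ = sim_11_module
    return ds, prepare_model_data(ds)


@pytest.fixture(scope="module")
def sim_11_module():
    from coxmgm.simulate import SimulationConfig, generate_dag, simulate_mixed_data
    model = generate_dag(SimulationConfig(n_nodes=11, avg_degree=2,
                                          n_samples=600, censoring="light", seed=3))
    return simulate_mixed_data(model)


class TestPseudolikelihood:
    def test_null_model_matches_independent_per_node_fits(self, mixed_md):
        ds, md = mixed_md
        # fit with overwhelming penalties: interactions zero, intercepts free
        fit = fit_coxmgm(md, 1e6, tol=1e-10, max_iter=2000)
        nll = negative_log_pseudolikelihood(fit.params, md)
        n = md.n
        expected = 0.0
        for s in range(md.p):    # Gaussian, fitted mean, unit variance
            x = md.X[:, s]
            expected += 0.5 * np.sum((x - x.mean()) ** 2) + 0.5 * n * np.log(2 * np.pi)
        for j, sl in enumerate(md.level_slices):   # multinomial MLE frequencies
            freq = md.D[:, sl].mean(axis=0)
            expected += -np.sum(md.D[:, sl].sum(axis=0) * np.log(freq))
        for m in range(md.r):    # null Cox partial likelihood
            ll, _, _ = cox.cox_loglik_eta(md.times[:, m], md.events[:, m],
                                          np.zeros(n))
            expected += -ll
        assert nll == pytest.approx(expected, rel=1e-4)

    def test_row_duplication_doubles_value(self, mixed_md):
        # additivity over samples holds exactly for the Gaussian and
        # multinomial conditionals; the Cox partial likelihood couples
        # samples through risk sets, so the check uses r = 0
        ds, md = mixed_md
        sub = MixedDataset(
            sample_ids=ds.sample_ids, continuous=ds.continuous,
            discrete=ds.discrete, times=np.empty((ds.n, 0)),
            events=np.empty((ds.n, 0), dtype=np.int64),
            continuous_names=ds.continuous_names,
            discrete_names=ds.discrete_names, censored_names=[], levels=ds.levels)
        smd = prepare_model_data(sub)
        params = MGMParams.zeros(smd.p, smd.level_slices, 0)
        params.alpha[:] = 0.1
        params.beta[0, 1] = params.beta[1, 0] = 0.2
        v1 = negative_log_pseudolikelihood(params, sub)
        v2 = negative_log_pseudolikelihood(params, _duplicate(sub))
        assert v2 == pytest.approx(2 * v1, rel=1e-9)

    def test_beta_perturbation_is_local_to_two_conditionals(self, mixed_md):
        # changing beta_st must leave every conditional except x_s, x_t alone;
        # total change = change attributable to those two Gaussian losses
        ds, md = mixed_md
        base = MGMParams.zeros(md.p, md.level_slices, md.r)
        pert = base.copy()
        pert.beta[0, 2] = pert.beta[2, 0] = 0.3

        def cont_loss(params, s):
            mu = params.alpha[s] + md.X @ params.beta[:, s]
            return 0.5 * np.sum((mu - md.X[:, s]) ** 2)

        delta_total = (negative_log_pseudolikelihood(pert, md)
                       - negative_log_pseudolikelihood(base, md))
        delta_local = sum(cont_loss(pert, s) - cont_loss(base, s) for s in (0, 2))
        assert delta_total == pytest.approx(delta_local, rel=1e-9)


class TestPenalizedObjective:
    def test_zero_params_zero_penalty(self, mixed_md):
        ds, md = mixed_md
        params = MGMParams.zeros(md.p, md.level_slices, md.r)
        lam = PenaltyVector(2, 2, 2, 2, 2)
        assert penalized_objective(params, md, lam) == pytest.approx(
            negative_log_pseudolikelihood(params, md))

    def test_group_l2_penalty_arithmetic(self, mixed_md):
        ds, md = mixed_md
        params = MGMParams.zeros(md.p, md.level_slices, md.r)
        sl = md.level_slices[0]
        params.rho[0, sl.start:sl.start + 3] = (3.0, 4.0, 0.0)
        lam = PenaltyVector(0, 2, 0, 0, 0)
        diff = (penalized_objective(params, md, lam)
                - negative_log_pseudolikelihood(params, md))
        assert diff == pytest.approx(2 * 5.0)

    def test_frobenius_penalty_arithmetic(self, mixed_md):
        ds, md = mixed_md
        params = MGMParams.zeros(md.p, md.level_slices, md.r)
        sl0, sl1 = md.level_slices[0], md.level_slices[1]
        params.phi[sl0.start:sl0.start + 2, sl1.start:sl1.start + 2] = 1.0
        params.phi[sl1, sl0] = params.phi[sl0, sl1].T
        lam = PenaltyVector(0, 0, 1, 0, 0)
        diff = (penalized_objective(params, md, lam)
                - negative_log_pseudolikelihood(params, md))
        assert diff == pytest.approx(2.0)

    def test_negative_penalty_rejected(self):
        with pytest.raises(ValueError):
            PenaltyVector(-0.1, 0, 0, 0, 0)


class TestFit:
    def test_overwhelming_penalty_empty_graph(self, mixed_md):
        ds, md = mixed_md
        fit = fit_coxmgm(md, 1e6)
        assert params_to_graph(fit.params, md).n_edges == 0

    def test_objective_trace_non_increasing(self, mixed_md):
        ds, md = mixed_md
        fit = fit_coxmgm(md, 0.1)
        for trace in fit.objective_traces:
            assert (np.diff(trace) <= 1e-10).all()

    def test_smooth_gradient_matches_finite_differences(self, mixed_md):
        from coxmgm.mgm import _smooth_parts
        ds, md = mixed_md
        rng = np.random.default_rng(0)
        P = MGMParams.zeros(md.p, md.level_slices, md.r)
        B = rng.normal(0, 0.05, P.beta.shape)
        P.beta[:] = B + B.T
        np.fill_diagonal(P.beta, 0)
        P.gamma[:] = rng.normal(0, 0.05, P.gamma.shape)
        P.rho[:] = rng.normal(0, 0.05, P.rho.shape)
        f, g = _smooth_parts(P, md, True)
        eps = 1e-6
        # symmetric beta perturbation carries the pair derivative
        Q1, Q2 = P.copy(), P.copy()
        Q1.beta[0, 1] += eps; Q1.beta[1, 0] += eps
        Q2.beta[0, 1] -= eps; Q2.beta[1, 0] -= eps
        fd = (_smooth_parts(Q1, md, False)[0] - _smooth_parts(Q2, md, False)[0]) / (2 * eps)
        assert g.beta[0, 1] == pytest.approx(fd, rel=1e-4)
        Q1, Q2 = P.copy(), P.copy()
        Q1.gamma[2, 0] += eps; Q2.gamma[2, 0] -= eps
        fd = (_smooth_parts(Q1, md, False)[0] - _smooth_parts(Q2, md, False)[0]) / (2 * eps)
        assert g.gamma[2, 0] == pytest.approx(fd, rel=1e-4)

    def test_continuous_only_matches_nodewise_lasso_oracle(self):
        rng = np.random.default_rng(5)
        n = 2000
        x1 = rng.normal(size=n)
        x2 = 0.5 * x1 + rng.normal(size=n)
        x3 = 0.5 * x2 + rng.normal(size=n)
        ds = MixedDataset([str(i) for i in range(n)], np.column_stack([x1, x2, x3]),
                          np.empty((n, 0), dtype=np.int64), np.empty((n, 0)),
                          np.empty((n, 0), dtype=np.int64),
                          ["x1", "x2", "x3"], [], [], [])
        md = prepare_model_data(ds)
        for lam in (0.05, 0.15):
            fit = fit_coxmgm(md, lam, tol=1e-9, max_iter=3000)
            pattern = {(s, t) for s in range(3) for t in range(s + 1, 3)
                       if abs(fit.params.beta[s, t]) > 1e-6}
            oracle = set()
            for s in range(3):
                others = [t for t in range(3) if t != s]
                l1 = Lasso(alpha=lam / 2).fit(md.X[:, others], md.X[:, s])
                for t, c in zip(others, l1.coef_):
                    if abs(c) > 1e-6:
                        oracle.add(tuple(sorted((s, t))))
            assert pattern == oracle == {(0, 1), (1, 2)}

    def test_edge_count_monotone_in_each_penalty(self, mixed_md):
        ds, md = mixed_md
        base = 0.15
        for field in ("cc", "cd", "dd", "sc", "sd"):
            counts = []
            for lam in np.geomspace(0.03, 1.0, 5):
                pv = {k: base for k in ("cc", "cd", "dd", "sc", "sd")}
                pv[field] = lam
                fit = fit_coxmgm(md, PenaltyVector(**pv), tol=1e-5)
                counts.append(params_to_graph(fit.params, md).n_edges)
            assert (np.diff(counts) <= 0).all(), (field, counts)

    def test_working_covariate_equals_citest_residual_column(self, mixed_md):
        ds, md = mixed_md
        col = expand_conditioning_set([ds.censored_names[0]], ds)[:, 0]
        np.testing.assert_allclose(md.C[:, 0], col, atol=1e-10)

    def test_censored_node_needs_events(self, small_mixed):
        small_mixed.events[:] = 0
        with pytest.raises(ValueError, match="events"):
            fit_coxmgm(small_mixed, 0.1)


class TestParamsToGraph:
    def test_zero_params_edgeless(self, mixed_md):
        ds, md = mixed_md
        g = params_to_graph(MGMParams.zeros(md.p, md.level_slices, md.r), md)
        assert g.n_edges == 0
        assert len(g.nodes) == ds.p + ds.q + ds.r

    def test_single_beta_entry_single_edge(self, mixed_md):
        ds, md = mixed_md
        params = MGMParams.zeros(md.p, md.level_slices, md.r)
        params.beta[0, 1] = params.beta[1, 0] = 0.5
        g = params_to_graph(params, md)
        assert g.n_edges == 1
        assert g.has_edge(md.cont_names[0], md.cont_names[1])

    def test_tiny_block_below_tolerance_is_no_edge(self, mixed_md):
        ds, md = mixed_md
        params = MGMParams.zeros(md.p, md.level_slices, md.r)
        params.rho[0, md.level_slices[0]] = 1e-12
        assert params_to_graph(params, md, zero_tol=1e-8).n_edges == 0
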