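import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter
from scipy import stats

from coxmgm import cox
from coxmgm.citest import CITestConfig, ci_test, expand_conditioning_set, martingale_residuals
from coxmgm.citest import test_censored_vs_continuous as censored_vs_continuous
from coxmgm.citest import test_censored_vs_discrete as censored_vs_discrete
from coxmgm.citest import test_noncensored as noncensored_test
from coxmgm.datamodel import MixedDataset

from conftest import make_mixed


def _dataset_with_effects(n=400, seed=0):
    """U -> V and U -> T0 so that tests have signal to find."""
    rng = np.random.default_rng(seed)
    u = rng.normal(size=n)
    v = 0.8 * u + rng.normal(size=n)
    g = rng.integers(0, 3, size=n)
    T = rng.exponential(np.exp(-u))
    C = rng.exponential(2.0, size=n)
    return MixedDataset([str(i) for i in range(n)],
                        np.column_stack([u, v]), g.reshape(-1, 1),
                        np.minimum(T, C).reshape(-1, 1),
                        (T <= C).astype(np.int64).reshape(-1, 1),
                        ["U", "V"], ["G"], ["T0"], [("a", "b", "c")])


class TestExpandConditioningSet:
    def test_empty_set_keeps_rows(self, small_mixed):
        Z = expand_conditioning_set([], small_mixed)
        assert Z.shape == (small_mixed.n, 0)

    def test_continuous_passes_through(self, small_mixed):
        Z = expand_conditioning_set(["U"], small_mixed)
        np.testing.assert_array_equal(Z[:, 0], small_mixed.column("U"))

    def test_discrete_reference_encoded(self, small_mixed):
        Z = expand_conditioning_set(["G"], small_mixed)
        assert Z.shape == (small_mixed.n, 2)
        assert set(np.unique(Z)) <= {0.0, 1.0}

    def test_censored_becomes_martingale_residuals(self, small_mixed):
        Z = expand_conditioning_set(["T0"], small_mixed)
        t, e = small_mixed.column("T0")
        np.testing.assert_allclose(Z[:, 0], martingale_residuals(t, e))

    def test_no_sample_dropping_with_censored_member(self, small_mixed):
        # unlike complete-case conditioning, every row is retained
        Z = expand_conditioning_set(["U", "G", "T0"], small_mixed)
        assert Z.shape[0] == small_mixed.n


class TestDispatcher:
    @pytest.mark.parametrize("x,y,S", [
        ("U", "V", ()), ("U", "G", ()), ("G", "U", ("V",)),
        ("T0", "U", ()), ("T0", "G", ("U",)), ("U", "V", ("G", "T0")),
    ])
    def test_symmetry(self, x, y, S, small_mixed):
        r1 = ci_test(x, y, S, small_mixed)
        r2 = ci_test(y, x, S, small_mixed)
        assert r1.p_value == r2.p_value
        assert r1.family == r2.family

    def test_symmetry_both_censored(self):
        ds = make_mixed(r=2)
        r1 = ci_test("T0", "T1", (), ds)
        r2 = ci_test("T1", "T0", (), ds)
        assert r1.p_value == r2.p_value

    def test_p_value_in_unit_interval(self, small_mixed):
        for x, y in (("U", "V"), ("U", "G"), ("T0", "G")):
            assert 0.0 <= ci_test(x, y, (), small_mixed).p_value <= 1.0

    def test_routing_censored_continuous(self, small_mixed):
        direct = censored_vs_continuous("T0", "U", (), small_mixed,
                                             CITestConfig())
        routed = ci_test("U", "T0", (), small_mixed)
        assert routed.p_value == direct.p_value
        assert routed.family == "cox-wald"

    def test_conditioning_set_must_exclude_endpoints(self, small_mixed):
        with pytest.raises(ValueError):
            ci_test("U", "V", ("U",), small_mixed)


class TestAgainstReferenceImplementations:
    def test_cc_equals_partial_correlation_t_test(self, small_mixed):
        res = noncensored_test("U", "V", ("G",), small_mixed, CITestConfig())
        # classical partial-correlation t-test
        Z = expand_conditioning_set(["G"], small_mixed)
        Z1 = np.column_stack([np.ones(small_mixed.n), Z])
        rx = small_mixed.column("U") - Z1 @ np.linalg.lstsq(Z1, small_mixed.column("U"), rcond=None)[0]
        ry = small_mixed.column("V") - Z1 @ np.linalg.lstsq(Z1, small_mixed.column("V"), rcond=None)[0]
        r = np.corrcoef(rx, ry)[0, 1]
        df = small_mixed.n - 2 - Z.shape[1]
        t = r * np.sqrt(df / (1 - r**2))
        p = 2 * stats.t.sf(abs(t), df)
        assert res.p_value == pytest.approx(p, abs=1e-10)

    def test_censored_vs_continuous_matches_lifelines_wald(self):
        ds = _dataset_with_effects(seed=3)
        res = censored_vs_continuous("T0", "U", (), ds, CITestConfig())
        t, e = ds.column("T0")
        df = pd.DataFrame({"u": ds.column("U"), "t": t, "e": e})
        ref = CoxPHFitter().fit(df, "t", "e", fit_options={"precision": 1e-10})
        z_ref = (ref.params_["u"] / ref.standard_errors_["u"])
        assert res.statistic == pytest.approx(z_ref, abs=1e-4)
        # identical statistic referred to the same t reference gives the same p
        assert res.p_value == pytest.approx(
            2 * stats.t.sf(abs(z_ref), res.df), abs=1e-5)

    def test_censored_vs_discrete_matches_two_model_oracle(self):
        ds = _dataset_with_effects(seed=4)
        res = censored_vs_discrete("T0", "G", ("U",), ds, CITestConfig())
        t, e = ds.column("T0")
        from coxmgm.datamodel import encode_discrete
        Z = np.column_stack([encode_discrete(ds.column("G"), 3, reference=True),
                             ds.column("U")])
        full = cox.cox_newton(Z, t, e)
        null = cox.cox_newton(ds.column("U").reshape(-1, 1), t, e)
        assert res.statistic == pytest.approx(2 * (full.loglik - null.loglik), abs=1e-6)
        assert res.df == 2

    @staticmethod
    def _two_discrete(n=300, seed=5):
        rng = np.random.default_rng(seed)
        return MixedDataset([str(i) for i in range(n)], np.empty((n, 0)),
                            np.column_stack([rng.integers(0, 3, n),
                                             rng.integers(0, 3, n)]),
                            np.empty((n, 0)), np.empty((n, 0), dtype=np.int64),
                            [], ["G", "G2"], [], [("a", "b", "c")] * 2)

    def test_dd_matches_statsmodels_mnlogit(self):
        import statsmodels.api as sm
        ds = self._two_discrete()
        res = noncensored_test("G", "G2", (), ds, CITestConfig())
        from coxmgm.datamodel import encode_discrete
        y = ds.column("G")
        X0 = np.ones((ds.n, 1))
        X1 = np.column_stack([X0, encode_discrete(ds.column("G2"), 3, reference=True)])
        ll0 = sm.MNLogit(y, X0).fit(disp=0, method="newton").llf
        ll1 = sm.MNLogit(y, X1).fit(disp=0, method="newton").llf
        assert res.statistic == pytest.approx(2 * (ll1 - ll0), abs=1e-5)
        assert res.df == 4

    def test_lrt_statistics_clamped_nonnegative(self):
        for seed in range(10):
            ds = _dataset_with_effects(seed=seed, n=120)
            r1 = censored_vs_discrete("T0", "G", (), ds, CITestConfig())
            r2 = noncensored_test("V", "G", (), ds, CITestConfig())
            assert r1.statistic >= 0 and 0 <= r1.p_value <= 1
            assert r2.statistic >= 0 and 0 <= r2.p_value <= 1


class TestPowerAndConditioning:
    def test_chain_conditioning_removes_dependence(self):
        rng = np.random.default_rng(0)
        rej_cond = rej_marg = 0
        reps = 120
        for _ in range(reps):
            n = 500
            x = rng.normal(size=n)
            z = 0.9 * x + rng.normal(size=n)
            y = 0.9 * z + rng.normal(size=n)
            ds = MixedDataset([str(i) for i in range(n)],
                              np.column_stack([x, y, z]),
                              np.empty((n, 0), dtype=np.int64), np.empty((n, 0)),
                              np.empty((n, 0), dtype=np.int64),
                              ["X", "Y", "Z"], [], [], [])
            rej_cond += ci_test("X", "Y", ("Z",), ds).p_value < 0.05
            rej_marg += ci_test("X", "Y", (), ds).p_value < 0.05
        assert rej_marg / reps > 0.95
        assert rej_cond / reps < 0.12

    def test_censored_common_cause_residual_conditioning(self):
        # X <- Z -> Y with censored Z: conditioning on the Martingale
        # residual strips most of the marginal dependence
        rng = np.random.default_rng(1)
        rej_cond = rej_marg = 0
        reps = 80
        for _ in range(reps):
            n = 400
            T = rng.exponential(1.0, size=n)          # latent event time
            z = -np.log(T)
            x = 0.4 * z + rng.normal(size=n)
            y = 0.4 * z + rng.normal(size=n)
            C = rng.exponential(2.88, size=n)         # ~30% censoring
            ds = MixedDataset([str(i) for i in range(n)],
                              np.column_stack([x, y]),
                              np.empty((n, 0), dtype=np.int64),
                              np.minimum(T, C).reshape(-1, 1),
                              (T <= C).astype(np.int64).reshape(-1, 1),
                              ["X", "Y"], [], ["Z"], [])
            rej_cond += ci_test("X", "Y", ("Z",), ds).p_value < 0.05
            rej_marg += ci_test("X", "Y", (), ds).p_value < 0.05
        assert rej_marg / reps > 0.9
        assert rej_cond < rej_marg * 0.5

    def test_power_against_log_linear_hazard(self):
        rng = np.random.default_rng(2)
        rejections = 0
        for _ in range(40):
            n = 500
            u = rng.normal(size=n)
            T = rng.exponential(np.exp(-u))
            C = rng.exponential(2.0, size=n)
            ds = MixedDataset([str(i) for i in range(n)], u.reshape(-1, 1),
                              np.empty((n, 0), dtype=np.int64),
                              np.minimum(T, C).reshape(-1, 1),
                              (T <= C).astype(np.int64).reshape(-1, 1),
                              ["U"], [], ["T0"], [])
            rejections += ci_test("T0", "U", (), ds).p_value < 0.05
        assert rejections / 40 > 0.95
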