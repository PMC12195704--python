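"""MR estimators against independent oracles and their statistical invariants."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mrscreen import (
    DomainError,
    MRModel,
    SimulationConfig,
    cml_ma,
    cochran_q,
    directionality_test,
    egger,
    harmonize,
    ivw,
    simulate_pair,
    wald_ratio,
)

from conftest import make_pair


class TestWaldRatio:
    def test_arithmetic(self):
        est = wald_ratio(make_pair(beta_exp=0.1, se_exp=0.02, beta_out=0.05, se_out=0.01))
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.1)

    def test_null_outcome(self):
        est = wald_ratio(make_pair(beta_out=0.0))
        assert est.beta == 0.0 and est.pval == 1.0

    def test_allele_recoding_invariance(self):
        a = wald_ratio(make_pair(beta_exp=0.1, beta_out=0.05))
        b = wald_ratio(make_pair(beta_exp=-0.1, beta_out=-0.05))
        assert a.beta == pytest.approx(b.beta) and a.se == pytest.approx(b.se)

    def test_zero_exposure_rejected(self):
        with pytest.raises(DomainError):
            wald_ratio(make_pair(beta_exp=0.0))


def _wls_through_origin(bx, by, w):
    """Normal-equations oracle for weighted regression through the origin."""
    bx, by, w = map(np.asarray, (bx, by, w))
    beta = (w * bx * by).sum() / (w * bx * bx).sum()
    se = 1.0 / math.sqrt((w * bx * bx).sum())
    return beta, se


def _wls_with_intercept(bx, by, w):
    """Normal-equations oracle for the Egger regression."""
    X = np.column_stack([np.ones_like(bx), bx])
    W = np.diag(w)
    xtwx_inv = np.linalg.inv(X.T @ W @ X)
    coef = xtwx_inv @ X.T @ W @ np.asarray(by)
    resid = by - X @ coef
    dof = len(bx) - 2
    sigma2 = (w * resid**2).sum() / dof
    cov = xtwx_inv * sigma2
    return coef, np.sqrt(np.diag(cov))


class TestIVW:
    def test_homogeneous_ratios(self):
        pairs = [make_pair(vid="a", beta_exp=0.1, beta_out=0.05, se_out=0.01),
                 make_pair(vid="b", beta_exp=0.2, beta_out=0.10, se_out=0.02)]
        fixed = ivw(pairs, "fixed")
        rand = ivw(pairs, "multiplicative_random")
        assert fixed.beta == pytest.approx(0.5)
        assert fixed.q_stat == pytest.approx(0.0, abs=1e-12)
        assert rand.se == pytest.approx(fixed.se)

    def test_matches_normal_equations_oracle(self, five_pairs):
        est = ivw(five_pairs, "fixed")
        bx = np.array([p.beta_exp for p in five_pairs])
        by = np.array([p.beta_out for p in five_pairs])
        w = np.array([1 / p.se_out**2 for p in five_pairs])
        beta_o, se_o = _wls_through_origin(bx, by, w)
        assert est.beta == pytest.approx(beta_o, abs=1e-10)
        assert est.se == pytest.approx(se_o, abs=1e-10)

    def test_equals_precision_weighted_wald_ratios(self, five_pairs):
        """Algebraic identity: IVW is the weighted mean of per-variant ratios
        with weights beta_exp^2 / se_out^2."""
        est = ivw(five_pairs, "fixed")
        ratios = np.array([p.beta_out / p.beta_exp for p in five_pairs])
        w = np.array([p.beta_exp**2 / p.se_out**2 for p in five_pairs])
        assert est.beta == pytest.approx((w * ratios).sum() / w.sum(), abs=1e-10)

    def test_single_pair_delegates_to_wald(self):
        pair = make_pair(beta_exp=0.1, beta_out=0.03)
        est = ivw([pair])
        assert est.method == "wald"
        assert est.beta == pytest.approx(wald_ratio(pair).beta)
        assert "single instrument" in est.notes

    def test_random_effects_never_deflates(self, five_pairs):
        assert ivw(five_pairs, "multiplicative_random").se >= ivw(five_pairs, "fixed").se

    def test_allele_recoding_invariance(self, five_pairs):
        flipped = [make_pair(vid=p.variant_id, beta_exp=-p.beta_exp, se_exp=p.se_exp,
                             beta_out=-p.beta_out, se_out=p.se_out)
                   for p in five_pairs[:2]] + list(five_pairs[2:])
        assert ivw(flipped, "fixed").beta == pytest.approx(
            ivw(five_pairs, "fixed").beta, abs=1e-12)


class TestCochranQ:
    def test_homogeneous_is_zero(self):
        pairs = [make_pair(vid="a", beta_exp=0.1, beta_out=0.05),
                 make_pair(vid="b", beta_exp=0.2, beta_out=0.10)]
        q, df, p = cochran_q(pairs, 0.5)
        assert q == pytest.approx(0.0, abs=1e-12) and df == 1 and p == pytest.approx(1.0)

    def test_hand_computed_sum(self):
        pairs = [make_pair(vid="a", beta_exp=0.1, beta_out=0.03, se_out=0.01),
                 make_pair(vid="b", beta_exp=0.2, beta_out=0.05, se_out=0.02),
                 make_pair(vid="c", beta_exp=0.15, beta_out=0.02, se_out=0.015)]
        theta = 0.2
        expected = ((0.03 - 0.02) / 0.01) ** 2 + ((0.05 - 0.04) / 0.02) ** 2 + (
            (0.02 - 0.03) / 0.015) ** 2
        q, df, _ = cochran_q(pairs, theta)
        assert q == pytest.approx(expected, abs=1e-10) and df == 2

    def test_duplicating_a_pair_never_decreases_q(self, five_pairs):
        q1, *_ = cochran_q(five_pairs, 0.3)
        q2, *_ = cochran_q(list(five_pairs) + [five_pairs[2]], 0.3)
        assert q2 >= q1

    def test_sparse_not_applicable(self):
        assert cochran_q([make_pair()], 0.5) is None


class TestEgger:
    def test_matches_normal_equations_oracle(self, five_pairs):
        est = egger(five_pairs)
        bx = np.array([p.beta_exp for p in five_pairs])
        by = np.array([p.beta_out for p in five_pairs])
        w = np.array([1 / p.se_out**2 for p in five_pairs])
        coef, se = _wls_with_intercept(bx, by, w)
        assert est.egger_intercept == pytest.approx(coef[0], abs=1e-10)
        assert est.beta == pytest.approx(coef[1], abs=1e-10)
        assert est.se == pytest.approx(se[1], abs=1e-10)
        assert est.egger_intercept_se == pytest.approx(se[0], abs=1e-10)

    def test_recovers_constant_pleiotropy(self):
        """With alpha added to every outcome effect, the intercept estimates alpha."""
        rng = np.random.default_rng(4)
        theta, alpha = 0.2, 0.04
        pairs = []
        for j in range(10):
            bx = 0.08 + 0.02 * j
            sy = 0.004
            by = theta * bx + alpha + rng.normal(0, sy)
            pairs.append(make_pair(vid=f"rs{j}", beta_exp=bx, se_exp=1e-4,
                                   beta_out=by, se_out=sy))
        est = egger(pairs)
        assert est.egger_intercept == pytest.approx(alpha, abs=0.01)
        assert est.beta == pytest.approx(theta, abs=0.1)

    def test_zero_pleiotropy_null_intercept(self):
        exp, out, _ = simulate_pair(SimulationConfig(
            n_variants=50, theta=0.2, n_exposure=10**7, n_outcome=10**7, seed=8))
        pairs, _ = harmonize(exp, out)
        est = egger(pairs)
        assert abs(est.egger_intercept) < 3 * est.egger_intercept_se + 1e-4

    def test_sparse_gated(self):
        with pytest.raises(DomainError):
            egger([make_pair(vid="a"), make_pair(vid="b")])


def _cml_exhaustive(pairs, k):
    """Oracle: enumerate every invalid subset of size k; keep the likelihood winner."""
    bx = np.array([p.beta_exp for p in pairs])
    by = np.array([p.beta_out for p in pairs])
    w = np.array([1 / p.se_out**2 for p in pairs])
    best = None
    for subset in itertools.combinations(range(len(pairs)), k):
        valid = np.ones(len(pairs), dtype=bool)
        valid[list(subset)] = False
        theta = (w[valid] * bx[valid] * by[valid]).sum() / (w[valid] * bx[valid] ** 2).sum()
        nll = 0.5 * (w[valid] * (by[valid] - theta * bx[valid]) ** 2).sum()
        if best is None or nll < best[1]:
            best = (theta, nll, subset)
    return best


class TestCMLMA:
    def test_homogeneous_ratios_put_weight_on_k0(self):
        pairs = [make_pair(vid=f"rs{j}", beta_exp=0.1 * (j + 1),
                           beta_out=0.05 * (j + 1), se_out=0.01)
                 for j in range(5)]
        result, est = cml_ma(pairs, n_bic=20_000)
        assert all(t == pytest.approx(0.5, abs=1e-9) for t in result.theta_k)
        assert est.beta == pytest.approx(0.5, abs=1e-9)
        assert int(np.argmax(result.weights)) == 0

    def test_per_k_matches_exhaustive_enumeration(self, five_pairs):
        """The iterative profile solution attains the global optimum at K=5."""
        result, _ = cml_ma(five_pairs, n_bic=20_000)
        for idx, k in enumerate(result.k_values):
            theta_o, nll_o, subset_o = _cml_exhaustive(five_pairs, k)
            assert result.theta_k[idx] == pytest.approx(theta_o, abs=1e-8)
            assert result.negloglik_k[idx] == pytest.approx(nll_o, abs=1e-8)
            assert set(result.invalid_sets[idx]) == {
                five_pairs[i].variant_id for i in subset_o}

    def test_k0_equals_ivw_ml(self, five_pairs):
        result, _ = cml_ma(five_pairs, n_bic=20_000)
        assert result.theta_k[0] == pytest.approx(ivw(five_pairs, "fixed").beta, abs=1e-8)

    def test_weights_sum_to_one_and_sets_sized(self, five_pairs):
        result, _ = cml_ma(five_pairs, n_bic=20_000)
        assert result.weights.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(result.weights >= 0)
        for k, s in zip(result.k_values, result.invalid_sets):
            assert len(s) == k

    def test_less_biased_than_ivw_under_directional_pleiotropy(self):
        """The model-averaged estimate sheds most of the pleiotropy bias that
        IVW absorbs — the reason this estimator exists."""
        theta = 0.2
        ivw_est, cml_est = [], []
        for r in range(60):
            cfg = SimulationConfig(n_variants=30, theta=theta, prop_invalid=0.3,
                                   n_exposure=50_000, n_outcome=50_000,
                                   seed=60_000 + r)
            exp, out, _ = simulate_pair(cfg)
            pairs, _ = harmonize(exp, out)
            ivw_est.append(ivw(pairs, "fixed").beta)
            cml_est.append(cml_ma(pairs)[1].beta)
        assert abs(np.mean(cml_est) - theta) < abs(np.mean(ivw_est) - theta)


class TestDirectionality:
    def test_dominant_exposure_signal(self):
        pairs = [make_pair(beta_exp=0.3, beta_out=0.02, eaf_exp=0.3, eaf_out=0.3)]
        res = directionality_test(pairs, 30_000, 20_000)
        assert res.direction_ok and res.steiger_p < 0.05

    def test_symmetric_case_is_inconclusive(self):
        pairs = [make_pair(beta_exp=0.1, beta_out=0.1, se_out=0.01,
                           eaf_exp=0.3, eaf_out=0.3)]
        res = directionality_test(pairs, 20_000, 20_000)
        assert res.r2_exposure == pytest.approx(res.r2_outcome)
        assert not res.direction_ok
        assert res.steiger_p == 1.0

    def test_simulated_forward_chain_detected(self):
        ok = 0
        for r in range(100):
            cfg = SimulationConfig(n_variants=20, theta=0.2, seed=70_000 + r)
            exp, out, _ = simulate_pair(cfg)
            pairs, _ = harmonize(exp, out)
            ok += directionality_test(pairs).direction_ok
        assert ok >= 99

    def test_r2_bounded(self, five_pairs):
        res = directionality_test(five_pairs, 30_000, 20_000)
        assert 0 <= res.r2_outcome <= res.r2_exposure <= 1


class TestModelObjects:
    def test_fit_auto_matches_functions(self, five_pairs):
        model = MRModel(five_pairs)
        assert model.fit("auto").beta == pytest.approx(
            ivw(five_pairs, "multiplicative_random").beta)
        assert model.fit("ivw_fixed").beta == pytest.approx(
            ivw(five_pairs, "fixed").beta)

    def test_summary_mentions_method_and_or(self, five_pairs):
        text = MRModel(five_pairs).fit("ivw_random").summary()
        assert "ivw_random" in text and "OR" in text and "Cochran Q" in text

    def test_fit_all_battery(self, five_pairs):
        methods = [r.method for r in MRModel(five_pairs).fit_all(n_bic=20_000)]
        assert methods == ["ivw_fixed", "ivw_random", "egger_slope", "cml_ma"]

    def test_from_dataframe(self):
        import pandas as pd

        df = pd.DataFrame({
            "beta_exp": [0.1, 0.2], "se_exp": [0.01, 0.01],
            "beta_out": [0.05, 0.1], "se_out": [0.01, 0.02],
        })
        model = MRModel.from_dataframe(df)
        assert model.fit("ivw_fixed").beta == pytest.approx(0.5)

    @given(st.integers(0, 10_000))
    @settings(max_examples=20, derandomize=True, deadline=None)
    def test_or_ci_consistent_with_beta_se(self, seed):
        cfg = SimulationConfig(n_variants=10, seed=seed)
        exp, out, _ = simulate_pair(cfg)
        pairs, _ = harmonize(exp, out)
        est = ivw(pairs, "fixed")
        assert est.or_ci.or_value == pytest.approx(math.exp(est.beta), rel=1e-12)
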