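"""BMA core: subset fits, search exactness, priors, Occam's window."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import ibmanet as ib
from ibmanet.bma import (
    RSS_FLOOR,
    CandidateModel,
    ModelSet,
    apply_model_priors,
    exhaustive_search,
    gaussian_bic,
)
from conftest import make_problem
from oracles import exhaustive_best_subsets


class TestFitSubset:
    def test_intercept_only_model(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        prob = ib.RegressionProblem(y, np.arange(8.0).reshape(4, 2) ** 2, ["a", "b"])
        model = ib.fit_subset(prob, ())
        assert model.rss == pytest.approx(5.0)
        assert model.bic == pytest.approx(4 * math.log(5 / 4) + math.log(4))
        assert model.intercept == pytest.approx(2.5)

    def test_perfect_fit_hits_rss_floor(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((10, 2))
        prob = ib.RegressionProblem(x[:, 0].copy(), x, ["a", "b"])
        model = ib.fit_subset(prob, (0,))
        assert model.rss == RSS_FLOOR
        assert math.isfinite(model.bic)

    def test_coefficients_match_normal_equations(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((20, 3))
        y = rng.standard_normal(20)
        prob = ib.RegressionProblem(y, x, ["a", "b", "c"])
        model = ib.fit_subset(prob, (0, 1, 2))
        design = np.column_stack([np.ones(20), x])
        beta = np.linalg.solve(design.T @ design, design.T @ y)
        assert model.intercept == pytest.approx(beta[0])
        for j in range(3):
            assert model.coefficients[j] == pytest.approx(beta[j + 1])

    def test_collinear_subset_flagged_invalid(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((15, 3))
        x[:, 2] = x[:, 0] + x[:, 1]
        prob = ib.RegressionProblem(rng.standard_normal(15), x, ["a", "b", "c"])
        assert not ib.fit_subset(prob, (0, 1, 2)).valid
        assert ib.fit_subset(prob, (0, 1)).valid

    def test_oversized_subset_rejected(self):
        prob = make_problem(0, n=5, q=4)
        with pytest.raises(ValueError):
            ib.fit_subset(prob, (0, 1, 2, 3))

    def test_constant_column_rejected_at_construction(self):
        x = np.ones((10, 2))
        x[:, 0] = np.arange(10)
        with pytest.raises(ValueError, match="constant"):
            ib.RegressionProblem(np.arange(10.0), x, ["a", "b"])


class TestBestSubsetSearch:
    def test_single_candidate_gives_two_models(self):
        prob = make_problem(0, q=1)
        models = ib.best_subset_search(prob, nbest=10)
        assert sorted(m.members for m in models) == [(), (0,)]

    def test_min_rss_monotone_in_size(self):
        prob = make_problem(5, n=30, q=8, signal=(1, 4))
        models = ib.best_subset_search(prob, nbest=5, max_size=6)
        best = {}
        for m in models:
            best[m.size] = min(best.get(m.size, math.inf), m.rss)
        for size in range(1, 7):
            assert best[size] <= best[size - 1] + 1e-12

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_enumeration(self, seed):
        prob = make_problem(seed, n=40, q=10, signal=(2, 7))
        models = ib.best_subset_search(prob, nbest=10, max_size=5)
        expected = exhaustive_best_subsets(
            prob.response, prob.predictors, nbest=10, max_size=5
        )
        got = {}
        for m in models:
            got.setdefault(m.size, []).append((m.rss, m.members))
        for size, fits in enumerate(expected):
            ours = sorted(got.get(size, []))
            assert [m for _, m in ours] == [m for _, m in fits]
            np.testing.assert_allclose(
                [r for r, _ in ours], [r for r, _ in fits], rtol=1e-8
            )

    def test_agrees_with_internal_exhaustive_fallback(self):
        prob = make_problem(11, n=35, q=9, signal=(0,))
        fast = ib.best_subset_search(prob, nbest=4, max_size=4)
        slow = exhaustive_search(prob, nbest=4, max_size=4)
        assert [m.members for m in fast] == [m.members for m in slow]

    def test_duplicated_column_never_coselected(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((30, 5))
        x[:, 4] = x[:, 1]
        y = x[:, 1] + 0.3 * rng.standard_normal(30)
        prob = ib.RegressionProblem(y, x, list("abcde"))
        models = ib.best_subset_search(prob, nbest=10, max_size=4)
        assert all(not {1, 4} <= set(m.members) for m in models)


class TestModelPrior:
    def test_uniform_prior_is_equal_across_models(self):
        pi = np.full(5, 0.5)
        lp1 = ib.model_log_prior((0, 2), pi)
        lp2 = ib.model_log_prior((1, 3, 4), pi)
        assert lp1 == pytest.approx(lp2)

    def test_two_candidate_product_form(self):
        pi = np.array([0.1, 0.2])
        expected = {(): 0.72, (0,): 0.08, (1,): 0.18, (0, 1): 0.02}
        total = 0.0
        for members, target in expected.items():
            prior = math.exp(ib.model_log_prior(members, pi))
            assert prior == pytest.approx(target, rel=1e-9)
            total += prior
        assert total == pytest.approx(1.0)

    def test_near_one_prior_forces_inclusion(self):
        pi = np.array([1.0, 0.5])
        gap = ib.model_log_prior((0,), pi) - ib.model_log_prior((), pi)
        assert gap == pytest.approx(math.log(1 - 1e-10) - math.log(1e-10), rel=1e-6)


def _model(members, bic, log_prior=0.0):
    return CandidateModel(members=members, rss=1.0, bic=bic, log_prior=log_prior)


class TestPosteriorAndWindow:
    def test_single_model_posterior_is_one(self):
        ms = ib.posterior_model_probs(ModelSet(models=[_model((0,), 3.0)]))
        assert ms.models[0].posterior_prob == pytest.approx(1.0)

    def test_equal_bics_follow_priors(self):
        ms = ModelSet(
            models=[_model((0,), 5.0, math.log(0.3)), _model((1,), 5.0, math.log(0.6))]
        )
        ms = ib.posterior_model_probs(ms)
        probs = [m.posterior_prob for m in ms]
        assert probs[0] == pytest.approx(1 / 3)
        assert probs[1] == pytest.approx(2 / 3)

    def test_bic_gap_closed_form(self):
        ms = ib.posterior_model_probs(
            ModelSet(models=[_model((0,), 10.0), _model((1,), 12.0)])
        )
        expected = 1 / (1 + math.exp(-1.0))
        assert ms.models[0].posterior_prob == pytest.approx(expected)

    def test_empty_model_set_is_an_error(self):
        with pytest.raises(ValueError):
            ib.posterior_model_probs(ModelSet(models=[]))

    def test_occams_window_drops_and_renormalizes(self):
        models = [_model((0,), 0.0), _model((1,), 0.0), _model((2,), 0.0)]
        for m, p in zip(models, (0.5, 0.3, 0.02)):
            m.posterior_prob = p
        out = ib.occams_window(ModelSet(models=models, normalized=True), 20.0)
        assert [m.members for m in out] == [(0,), (1,)]
        assert [m.posterior_prob for m in out] == pytest.approx([0.625, 0.375])

    def test_occams_window_huge_or_keeps_all(self):
        models = [_model((0,), 0.0), _model((1,), 0.0)]
        models[0].posterior_prob, models[1].posterior_prob = 0.999, 0.001
        out = ib.occams_window(ModelSet(models=models, normalized=True), 1e9)
        assert len(out) == 2

    @given(st.lists(st.floats(0.01, 100.0), min_size=1, max_size=12))
    def test_normalization_and_cutoff_invariants(self, weights):
        models = []
        for j, w in enumerate(weights):
            m = _model((j,), bic=-2 * math.log(w))
            models.append(m)
        ms = ib.posterior_model_probs(ModelSet(models=models))
        assert sum(m.posterior_prob for m in ms) == pytest.approx(1.0, abs=1e-9)
        out = ib.occams_window(ms, 20.0)
        assert sum(m.posterior_prob for m in out) == pytest.approx(1.0, abs=1e-9)
        # every raw survivor weight is within a factor OR of the best
        raw = np.array(weights)
        best = raw.max()
        kept = raw[raw >= best / 20.0]
        assert len(out) == len(kept)


class TestInclusion:
    def test_direct_sum(self):
        a, b = _model((0,), 0.0), _model((1,), 0.0)
        a.posterior_prob, b.posterior_prob = 0.6, 0.4
        a.coefficients, b.coefficients = {0: 2.0}, {1: -1.0}
        a.intercept = b.intercept = 0.0
        s = ib.inclusion_probabilities(
            ModelSet(models=[a, b], normalized=True), ["A", "B"]
        )
        assert s.inclusion == pytest.approx([0.6, 0.4])
        assert s.coefficients == pytest.approx([1.2, -0.4])

    def test_always_and_never_present(self):
        a, b = _model((0,), 0.0), _model((0, 1), 0.0)
        a.posterior_prob, b.posterior_prob = 0.7, 0.3
        a.intercept = b.intercept = 0.0
        s = ib.inclusion_probabilities(
            ModelSet(models=[a, b], normalized=True), ["A", "B", "C"]
        )
        assert s.inclusion[0] == pytest.approx(1.0)
        assert s.inclusion[2] == 0.0


class TestPriorEffects:
    def test_uniform_prior_preserves_bic_ranking(self):
        prob = make_problem(7, n=40, q=8, signal=(3,))
        models = ib.best_subset_search(prob, nbest=8, max_size=4)
        apply_model_priors(models, np.full(8, 0.5))
        ms = ib.posterior_model_probs(models)
        by_posterior = sorted(ms, key=lambda m: -m.posterior_prob)
        by_bic = sorted(ms, key=lambda m: m.bic)
        assert [m.members for m in by_posterior] == [m.members for m in by_bic]

    @pytest.mark.parametrize("seed", range(5))
    def test_raising_a_prior_never_lowers_inclusion(self, seed):
        rng = np.random.default_rng(seed)
        prob = make_problem(seed + 50, n=30, q=6, signal=(0,))
        pi_lo = rng.uniform(0.05, 0.6, size=6)
        target = int(rng.integers(6))
        pi_hi = pi_lo.copy()
        pi_hi[target] = min(0.99, pi_lo[target] + rng.uniform(0.1, 0.4))

        def incl(pi):
            models = ib.best_subset_search(prob, nbest=64, max_size=6)
            apply_model_priors(models, pi)
            ms = ib.posterior_model_probs(models)
            return ib.inclusion_probabilities(ms, prob.candidate_ids).inclusion

        assert incl(pi_hi)[target] >= incl(pi_lo)[target] - 1e-12


def test_gaussian_bic_floors_rss():
    assert math.isfinite(gaussian_bic(0.0, 10, 2))
    assert gaussian_bic(0.0, 10, 2) == gaussian_bic(1e-15, 10, 2)
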