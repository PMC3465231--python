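"""Supervised prior construction: calibration, imputation, logistic BMA."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import ibmanet as ib
from ibmanet.priors import BiasAdjustment, TrainingSet


class TestSamplingRates:
    def test_yeast_scale_calibration(self):
        adj = ib.compute_sampling_rates(583, 444, 6000, 2.76)
        assert adj.pi1 * 100 == pytest.approx(3.52, abs=0.005)
        assert adj.pi0 * 100 == pytest.approx(0.0012, abs=0.0001)
        assert adj.odds_ratio == pytest.approx(2853, abs=1)
        assert adj.tau == pytest.approx(0.00046, abs=1e-6)
        assert adj.offset == pytest.approx(-math.log(adj.odds_ratio))

    def test_hand_arithmetic_small_case(self):
        adj = ib.compute_sampling_rates(100, 100, 1000, 2)
        assert adj.pi1 == pytest.approx(0.05)
        assert adj.pi0 == pytest.approx(100 / (1000 * 998))
        assert adj.odds_ratio == pytest.approx(0.05 * 1000 * 998 / 100)

    def test_proportional_sampling_is_neutral(self):
        # sampling positives and negatives at the same 1% rate
        adj = ib.compute_sampling_rates(20, 9980, 1000, 2)
        assert adj.odds_ratio == pytest.approx(1.0)
        assert adj.offset == pytest.approx(0.0)

    def test_dense_network_rejected(self):
        with pytest.raises(ValueError):
            ib.compute_sampling_rates(10, 10, 100, 150)


class TestAdjustProbability:
    def test_neutral_ratio_is_identity(self):
        adj = BiasAdjustment.neutral()
        assert ib.adjust_probability(0.37, adj) == pytest.approx(0.37)

    def test_hand_arithmetic(self):
        adj = BiasAdjustment(pi1=0.2, pi0=0.1)  # ratio 2
        assert ib.adjust_probability(0.5, adj) == pytest.approx(1 / 3)

    def test_boundary_values_are_clipped(self):
        adj = BiasAdjustment(pi1=0.2, pi0=0.1)
        assert 0.0 < ib.adjust_probability(1.0, adj) < 1.0

    @given(
        st.floats(0.01, 0.99),
        st.floats(0.02, 0.98),
        st.floats(1.1, 100.0),
    )
    def test_monotone_in_raw_and_ratio(self, p1, p2, ratio):
        adj = BiasAdjustment(pi1=min(ratio * 0.001, 1.0), pi0=0.001)
        lo, hi = sorted((p1, p2))
        assert ib.adjust_probability(hi, adj) >= ib.adjust_probability(lo, adj)
        stronger = BiasAdjustment(pi1=min(2 * ratio * 0.001, 1.0), pi0=0.001)
        if stronger.odds_ratio > adj.odds_ratio:
            assert ib.adjust_probability(p1, stronger) < ib.adjust_probability(p1, adj)


def toy_training(n_missing=3, seed=0):
    rng = np.random.default_rng(seed)
    n = 20
    labels = np.array([1] * 10 + [0] * 10)
    chip = rng.uniform(0, 5, n)
    chip[:n_missing] = np.nan
    df = pd.DataFrame(
        {
            "regulator_id": [f"r{i}" for i in range(n)],
            "gene_id": [f"g{i}" for i in range(n)],
            "label": labels,
            "chip": chip,
            "score": rng.standard_normal(n),
        }
    )
    return TrainingSet(examples=df, feature_names=["chip", "score"])


class TestImputation:
    def test_complete_data_passes_through(self):
        train = toy_training(n_missing=0)
        copies = ib.impute_missing_chip(train, n_imputations=4, seed=1)
        assert len(copies) == 4
        for c in copies:
            pd.testing.assert_frame_equal(c.examples, train.examples)

    def test_imputed_values_come_from_same_label_class(self):
        train = toy_training(n_missing=6, seed=2)
        observed = {
            lab: set(
                train.examples.loc[
                    (train.examples["label"] == lab)
                    & train.examples["chip"].notna(),
                    "chip",
                ]
            )
            for lab in (0, 1)
        }
        for copy in ib.impute_missing_chip(train, n_imputations=5, seed=3):
            assert not copy.examples["chip"].isna().any()
            filled = copy.examples.loc[train.examples["chip"].isna()]
            for _, row in filled.iterrows():
                assert row["chip"] in observed[row["label"]]

    def test_label_class_without_observations_is_an_error(self):
        train = toy_training(n_missing=0)
        df = train.examples.copy()
        df.loc[df["label"] == 1, "chip"] = np.nan
        broken = train.copy_with(df)
        with pytest.raises(ValueError, match="label class"):
            ib.impute_missing_chip(broken, n_imputations=2, seed=0)

    def test_seed_reproducibility(self):
        train = toy_training(n_missing=5, seed=4)
        a = ib.impute_missing_chip(train, n_imputations=3, seed=7)
        b = ib.impute_missing_chip(train, n_imputations=3, seed=7)
        for ca, cb in zip(a, b):
            pd.testing.assert_frame_equal(ca.examples, cb.examples)


class TestTruncation:
    def test_rules(self):
        train = toy_training(n_missing=0, seed=5)
        hi = train.examples["score"].max()
        lo = train.examples["score"].min()
        table = pd.DataFrame(
            {
                "regulator_id": ["a", "b", "c", "d"],
                "gene_id": ["w", "x", "y", "z"],
                "chip": [1.0, 2.0, 3.0, 4.0],
                "score": [0.0, hi, hi + 7.3, lo - 2.0],
            }
        )
        out = ib.truncate_extremes(table, train)
        assert out.loc[0, "score"] == 0.0  # within range: unchanged
        assert out.loc[1, "score"] == hi  # boundary: unchanged
        assert out.loc[2, "score"] == hi  # above: clamped to training max
        assert out.loc[3, "score"] == lo  # below: clamped to training min

    def test_lower_tail_optional(self):
        train = toy_training(n_missing=0, seed=5)
        lo = train.examples["score"].min()
        table = pd.DataFrame(
            {
                "regulator_id": ["a"],
                "gene_id": ["w"],
                "chip": [1.0],
                "score": [lo - 2.0],
            }
        )
        out = ib.truncate_extremes(table, train, lower=False)
        assert out.loc[0, "score"] == lo - 2.0

    def test_idempotent(self):
        train = toy_training(n_missing=0, seed=6)
        rng = np.random.default_rng(0)
        table = pd.DataFrame(
            {
                "regulator_id": [f"r{i}" for i in range(30)],
                "gene_id": [f"g{i}" for i in range(30)],
                "chip": rng.uniform(-10, 10, 30),
                "score": rng.uniform(-10, 10, 30),
            }
        )
        once = ib.truncate_extremes(table, train)
        twice = ib.truncate_extremes(once, train)
        pd.testing.assert_frame_equal(once, twice)


def single_feature_training(n=200, informative=True, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    if informative:
        prob = 1 / (1 + np.exp(-(0.5 + 3.0 * x)))
        labels = (rng.random(n) < prob).astype(int)
    else:
        labels = rng.integers(0, 2, n)
    df = pd.DataFrame(
        {
            "regulator_id": [f"r{i}" for i in range(n)],
            "gene_id": [f"g{i}" for i in range(n)],
            "label": labels,
            "chip": x,
        }
    )
    return TrainingSet(examples=df, feature_names=["chip"])


class TestLogisticBma:
    def test_separable_feature_has_inclusion_near_one(self):
        rng = np.random.default_rng(1)
        n = 100
        x = np.concatenate([rng.uniform(1, 2, 50), rng.uniform(-2, -1, 50)])
        df = pd.DataFrame(
            {
                "regulator_id": [f"r{i}" for i in range(n)],
                "gene_id": [f"g{i}" for i in range(n)],
                "label": [1] * 50 + [0] * 50,
                "chip": x,
            }
        )
        train = TrainingSet(examples=df, feature_names=["chip"])
        model = ib.fit_regulatory_model([train], BiasAdjustment.neutral())
        assert model.inclusion["chip"] > 0.95

    def test_pure_noise_feature_has_low_inclusion(self):
        train = single_feature_training(n=400, informative=False, seed=3)
        model = ib.fit_regulatory_model([train], BiasAdjustment.neutral())
        assert model.inclusion["chip"] < 0.5

    def test_single_feature_matches_plain_logistic_fit(self):
        """With no offset, one imputation and one dominant feature, BMA
        collapses to the ordinary maximum-likelihood logistic fit."""
        sm = pytest.importorskip("statsmodels.api")
        train = single_feature_training(n=300, informative=True, seed=4)
        model = ib.fit_regulatory_model([train], BiasAdjustment.neutral())
        table = pd.DataFrame(
            {
                "regulator_id": [f"R{i}" for i in range(7)],
                "gene_id": [f"G{i}" for i in range(7)],
                "chip": np.linspace(-1.5, 1.5, 7),
            }
        )
        matrix = ib.predict_regulatory_potential(model, table, seed=0)
        y = train.examples["label"].to_numpy()
        design = sm.add_constant(train.examples["chip"].to_numpy())
        oracle_fit = sm.Logit(y, design).fit(disp=0)
        expected = oracle_fit.predict(sm.add_constant(table["chip"].to_numpy()))
        got = [
            float(matrix.pi.loc[g, r])
            for r, g in zip(table["regulator_id"], table["gene_id"])
        ]
        np.testing.assert_allclose(got, expected, atol=1e-4)


@pytest.fixture(scope="module")
def small_benchmark():
    cfg = ib.SimulationConfig(
        n_genes=80, n_samples=20, n_timepoints=4,
        n_pos=150, n_neg=120, seed=5,
    )
    truth = ib.sample_true_network(cfg)
    train, table = ib.generate_external_evidence(truth, cfg)
    adj = ib.compute_sampling_rates(
        cfg.n_pos, cfg.n_neg, cfg.n_genes,
        ib.mean_in_degree(cfg.in_degree_decay),
    )
    imputed = ib.impute_missing_chip(train, 5, seed=6)
    table = ib.truncate_extremes(table, train)
    model = ib.fit_regulatory_model(imputed, adj)
    matrix = ib.predict_regulatory_potential(model, table, seed=7)
    return truth, model, matrix


class TestPrediction:

    def test_expected_regulators_per_gene_is_order_one(self, small_benchmark):
        _, _, matrix = small_benchmark
        mean_expected = matrix.expected_regulators.mean()
        assert 0.2 < mean_expected < 20.0

    def test_true_edges_receive_higher_priors(self, small_benchmark):
        truth, _, matrix = small_benchmark
        long = matrix.to_long().set_index(["regulator_id", "gene_id"])["pi"]
        on_edges = [long.loc[(r, g)] for r, g in truth.edges]
        assert np.mean(on_edges) > 5 * float(matrix.pi.stack().mean())

    def test_prediction_output_is_complete_despite_missing_chip(self, small_benchmark):
        # every scored (non-self) pair gets a probability; only the
        # self-pair diagonal, which is never scored, stays empty
        _, _, matrix = small_benchmark
        pi = matrix.pi.copy()
        np.fill_diagonal(pi.values, 0.0)
        assert pi.notna().all().all()

    def test_monotone_in_positive_evidence(self, small_benchmark):
        _, model, _ = small_benchmark
        base = pd.DataFrame(
            {
                "regulator_id": ["ra", "rb"],
                "gene_id": ["ga", "gb"],
                "coexpression": [0.0, 2.0],
                "chip": [1.0, 1.0],
                "curated": [0.0, 0.0],
                "polymorphism": [0.0, 0.0],
                "go_overlap": [0.0, 0.0],
            }
        )
        out = ib.predict_regulatory_potential(model, base, seed=8)
        lo = float(out.pi.loc["ga", "ra"])
        hi = float(out.pi.loc["gb", "rb"])
        if model.coefficients["coexpression"] > 0:
            assert hi >= lo
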