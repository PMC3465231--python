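"""Shared fixtures: seeded regression instances and the recovery benchmark."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ibmanet as ib
from ibmanet.assess import all_pairs_universe, contingency_assess
from ibmanet.ibma import IbmaConfig

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_problem(seed, n=40, q=10, signal=(), coef=1.5, noise=1.0):
    """Random Gaussian regression instance with optional true signal."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, q))
    beta = np.zeros(q)
    for j in signal:
        beta[j] = coef * (1 if rng.random() < 0.5 else -1)
    y = x @ beta + noise * rng.standard_normal(n)
    return ib.RegressionProblem(y, x, [f"c{j}" for j in range(q)])


# ---------------------------------------------------------------------------
# Recovery benchmark: the simulation study conditions (300 genes, 97 samples,
# six time points) with the supervised prior stage run per seed, models
# capped at five regulators, and the TPR of each engine variant against the
# generating network at the 50% edge threshold.
# ---------------------------------------------------------------------------

BENCHMARK_SEEDS = (0, 1, 2, 3, 4)
BENCHMARK_VARIANTS = ("prior", "shortlist", "noprior")


def run_recovery_benchmark(
    seeds=BENCHMARK_SEEDS,
    variants=BENCHMARK_VARIANTS,
    n_genes=300,
    n_samples=97,
    n_timepoints=6,
    max_size=5,
):
    tprs = {v: [] for v in variants}
    for seed in seeds:
        cfg = ib.SimulationConfig(
            n_genes=n_genes,
            n_samples=n_samples,
            n_timepoints=n_timepoints,
            seed=seed,
        )
        truth = ib.sample_true_network(cfg)
        observed, _ = ib.generate_timeseries(truth, cfg)
        train, table = ib.generate_external_evidence(truth, cfg)
        adj = ib.compute_sampling_rates(
            cfg.n_pos, cfg.n_neg, cfg.n_genes, ib.mean_in_degree(cfg.in_degree_decay)
        )
        imputed = ib.impute_missing_chip(train, 20, seed=seed * 7 + 1)
        table = ib.truncate_extremes(table, train)
        model = ib.fit_regulatory_model(imputed, adj)
        prior_matrix = ib.predict_regulatory_potential(model, table, seed=seed * 7 + 2)
        universe = all_pairs_universe(observed.gene_ids, include_self=True)
        for variant in variants:
            icfg = IbmaConfig(
                variant=variant,
                max_size=max_size,
                tau=ib.mean_in_degree(cfg.in_degree_decay) / n_genes,
                seed=seed,
            )
            net = ib.build_network(
                observed,
                prior_matrix if variant in ("prior", "shortlist") else None,
                icfg,
            )
            result = contingency_assess(net, truth.edges, universe)
            tprs[variant].append(result.tpr)
    return tprs


@pytest.fixture(scope="session")
def recovery_benchmark():
    """TPR-vs-truth per variant over the five benchmark seeds (heavy)."""
    return run_recovery_benchmark()
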