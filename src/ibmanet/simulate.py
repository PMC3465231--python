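"""Synthetic benchmark generator for lag-linear regulatory networks.

Emulates the study design of a rapamycin-perturbation time course in a
panel of genotyped yeast segregants: 97 samples (95 segregants plus the two
parental strains) profiled over six time points.  The generative model is

* a sparse true network in which each regulated gene draws its in-degree
  from the truncated-geometric law ``p(m) ∝ exp(-lambda * m)``, ``m >= 1``
  (the empirical exponential in-degree law ``157 exp(-0.45 m)``; the scale
  only shapes the histogram, the decay fixes a mean of ``1/(1 - e^-lambda)
  ≈ 2.76`` regulators per gene at lambda = 0.45);
* a first-order lag-linear recursion for the noise-free expression,
  ``X_true[g, t] = b_g0 + sum_{r in R_g} b_gr X_true[r, t-1]``, seeded by
  per-sample initial conditions at t = 0;
* additive Gaussian measurement noise, ``X = X_true + N(0, sigma_g^2)``;
* per-pair external-evidence features whose distributions are shifted on
  true edges, with ChIP evidence missing at ~9%, and a labeled training
  sample of 583 positive and 444 negative pairs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

from ibmanet.priors import TrainingSet

logger = logging.getLogger(__name__)

FEATURE_NAMES = ["coexpression", "chip", "curated", "polymorphism", "go_overlap"]


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic benchmark.

    Defaults mirror the real study: 3556 analyzed genes, 97 samples, six
    time points, in-degree decay 0.45 (mean ~2.76 regulators per regulated
    gene), 583/444 positive/negative training pairs and ~9% missing ChIP
    evidence.  ``informativeness`` in [0, 1] scales how strongly the
    external-evidence features separate true edges from non-edges (0 makes
    them pure noise).
    """

    n_genes: int = 3556
    n_samples: int = 97
    n_timepoints: int = 6
    in_degree_decay: float = 0.45
    in_degree_scale: float = 157.0
    zero_in_degree_fraction: float = 0.0
    coef_min: float = 0.2
    coef_max: float = 1.0
    intercept_sd: float = 0.25
    noise_scale: float = 0.5
    spectral_limit: float = 0.95
    informativeness: float = 0.8
    missing_chip_rate: float = 0.09
    n_pos: int = 583
    n_neg: int = 444
    negative_scheme: str = "all_pairs"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_samples, self.n_timepoints) <= 0:
            raise ValueError("dimensions must be positive")
        if self.in_degree_decay <= 0:
            raise ValueError("in-degree decay must be positive")
        if not (0 <= self.missing_chip_rate < 1):
            raise ValueError("missing_chip_rate must lie in [0, 1)")
        if not (0 <= self.zero_in_degree_fraction < 1):
            raise ValueError("zero_in_degree_fraction must lie in [0, 1)")
        if self.negative_scheme not in ("all_pairs", "regulators_only"):
            raise ValueError("negative_scheme must be all_pairs or regulators_only")

    @property
    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes - 1))
        return [f"g{i:0{width}d}" for i in range(self.n_genes)]


@dataclass
class TrueNetworkSpec:
    """Ground-truth network: regulator sets, coefficients, noise scales."""

    gene_ids: list[str]
    regulator_sets: dict[str, tuple[str, ...]]
    intercepts: dict[str, float]
    coefficients: dict[tuple[str, str], float]
    noise_sd: dict[str, float]

    def __post_init__(self) -> None:
        for g, sd in self.noise_sd.items():
            if sd <= 0:
                raise ValueError(f"noise sd for {g} must be positive")
        for g, regs in self.regulator_sets.items():
            for r in regs:
                if (g, r) not in self.coefficients:
                    raise ValueError(f"missing coefficient for pair ({g}, {r})")

    @property
    def edges(self) -> set:
        """True directed edges as (regulator, target) pairs."""
        return {
            (r, g) for g, regs in self.regulator_sets.items() for r in regs
        }

    def coefficient_matrix(self) -> sparse.csr_matrix:
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        rows, cols, vals = [], [], []
        for (g, r), beta in self.coefficients.items():
            rows.append(idx[g])
            cols.append(idx[r])
            vals.append(beta)
        n = len(self.gene_ids)
        return sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))


def mean_in_degree(decay: float) -> float:
    """Mean of the truncated-geometric in-degree law p(m) ∝ e^(-decay*m), m >= 1.

    Closed form ``1/(1 - e^(-decay))``; 2.7589... at decay 0.45.
    """
    if decay <= 0:
        raise ValueError("decay must be positive")
    return 1.0 / (1.0 - math.exp(-decay))


def _spectral_radius_estimate(mat: sparse.csr_matrix, rng, n_iter: int = 60) -> float:
    """Power-iteration estimate of the spectral radius (growth rate)."""
    n = mat.shape[0]
    x = rng.standard_normal(n)
    x /= np.linalg.norm(x)
    rho = 0.0
    for _ in range(n_iter):
        y = mat @ x
        norm = np.linalg.norm(y)
        if norm == 0:
            return 0.0
        rho = norm
        x = y / norm
    return float(rho)


def sample_true_network(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> TrueNetworkSpec:
    """Draw a ground-truth network from the configured in-degree law.

    Per regulated gene the in-degree is geometric (support m >= 1, decay
    ``in_degree_decay``); regulators are sampled uniformly without
    replacement excluding the gene itself; coefficients have uniform
    magnitude in [coef_min, coef_max] with random sign.  If the estimated
    spectral radius of the coefficient matrix exceeds ``spectral_limit``
    all coefficients are rescaled so the lag recursion stays stable.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_genes
    genes = config.gene_ids
    p_geom = 1.0 - math.exp(-config.in_degree_decay)
    regulator_sets: dict[str, tuple[str, ...]] = {}
    intercepts: dict[str, float] = {}
    coefficients: dict[tuple[str, str], float] = {}
    noise_sd: dict[str, float] = {}
    for i, g in enumerate(genes):
        intercepts[g] = float(rng.normal(0.0, config.intercept_sd))
        noise_sd[g] = float(config.noise_scale * rng.uniform(0.5, 1.5))
        if config.zero_in_degree_fraction and rng.random() < config.zero_in_degree_fraction:
            regulator_sets[g] = ()
            continue
        m = int(rng.geometric(p_geom))
        while m > n - 1:
            m = int(rng.geometric(p_geom))
        others = rng.choice(n - 1, size=m, replace=False)
        regs = tuple(genes[j if j < i else j + 1] for j in np.sort(others))
        regulator_sets[g] = regs
        for r in regs:
            mag = rng.uniform(config.coef_min, config.coef_max)
            sign = 1.0 if rng.random() < 0.5 else -1.0
            coefficients[(g, r)] = float(sign * mag)
    truth = TrueNetworkSpec(
        gene_ids=genes,
        regulator_sets=regulator_sets,
        intercepts=intercepts,
        coefficients=coefficients,
        noise_sd=noise_sd,
    )
    if coefficients:
        mat = truth.coefficient_matrix()
        rho = _spectral_radius_estimate(mat, rng)
        if rho > config.spectral_limit:
            scale = config.spectral_limit / rho
            logger.info(
                "rescaling coefficients by %.3f (spectral radius %.3f)", scale, rho
            )
            truth.coefficients = {k: v * scale for k, v in coefficients.items()}
    return truth


def generate_timeseries(
    truth: TrueNetworkSpec,
    config: SimulationConfig,
    x0: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
):
    """Generate observed and noise-free expression series from the truth.

    ``X_true[g, t, s] = b_g0 + sum_r b_gr X_true[r, t-1, s]`` for
    ``t = 1..T-1``, with ``X_true[:, 0, :] = x0`` (independent standard
    normals by default, standing in for observed baseline measurements);
    the observed series adds N(0, sigma_g^2) noise at t >= 1, and both
    series share the t = 0 slice.  Returns (observed, noise_free).
    """
    from ibmanet.ibma import ExpressionSeries

    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    genes = truth.gene_ids
    n, t_total, s = len(genes), config.n_timepoints, config.n_samples
    if x0 is None:
        x0 = rng.standard_normal((n, s))
    else:
        x0 = np.asarray(x0, dtype=float)
        if x0.shape != (n, s):
            raise ValueError("x0 must cover all genes and samples")
    mat = truth.coefficient_matrix()
    b0 = np.array([truth.intercepts[g] for g in genes])
    true_vals = np.empty((n, t_total, s))
    true_vals[:, 0, :] = x0
    for t in range(1, t_total):
        true_vals[:, t, :] = b0[:, None] + mat @ true_vals[:, t - 1, :]
        bad = ~np.isfinite(true_vals[:, t, :]).all(axis=1) | (
            np.abs(true_vals[:, t, :]).max(axis=1) > 1e6
        )
        if bad.any():
            offenders = [genes[i] for i in np.flatnonzero(bad)[:10]]
            raise FloatingPointError(
                f"lag recursion diverged at t={t} for genes {offenders}"
            )
    sd = np.array([truth.noise_sd[g] for g in genes])
    noise = rng.standard_normal((n, t_total, s)) * sd[:, None, None]
    observed = true_vals + noise
    observed[:, 0, :] = x0  # t = 0 is the shared initial condition
    times = list(range(t_total))
    samples = [f"s{j:03d}" for j in range(s)]
    return (
        ExpressionSeries(observed, list(genes), times, samples),
        ExpressionSeries(true_vals.copy(), list(genes), times, samples),
    )


def generate_external_evidence(
    truth: TrueNetworkSpec,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
):
    """Emit per-pair external-evidence features and a labeled training set.

    Features for all ordered non-self pairs: a co-expression score, a ChIP
    binding score (missing at ``missing_chip_rate``), a curated-regulator
    indicator, a sequence-polymorphism score and a GO-overlap score.  On
    true edges each continuous score is shifted upwards in proportion to
    ``informativeness`` and the curated/ChIP evidence is enriched; at
    informativeness 0 all features are label-independent noise.  The
    training set samples ``n_pos`` true edges and ``n_neg`` non-edges.
    Returns ``(training_set, all_pairs_feature_table)``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    genes = truth.gene_ids
    n = len(genes)
    # ordered non-self pairs (regulator r, target g), rows sorted by (g, r)
    tgt_idx, reg_idx = np.where(~np.eye(n, dtype=bool))
    n_pairs = len(reg_idx)
    gene_arr = np.asarray(genes)
    index = {g: i for i, g in enumerate(genes)}
    edge = np.zeros(n_pairs, dtype=bool)
    for r, g in truth.edges:
        ri, gi = index[r], index[g]
        edge[gi * (n - 1) + (ri if ri < gi else ri - 1)] = True

    a = config.informativeness
    coexpression = rng.standard_normal(n_pairs) + 1.5 * a * edge
    polymorphism = rng.standard_normal(n_pairs) + 1.0 * a * edge
    go_overlap = rng.standard_normal(n_pairs) + 0.8 * a * edge
    curated = (
        rng.random(n_pairs) < np.where(edge, 0.02 + 0.4 * a, 0.02)
    ).astype(float)
    # ChIP evidence on the -log10 p-value scale: non-edges uniform-ish small,
    # true edges inflated with informativeness
    chip = rng.exponential(0.5, size=n_pairs) + np.where(
        edge, rng.exponential(2.0 * a + 1e-12, size=n_pairs), 0.0
    )
    chip[rng.random(n_pairs) < config.missing_chip_rate] = np.nan

    table = pd.DataFrame(
        {
            "regulator_id": gene_arr[reg_idx],
            "gene_id": gene_arr[tgt_idx],
            "coexpression": coexpression,
            "chip": chip,
            "curated": curated,
            "polymorphism": polymorphism,
            "go_overlap": go_overlap,
        }
    )

    pos_rows = np.flatnonzero(edge)
    if len(pos_rows) < config.n_pos:
        raise ValueError(
            f"only {len(pos_rows)} true edges available for {config.n_pos} positives"
        )
    neg_mask = ~edge
    if config.negative_scheme == "regulators_only":
        regulators = {index[r] for r, _ in truth.edges}
        neg_mask &= np.isin(reg_idx, sorted(regulators))
    neg_rows = np.flatnonzero(neg_mask)
    if len(neg_rows) < config.n_neg:
        raise ValueError("not enough negative pairs to sample the training set")
    chosen_pos = rng.choice(pos_rows, size=config.n_pos, replace=False)
    chosen_neg = rng.choice(neg_rows, size=config.n_neg, replace=False)
    rows = np.concatenate([chosen_pos, chosen_neg])
    labels = np.concatenate(
        [np.ones(config.n_pos, dtype=int), np.zeros(config.n_neg, dtype=int)]
    )
    examples = table.iloc[rows].reset_index(drop=True)
    examples.insert(2, "label", labels)
    train = TrainingSet(
        examples=examples, feature_names=FEATURE_NAMES, chip_feature="chip"
    )
    return train, table
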