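"""Iterative BMA over ranked candidate shortlists, and network assembly.

With thousands of candidate regulators and only a few hundred observations
per gene, BMA cannot be applied to all candidates at once.  The iterative
scheme works through a ranked shortlist of the top ``p`` candidates in
sliding windows of ``w``:

1. Fill the window with the top ``w`` shortlisted candidates.
2. Run the best-subset search inside the window; weight models by BIC and by
   their prior probability computed relative to the window's candidates;
   apply Occam's window.
3. Archive every retained model; discard window candidates whose posterior
   inclusion probability falls below the drop threshold (5%) and refill the
   window from the shortlist.
4. Once all ``p`` candidates have been processed, recompute each archived
   model's prior relative to the full shortlist, apply Occam's window to the
   cumulative archive, and report final inclusion probabilities.

Four variants are supported.  ``prior`` ranks candidates by their regulatory
potential pi_gr and uses pi_gr in the model prior; ``shortlist`` ranks by
pi_gr but keeps the model prior uniform; ``size`` ignores external knowledge
except for a constant prior pi = tau (the assumed network density), turning
the model prior into a pure size penalty; ``noprior`` uses the expression
data alone.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from ibmanet import bma
from ibmanet.bma import (
    CandidateModel,
    ModelSet,
    RegressionProblem,
    apply_model_priors,
    best_subset_search,
    inclusion_probabilities,
    occams_window,
    posterior_model_probs,
)
from ibmanet.network import RegulatoryNetwork

logger = logging.getLogger(__name__)

VARIANTS = ("prior", "size", "shortlist", "noprior")

#: Default assumed network density: 2.76 expected regulators per gene over a
#: 6000-gene genome, from the empirical exponential in-degree law.
DEFAULT_TAU = 2.76 / 6000


@dataclass
class ExpressionSeries:
    """Expression values indexed (gene, time, sample).

    ``values[g, t, s]`` is the expression of gene ``g`` at time point ``t``
    in sample ``s``.  Time points are assumed ordered and uniformly spaced.
    Steady-state data are represented with a single time point.
    """

    values: np.ndarray
    gene_ids: list[str]
    time_ids: list | None = None
    sample_ids: list | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be a (gene, time, sample) array")
        g, t, s = self.values.shape
        if len(self.gene_ids) != g:
            raise ValueError("gene_ids length does not match values")
        if len(set(self.gene_ids)) != g:
            raise ValueError("gene_ids must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        if self.time_ids is None:
            self.time_ids = list(range(t))
        if self.sample_ids is None:
            self.sample_ids = list(range(s))
        if len(self.time_ids) != t or len(self.sample_ids) != s:
            raise ValueError("time_ids/sample_ids do not match values")
        self._gene_index = {gid: i for i, gid in enumerate(self.gene_ids)}

    @classmethod
    def from_matrix(cls, matrix, gene_ids, sample_ids=None) -> "ExpressionSeries":
        """Wrap a steady-state gene x sample matrix as a single time point."""
        matrix = np.asarray(matrix, dtype=float)
        return cls(
            values=matrix[:, None, :],
            gene_ids=list(gene_ids),
            time_ids=[0],
            sample_ids=sample_ids,
        )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_times(self) -> int:
        return self.values.shape[1]

    @property
    def n_samples(self) -> int:
        return self.values.shape[2]

    def index_of(self, gene_id: str) -> int:
        try:
            return self._gene_index[gene_id]
        except KeyError:
            raise KeyError(f"gene {gene_id!r} not found") from None


@dataclass
class IbmaConfig:
    """Tuning parameters of the iterative BMA engine.

    ``p`` is the shortlist length, ``w`` the BMA window size, ``nbest`` the
    number of models retained per size by the subset search, ``occam_or``
    the Occam's-window odds ratio, ``drop_threshold`` the inclusion
    probability below which a window candidate is discarded, and
    ``edge_threshold`` the final inclusion probability required to report a
    regulatory edge.  ``tau`` is the assumed network density used by the
    ``size`` variant.  ``max_size`` caps the number of regulators per model
    (``None``: min(10, N - 2)).
    """

    variant: str = "prior"
    p: int = 100
    w: int = 30
    nbest: int = 10
    occam_or: float = 20.0
    drop_threshold: float = 0.05
    edge_threshold: float = 0.5
    tau: float = DEFAULT_TAU
    max_size: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if not (1 <= self.w <= self.p):
            raise ValueError("window size w must satisfy 1 <= w <= p")
        if not (0 < self.drop_threshold < self.edge_threshold <= 1):
            raise ValueError("need 0 < drop_threshold < edge_threshold <= 1")
        if self.nbest < 1:
            raise ValueError("nbest must be >= 1")
        if self.occam_or <= 1:
            raise ValueError("occam_or must exceed 1")
        if not (0 < self.tau < 1):
            raise ValueError("tau must lie in (0, 1)")


@dataclass
class GeneSelectionResult:
    """Final iBMA output for one target gene."""

    gene: str
    inclusion: dict[str, float]
    coefficients: dict[str, float]
    intercept: float
    retained_models: ModelSet
    selected_regulators: list[str]
    n_iterations: int = 0


def build_lag_problem(
    expr: ExpressionSeries,
    gene: str,
    candidates: list[str],
    prior_inclusion=None,
) -> RegressionProblem:
    """Time-lag regression problem: gene at t on candidates at t - 1.

    The response stacks ``X[g, t, s]`` over transitions ``t = 1..T-1`` and
    all samples (row order: time-major, then sample); the predictor column
    for candidate ``r`` holds ``X[r, t-1, s]`` in the same row order, giving
    ``N = (T - 1) * S`` observations.
    """
    if expr.n_times < 2:
        raise ValueError("lag regression requires at least 2 time points")
    gi = expr.index_of(gene)
    ci = [expr.index_of(c) for c in candidates]
    y = expr.values[gi, 1:, :].ravel()
    x = expr.values[ci, :-1, :].reshape(len(ci), -1).T
    return RegressionProblem(
        response=y,
        predictors=x,
        candidate_ids=list(candidates),
        prior_inclusion=prior_inclusion,
    )


def build_static_problem(
    expr: ExpressionSeries,
    gene: str,
    candidates: list[str],
    prior_inclusion=None,
) -> RegressionProblem:
    """Steady-state regression: gene on candidates at the same time point.

    The target gene is removed from its own candidate set (a static
    self-edge is unidentifiable and would be a perfect predictor).
    """
    if expr.n_times != 1:
        raise ValueError("static regression expects a single time point")
    gi = expr.index_of(gene)
    if gene in candidates:
        logger.info("removed target gene %s from its own static candidate set", gene)
        keep = [i for i, c in enumerate(candidates) if c != gene]
        candidates = [candidates[i] for i in keep]
        if prior_inclusion is not None:
            prior_inclusion = np.asarray(prior_inclusion, dtype=float)[keep]
    if not candidates:
        raise ValueError("no candidates left after removing the target gene")
    ci = [expr.index_of(c) for c in candidates]
    return RegressionProblem(
        response=expr.values[gi, 0, :],
        predictors=expr.values[ci, 0, :].T,
        candidate_ids=list(candidates),
        prior_inclusion=prior_inclusion,
    )


def _univariate_r2(problem: RegressionProblem) -> np.ndarray:
    y = problem.response - problem.response.mean()
    x = problem.predictors - problem.predictors.mean(axis=0)
    sy = float(y @ y)
    sx = np.einsum("ij,ij->j", x, x)
    sxy = x.T @ y
    denom = sx * sy
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(denom > 0, sxy**2 / np.where(denom > 0, denom, 1.0), 0.0)
    return r2


def rank_candidates(
    gene: str,
    priors,
    expr: ExpressionSeries,
    variant: str,
    candidates: list[str] | None = None,
    mode: str = "lag",
) -> list[str]:
    """Rank candidate regulators for one target gene.

    ``prior``/``shortlist`` rank by descending regulatory potential pi_gr
    (ties broken by candidate order); ``size``/``noprior`` rank by the
    R-squared of the univariate lag (or static) regression of the target on
    each candidate, using no external knowledge.
    """
    if candidates is None:
        candidates = list(expr.gene_ids)
        if mode == "static":
            candidates = [c for c in candidates if c != gene]
    if variant in ("prior", "shortlist"):
        if priors is None:
            raise ValueError(
                f"variant {variant!r} needs a regulatory prior matrix; "
                "use variant 'size' or 'noprior' without external knowledge"
            )
        pi = priors.row(gene, candidates)
        keys = -np.asarray(pi, dtype=float)
    else:
        builder = build_static_problem if mode == "static" else build_lag_problem
        problem = builder(expr, gene, candidates)
        candidates = problem.candidate_ids
        keys = -_univariate_r2(problem)
    order = np.lexsort((np.arange(len(candidates)), keys))
    return [candidates[i] for i in order]


def _window_max_size(config: IbmaConfig, n_obs: int, n_window: int) -> int:
    cap = min(10, n_obs - 2)
    if config.max_size is not None:
        cap = min(config.max_size, n_obs - 2)
    return max(0, min(cap, n_window))


def ibma_select(
    problem: RegressionProblem,
    config: IbmaConfig,
    gene: str = "target",
) -> GeneSelectionResult:
    """Run iterative BMA for one target gene.

    ``problem`` holds the (already ranked) shortlist of candidates as its
    predictor columns, with ``problem.prior_inclusion`` carrying the
    per-candidate prior appropriate to the variant (pi_gr, tau, or the
    uniform 0.5).  Models selected at any iteration are archived and the
    final Occam's window is applied to the cumulative archive with priors
    recomputed relative to the full shortlist.
    """
    p = problem.n_candidates
    if p < 1:
        return GeneSelectionResult(
            gene=gene,
            inclusion={},
            coefficients={},
            intercept=math.nan,
            retained_models=ModelSet(models=[], normalized=False),
            selected_regulators=[],
        )
    n = problem.n_obs
    pi_full = np.clip(problem.prior_inclusion, bma.PI_CLIP, 1.0 - bma.PI_CLIP)

    window: list[int] = list(range(min(config.w, p)))
    next_idx = len(window)
    # archive: subset of shortlist indices -> (rss, bic)
    archive: dict[frozenset, tuple[float, float]] = {}
    n_iterations = 0

    while True:
        n_iterations += 1
        sub = problem.restrict(window)
        max_size = _window_max_size(config, n, len(window))
        models = best_subset_search(sub, nbest=config.nbest, max_size=max_size)
        apply_model_priors(models, pi_full[window])
        models = posterior_model_probs(models)
        models = occams_window(models, config.occam_or)

        for m in models:
            key = frozenset(window[j] for j in m.members)
            if key in archive:
                old_rss, old_bic = archive[key]
                if abs(old_bic - m.bic) > 1e-6:
                    logger.warning(
                        "model %s re-encountered with BIC %.6f vs %.6f",
                        sorted(key), m.bic, old_bic,
                    )
                if m.bic < old_bic:
                    archive[key] = (m.rss, m.bic)
            else:
                archive[key] = (m.rss, m.bic)

        summary = inclusion_probabilities(models, sub.candidate_ids)
        drop = [
            j for j, inc in enumerate(summary.inclusion)
            if inc < config.drop_threshold
        ]
        if not drop:
            # stall guard: force out the weakest candidate so the shortlist
            # always advances and the loop terminates within p iterations
            drop = [int(np.argmin(summary.inclusion))]
        dropped = set(drop)
        survivors = [window[j] for j in range(len(window)) if j not in dropped]
        if next_idx >= p:
            break
        while len(survivors) < config.w and next_idx < p:
            survivors.append(next_idx)
            next_idx += 1
        window = survivors

    # final stage: cumulative archive, priors relative to the full shortlist
    final_models = [
        CandidateModel(members=tuple(sorted(key)), rss=rss, bic=bic)
        for key, (rss, bic) in archive.items()
    ]
    final = ModelSet(models=final_models, normalized=False)
    apply_model_priors(final, pi_full)
    final = posterior_model_probs(final)
    final = occams_window(final, config.occam_or)

    gram, bvec, _, xbar, ybar = bma._centered_gram(problem)
    for m in final:
        bma._attach_coefficients(m, gram, bvec, xbar, ybar)
    summary = inclusion_probabilities(final, problem.candidate_ids)

    ids = problem.candidate_ids
    inclusion = {ids[j]: float(summary.inclusion[j]) for j in range(p)}
    selected = [
        ids[j] for j in range(p)
        if summary.inclusion[j] >= config.edge_threshold
    ]
    logger.debug(
        "gene %s: %d iterations, %d archived models, %d retained, %d selected",
        gene, n_iterations, len(archive), len(final), len(selected),
    )
    return GeneSelectionResult(
        gene=gene,
        inclusion=inclusion,
        coefficients={ids[j]: float(summary.coefficients[j]) for j in range(p)},
        intercept=float(summary.intercept),
        retained_models=final,
        selected_regulators=selected,
        n_iterations=n_iterations,
    )


def _prior_vector(
    config: IbmaConfig, priors, gene: str, shortlist: list[str]
) -> np.ndarray:
    if config.variant == "prior":
        return np.asarray(priors.row(gene, shortlist), dtype=float)
    if config.variant == "size":
        return np.full(len(shortlist), config.tau)
    return np.full(len(shortlist), 0.5)  # shortlist / noprior: uniform


def select_gene(
    expr: ExpressionSeries,
    gene: str,
    config: IbmaConfig,
    priors=None,
    candidates: list[str] | None = None,
    mode: str = "lag",
) -> GeneSelectionResult:
    """Rank, shortlist and run iBMA for a single target gene."""
    ranked = rank_candidates(
        gene, priors, expr, config.variant, candidates=candidates, mode=mode
    )
    shortlist = ranked[: config.p]
    pi = _prior_vector(config, priors, gene, shortlist)
    builder = build_static_problem if mode == "static" else build_lag_problem
    problem = builder(expr, gene, shortlist, prior_inclusion=pi)
    return ibma_select(problem, config, gene=gene)


def build_network(
    expr: ExpressionSeries,
    priors,
    config: IbmaConfig,
    targets: list[str] | None = None,
    candidates: list[str] | None = None,
    mode: str = "lag",
) -> RegulatoryNetwork:
    """Infer the regulatory network: iBMA per target gene, thresholded edges.

    Emits directed edges ``r -> g`` weighted by the final posterior
    inclusion probability, keeping edges with weight >= the configured edge
    threshold.  Genes are processed independently, so the result does not
    depend on the processing schedule.  In lag mode a gene may select itself
    (time-lagged autoregulation); static mode excludes self-edges.
    """
    if config.variant in ("prior", "shortlist"):
        if priors is None:
            raise ValueError(
                f"variant {config.variant!r} needs a regulatory prior matrix; "
                "use variant 'size' or 'noprior' without external knowledge"
            )
        missing = [g for g in expr.gene_ids if g not in priors.target_ids]
        if targets is None and missing:
            raise ValueError(
                f"prior matrix lacks rows for {len(missing)} genes, e.g. {missing[:3]}"
            )
    if targets is None:
        targets = list(expr.gene_ids)
    rows = []
    results = {}
    for gene in targets:
        res = select_gene(
            expr, gene, config, priors=priors, candidates=candidates, mode=mode
        )
        results[gene] = res
        for reg in res.selected_regulators:
            if reg == gene:
                logger.info("retained lag-mode self-edge on %s", gene)
            rows.append((reg, gene, res.inclusion[reg]))
    net = RegulatoryNetwork.from_edges(
        rows, gene_universe=set(expr.gene_ids), mode=mode
    )
    net.results = results
    return net
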