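"""Bayesian model averaging for Gaussian linear regression.

This module implements single-response BMA over subsets of candidate
regulators: an exact best-subset search (the ``nbest`` lowest-RSS models of
each size), BIC approximation of each model's integrated likelihood,
informative model priors built from per-candidate prior inclusion
probabilities, Occam's window, and posterior inclusion probabilities.

The posterior weight of a candidate model :math:`M_k` with regulator subset
:math:`S_k` is

.. math::

    \\Pr(M_k \\mid D) \\propto \\exp(-\\mathrm{BIC}_k / 2)
        \\prod_{r \\in S_k} \\pi_r \\prod_{r \\notin S_k} (1 - \\pi_r),

where :math:`\\pi_r` is the prior probability that candidate *r* is a
regulator of the response gene.  The posterior inclusion probability of a
candidate is the summed posterior weight of all retained models containing
it.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np

try:  # pragma: no cover - exercised implicitly
    import numba
except ImportError:  # pragma: no cover
    numba = None

logger = logging.getLogger(__name__)

#: Residual sums of squares are floored here before entering a logarithm,
#: guarding perfect fits (e.g. noise-free simulated data).
RSS_FLOOR = 1e-12

#: Prior inclusion probabilities are clipped to [PI_CLIP, 1 - PI_CLIP] before
#: taking logs; pi in {0, 1} would hard-exclude/include a candidate, and the
#: clipped value preserves that forcing behaviour with finite arithmetic.
PI_CLIP = 1e-10

#: Relative pivot tolerance below which a candidate is treated as collinear
#: with the current subset (the subset is singular and skipped).
_SINGULAR_TOL = 1e-9

#: Bitmask-based subset bookkeeping limits the search to 62 candidates; the
#: iterative engine only ever searches windows of w (30 by default).
MAX_SEARCH_CANDIDATES = 62


@dataclass
class RegressionProblem:
    """A single-gene variable-selection problem.

    Parameters
    ----------
    response:
        Observed expression of the target gene, length ``N``.
    predictors:
        ``N x q`` matrix of candidate-regulator expression values.
    candidate_ids:
        Identifier per predictor column.
    prior_inclusion:
        Per-candidate prior probability of being a regulator, in ``[0, 1]``.
        Defaults to the uniform 0.5, under which the model prior is flat.
    """

    response: np.ndarray
    predictors: np.ndarray
    candidate_ids: list[str]
    prior_inclusion: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.response = np.asarray(self.response, dtype=float)
        self.predictors = np.asarray(self.predictors, dtype=float)
        if self.predictors.ndim != 2:
            raise ValueError("predictors must be a 2-D matrix")
        n, q = self.predictors.shape
        if self.response.shape != (n,):
            raise ValueError("response length does not match predictor rows")
        if n < 3:
            raise ValueError("at least 3 observations are required")
        if q < 1:
            raise ValueError("at least one candidate predictor is required")
        if len(self.candidate_ids) != q:
            raise ValueError("candidate_ids length does not match predictors")
        if not np.all(np.isfinite(self.response)) or not np.all(
            np.isfinite(self.predictors)
        ):
            raise ValueError("response and predictors must be finite")
        constant = np.ptp(self.predictors, axis=0) == 0.0
        if np.any(constant):
            bad = [self.candidate_ids[i] for i in np.flatnonzero(constant)]
            raise ValueError(f"constant predictor columns rejected: {bad}")
        if self.prior_inclusion is None:
            self.prior_inclusion = np.full(q, 0.5)
        else:
            self.prior_inclusion = np.asarray(self.prior_inclusion, dtype=float)
            if self.prior_inclusion.shape != (q,):
                raise ValueError("prior_inclusion length does not match predictors")
            if np.any(self.prior_inclusion < 0) or np.any(self.prior_inclusion > 1):
                raise ValueError("prior_inclusion values must lie in [0, 1]")

    @property
    def n_obs(self) -> int:
        return self.predictors.shape[0]

    @property
    def n_candidates(self) -> int:
        return self.predictors.shape[1]

    def restrict(self, indices: list[int] | np.ndarray) -> "RegressionProblem":
        """Return the sub-problem on the given candidate columns."""
        idx = np.asarray(indices, dtype=int)
        return RegressionProblem(
            response=self.response,
            predictors=self.predictors[:, idx],
            candidate_ids=[self.candidate_ids[i] for i in idx],
            prior_inclusion=self.prior_inclusion[idx],
        )


@dataclass
class CandidateModel:
    """One regression model: a regulator subset with its fit summaries.

    ``members`` holds column indices into the owning problem's candidate
    list.  ``log_prior`` is unnormalized; ``posterior_prob`` is populated by
    :func:`posterior_model_probs`.
    """

    members: tuple[int, ...]
    rss: float
    bic: float
    log_prior: float = math.nan
    posterior_prob: float = math.nan
    coefficients: dict[int, float] = field(default_factory=dict)
    intercept: float = math.nan
    valid: bool = True

    def __post_init__(self) -> None:
        members = tuple(sorted(int(m) for m in self.members))
        if len(set(members)) != len(members):
            raise ValueError("model members contain duplicates")
        self.members = members
        if self.valid and self.rss < 0:
            raise ValueError("residual sum of squares must be non-negative")

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class ModelSet:
    """A collection of candidate models, e.g. the Occam's-window survivors."""

    models: list[CandidateModel]
    normalized: bool = False

    def __len__(self) -> int:
        return len(self.models)

    def __iter__(self):
        return iter(self.models)


@dataclass
class BmaSummary:
    """Posterior inclusion probabilities and model-averaged coefficients."""

    candidate_ids: list[str]
    inclusion: np.ndarray
    coefficients: np.ndarray
    intercept: float

    def inclusion_of(self, candidate_id: str) -> float:
        return float(self.inclusion[self.candidate_ids.index(candidate_id)])


def gaussian_bic(rss: float, n_obs: int, n_members: int) -> float:
    """Gaussian-regression BIC with the error variance profiled out.

    ``BIC = N ln(RSS / N) + (k + 1) ln N`` where ``k`` counts the regulators
    and the ``+1`` counts the intercept.  Additive constants shared by all
    models cancel in posterior odds.
    """
    rss = max(float(rss), RSS_FLOOR)
    return n_obs * math.log(rss / n_obs) + (n_members + 1) * math.log(n_obs)


def fit_subset(problem: RegressionProblem, members) -> CandidateModel:
    """Ordinary-least-squares fit of one regulator subset, with intercept.

    A collinear (singular) subset yields a model flagged ``valid=False``;
    such models are excluded from search results.
    """
    members = tuple(sorted(int(m) for m in members))
    n = problem.n_obs
    if len(members) > n - 2:
        raise ValueError("subset larger than N - 2 observations")
    if any(m < 0 or m >= problem.n_candidates for m in members):
        raise ValueError("members outside the candidate set")
    y = problem.response
    x = np.column_stack(
        [np.ones(n)] + [problem.predictors[:, m] for m in members]
    )
    beta, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    if rank < x.shape[1]:
        return CandidateModel(
            members=members, rss=math.inf, bic=math.inf, valid=False
        )
    resid = y - x @ beta
    rss = max(float(resid @ resid), RSS_FLOOR)
    return CandidateModel(
        members=members,
        rss=rss,
        bic=gaussian_bic(rss, n, len(members)),
        coefficients={m: float(b) for m, b in zip(members, beta[1:])},
        intercept=float(beta[0]),
    )


# ---------------------------------------------------------------------------
# Best-subset search
# ---------------------------------------------------------------------------


def _bnb_kernel(gram, bvec, rss0, diag0, nbest, max_size, tol):
    """Depth-first branch and bound over regulator subsets.

    Operates on the centered Gram matrix (intercept profiled out).  Keeps
    the ``nbest`` lowest-RSS subsets of every size 1..max_size.  Pruning
    uses the monotonicity of RSS: no descendant of a node can have a lower
    RSS than the fit on the node's subset joined with its whole remaining
    candidate pool.  Returns per-size arrays of RSS values, subset bitmasks
    and counts.
    """
    q = gram.shape[0]
    out_rss = np.full((max_size + 1, nbest), np.inf)
    out_mask = np.zeros((max_size + 1, nbest), np.int64)
    out_cnt = np.zeros(max_size + 1, np.int64)
    out_rss[0, 0] = rss0
    out_cnt[0] = 1
    if max_size == 0 or q == 0:
        return out_rss, out_mask, out_cnt

    levels = max_size + 1
    pool = np.zeros((levels, q), np.int64)
    plen = np.zeros(levels, np.int64)
    gres = np.zeros((levels, q, q))
    bres = np.zeros((levels, q))
    rss_l = np.zeros(levels)
    mask_l = np.zeros(levels, np.int64)
    ptr = np.zeros(levels, np.int64)

    for j in range(q):
        pool[0, j] = j
    plen[0] = q
    gres[0, :, :] = gram
    bres[0, :] = bvec
    rss_l[0] = rss0
    mask_l[0] = 0
    ptr[0] = 0

    scratch = np.zeros((q, q))
    sb = np.zeros(q)

    level = 0
    while level >= 0:
        if ptr[level] >= plen[level]:
            level -= 1
            continue
        i = ptr[level]
        ptr[level] += 1
        v = pool[level, i]
        d = gres[level, i, i]
        if d <= tol * diag0[v] or d <= 0.0:
            continue  # collinear with current subset: singular, skip subtree
        bv = bres[level, i]
        child_rss = rss_l[level] - bv * bv / d
        if child_rss < 0.0:
            child_rss = 0.0
        child_mask = mask_l[level] | (np.int64(1) << v)
        size = level + 1

        # record at this size
        cnt = out_cnt[size]
        if cnt < nbest:
            out_rss[size, cnt] = child_rss
            out_mask[size, cnt] = child_mask
            out_cnt[size] = cnt + 1
        else:
            wi = 0
            for k in range(1, nbest):
                if out_rss[size, k] > out_rss[size, wi] or (
                    out_rss[size, k] == out_rss[size, wi]
                    and out_mask[size, k] > out_mask[size, wi]
                ):
                    wi = k
            if child_rss < out_rss[size, wi] or (
                child_rss == out_rss[size, wi]
                and child_mask < out_mask[size, wi]
            ):
                out_rss[size, wi] = child_rss
                out_mask[size, wi] = child_mask

        m = plen[level] - i - 1
        if size < max_size and m > 0:
            nl = level + 1
            dinv = 1.0 / d
            sum_marg = 0.0
            for j in range(m):
                cj = gres[level, i + 1 + j, i]
                bres[nl, j] = bres[level, i + 1 + j] - cj * bv * dinv
                pool[nl, j] = pool[level, i + 1 + j]
                for k2 in range(j + 1):
                    val = (
                        gres[level, i + 1 + j, i + 1 + k2]
                        - cj * gres[level, i + 1 + k2, i] * dinv
                    )
                    gres[nl, j, k2] = val
                    gres[nl, k2, j] = val
            for j in range(m):
                dj = gres[nl, j, j]
                if dj > tol * diag0[pool[nl, j]]:
                    sum_marg += bres[nl, j] * bres[nl, j] / dj

            lo = size + 1
            hi = size + m
            if hi > max_size:
                hi = max_size

            # cheap gate first (sum of marginal reductions), exact joint
            # bound via a sweep only when the gate suggests pruning
            prune = True
            opt = child_rss - sum_marg
            for k in range(lo, hi + 1):
                if out_cnt[k] < nbest:
                    prune = False
                    break
                worst = out_rss[k, 0]
                for k3 in range(1, nbest):
                    if out_rss[k, k3] > worst:
                        worst = out_rss[k, k3]
                if not opt > worst:
                    prune = False
                    break
            if prune:
                # exact lower bound: RSS of subset joined with entire pool
                for j in range(m):
                    sb[j] = bres[nl, j]
                    for k2 in range(j + 1):
                        scratch[j, k2] = gres[nl, j, k2]
                joint = 0.0
                for j in range(m):
                    dj = scratch[j, j]
                    if dj <= tol * diag0[pool[nl, j]] or dj <= 0.0:
                        continue
                    joint += sb[j] * sb[j] / dj
                    for r in range(j + 1, m):
                        f = scratch[r, j] / dj
                        sb[r] -= f * sb[j]
                        for c2 in range(j + 1, r + 1):
                            scratch[r, c2] -= f * scratch[c2, j]
                bound = child_rss - joint
                prune = True
                for k in range(lo, hi + 1):
                    if out_cnt[k] < nbest:
                        prune = False
                        break
                    worst = out_rss[k, 0]
                    for k3 in range(1, nbest):
                        if out_rss[k, k3] > worst:
                            worst = out_rss[k, k3]
                    if not bound > worst:
                        prune = False
                        break
            if not prune:
                plen[nl] = m
                rss_l[nl] = child_rss
                mask_l[nl] = child_mask
                ptr[nl] = 0
                level = nl
    return out_rss, out_mask, out_cnt


if numba is not None:
    _bnb_kernel = numba.njit(cache=True)(_bnb_kernel)


def _centered_gram(problem: RegressionProblem):
    y = problem.response
    x = problem.predictors
    yc = y - y.mean()
    xc = x - x.mean(axis=0)
    gram = xc.T @ xc
    bvec = xc.T @ yc
    rss0 = float(yc @ yc)
    return gram, bvec, rss0, x.mean(axis=0), float(y.mean())


def best_subset_search(
    problem: RegressionProblem, nbest: int, max_size: int | None = None
) -> ModelSet:
    """Exact per-size best-subset search.

    For each model size ``0..max_size`` the ``nbest`` subsets with smallest
    residual sum of squares are returned (the size-0, intercept-only model
    is always included once).  The search is a branch and bound exploiting
    RSS monotonicity under variable addition, so its output agrees with
    exhaustive enumeration; singular (collinear) subsets are skipped.

    Candidates are visited in order of decreasing marginal RSS reduction,
    which maximizes pruning; near-exact RSS ties at the ``nbest`` boundary
    are broken deterministically by the subset bitmask in that internal
    ordering.
    """
    if nbest < 1:
        raise ValueError("nbest must be >= 1")
    n, q = problem.n_obs, problem.n_candidates
    if q > MAX_SEARCH_CANDIDATES:
        raise ValueError(
            f"best_subset_search supports at most {MAX_SEARCH_CANDIDATES} candidates"
        )
    cap = min(10, n - 2)
    if max_size is None:
        max_size = cap
    max_size = min(max_size, q, n - 2)
    if max_size < 0:
        raise ValueError("max_size must be non-negative")

    gram, bvec, rss0, xbar, ybar = _centered_gram(problem)
    diag = np.diag(gram).copy()
    marginal = np.where(diag > 0, bvec**2 / np.where(diag > 0, diag, 1.0), 0.0)
    order = np.lexsort((np.arange(q), -marginal))
    gperm = np.ascontiguousarray(gram[np.ix_(order, order)])
    bperm = np.ascontiguousarray(bvec[order])
    dperm = np.ascontiguousarray(diag[order])

    out_rss, out_mask, out_cnt = _bnb_kernel(
        gperm, bperm, max(rss0, RSS_FLOOR), dperm, nbest, max_size, _SINGULAR_TOL
    )

    models: list[CandidateModel] = []
    for size in range(max_size + 1):
        entries = []
        for k in range(out_cnt[size]):
            mask = int(out_mask[size, k])
            members = tuple(
                sorted(int(order[b]) for b in range(q) if mask >> b & 1)
            )
            entries.append((float(out_rss[size, k]), members))
        entries.sort()
        for rss, members in entries:
            rss = max(rss, RSS_FLOOR)
            model = CandidateModel(
                members=members,
                rss=rss,
                bic=gaussian_bic(rss, n, size),
            )
            _attach_coefficients(model, gram, bvec, xbar, ybar)
            models.append(model)
    return ModelSet(models=models, normalized=False)


def _attach_coefficients(model, gram, bvec, xbar, ybar) -> None:
    """OLS coefficients for a subset from the centered normal equations."""
    s = list(model.members)
    if not s:
        model.coefficients = {}
        model.intercept = ybar
        return
    beta = np.linalg.solve(gram[np.ix_(s, s)], bvec[s])
    model.coefficients = {m: float(b) for m, b in zip(s, beta)}
    model.intercept = float(ybar - beta @ xbar[s])


def exhaustive_search(
    problem: RegressionProblem, nbest: int, max_size: int | None = None
) -> ModelSet:
    """Plain enumeration over all subsets (fallback for small q, <= 15)."""
    n, q = problem.n_obs, problem.n_candidates
    if q > 15:
        raise ValueError("exhaustive enumeration limited to q <= 15")
    if max_size is None:
        max_size = min(10, n - 2)
    max_size = min(max_size, q, n - 2)
    models: list[CandidateModel] = []
    for size in range(max_size + 1):
        fits = [
            fit_subset(problem, members)
            for members in itertools.combinations(range(q), size)
        ]
        fits = [f for f in fits if f.valid]
        fits.sort(key=lambda f: (f.rss, f.members))
        models.extend(fits[:nbest])
    return ModelSet(models=models, normalized=False)


# ---------------------------------------------------------------------------
# Priors, posteriors, Occam's window, inclusion
# ---------------------------------------------------------------------------


def model_log_prior(members, prior_inclusion: np.ndarray) -> float:
    """Unnormalized log prior of a model under independent inclusion priors.

    ``sum_{r in members} ln pi_r + sum_{r not in members} ln(1 - pi_r)``
    over the supplied reference candidate set (a BMA window or the full
    shortlist).  Probabilities are clipped away from {0, 1} so the log stays
    finite while a pi near 1 (0) still effectively forces the candidate in
    (out).
    """
    pi = np.clip(np.asarray(prior_inclusion, dtype=float), PI_CLIP, 1.0 - PI_CLIP)
    inmask = np.zeros(pi.shape[0], dtype=bool)
    inmask[list(members)] = True
    return float(np.sum(np.log(np.where(inmask, pi, 1.0 - pi))))


def apply_model_priors(models: ModelSet, prior_inclusion: np.ndarray) -> ModelSet:
    """Set every model's log prior relative to the given candidate set."""
    for m in models:
        m.log_prior = model_log_prior(m.members, prior_inclusion)
    return models


def posterior_model_probs(models: ModelSet) -> ModelSet:
    """Normalize posterior model probabilities.

    ``Pr(M_k | D) ∝ exp(-BIC_k / 2 + log_prior_k)``, computed through a
    log-sum-exp for numerical stability.
    """
    valid = [m for m in models if m.valid]
    if not valid:
        raise ValueError("cannot normalize an empty model set")
    logw = np.array([-m.bic / 2.0 + m.log_prior for m in valid])
    if np.any(np.isnan(logw)):
        raise ValueError("models must have bic and log_prior set")
    logw -= logw.max()
    w = np.exp(logw)
    w /= w.sum()
    for m, p in zip(valid, w):
        m.posterior_prob = float(p)
    return ModelSet(models=valid, normalized=True)


def occams_window(models: ModelSet, or_ratio: float) -> ModelSet:
    """Discard models with posterior odds below 1/OR against the best model.

    Survivors (posterior probability >= max / OR, inclusive) are
    renormalized to sum to one.
    """
    if not models.normalized:
        raise ValueError("occams_window expects a normalized model set")
    if or_ratio <= 1:
        raise ValueError("OR must exceed 1")
    best = max(m.posterior_prob for m in models)
    cutoff = best / or_ratio
    kept = [m for m in models if m.posterior_prob >= cutoff]
    total = sum(m.posterior_prob for m in kept)
    for m in kept:
        m.posterior_prob = m.posterior_prob / total
    return ModelSet(models=kept, normalized=True)


def inclusion_probabilities(models: ModelSet, candidate_ids: list[str]) -> BmaSummary:
    """Posterior inclusion probabilities and model-averaged coefficients.

    The inclusion probability of candidate *r* is the summed posterior
    probability of retained models containing it; the BMA coefficient is
    the posterior-weighted average of per-model OLS coefficients, counting
    0 where the candidate is excluded.
    """
    if not models.normalized:
        raise ValueError("inclusion_probabilities expects a normalized model set")
    q = len(candidate_ids)
    incl = np.zeros(q)
    coef = np.zeros(q)
    intercept = 0.0
    for m in models:
        for r in m.members:
            incl[r] += m.posterior_prob
            coef[r] += m.posterior_prob * m.coefficients.get(r, 0.0)
        intercept += m.posterior_prob * (m.intercept if math.isfinite(m.intercept) else 0.0)
    np.clip(incl, 0.0, 1.0, out=incl)
    return BmaSummary(
        candidate_ids=list(candidate_ids),
        inclusion=incl,
        coefficients=coef,
        intercept=intercept,
    )
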