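"""Independent brute-force oracles used to validate the BMA machinery.

Everything here is deliberately written from first principles (per-subset
least-squares solves, explicit enumeration, direct summation) and shares no
code path with the package implementation it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

RSS_FLOOR = 1e-12


def ols_rss(y, x, members):
    """RSS of the OLS fit with intercept on one subset; None if singular."""
    n = len(y)
    design = np.column_stack([np.ones(n)] + [x[:, m] for m in members])
    beta, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        return None
    resid = y - design @ beta
    return max(float(resid @ resid), RSS_FLOOR)


def exhaustive_best_subsets(y, x, nbest, max_size):
    """nbest lowest-RSS subsets per size, by full enumeration."""
    q = x.shape[1]
    out = []
    for size in range(max_size + 1):
        fits = []
        for members in itertools.combinations(range(q), size):
            rss = ols_rss(y, x, members)
            if rss is not None:
                fits.append((rss, members))
        fits.sort()
        out.append(fits[:nbest])
    return out


def brute_force_inclusion(y, x, pi, or_ratio, max_size=None):
    """Posterior inclusion probabilities over the full model space.

    Enumerates every subset up to max_size, scores each with the Gaussian
    BIC and the independent-inclusion prior, normalizes, applies the
    posterior-odds window and sums the surviving posterior mass per
    candidate.
    """
    n, q = x.shape
    if max_size is None:
        max_size = q
    pi = np.clip(np.asarray(pi, dtype=float), 1e-10, 1 - 1e-10)
    entries = []
    for size in range(max_size + 1):
        for members in itertools.combinations(range(q), size):
            rss = ols_rss(y, x, members)
            if rss is None:
                continue
            bic = n * math.log(rss / n) + (len(members) + 1) * math.log(n)
            lp = sum(math.log(pi[j]) for j in members) + sum(
                math.log(1 - pi[j]) for j in range(q) if j not in members
            )
            entries.append((members, -bic / 2 + lp))
    logw = np.array([e[1] for e in entries])
    w = np.exp(logw - logw.max())
    w /= w.sum()
    keep = w >= w.max() / or_ratio
    w = w[keep]
    w /= w.sum()
    members_kept = [m for (m, _), k in zip(entries, keep) if k]
    incl = np.zeros(q)
    for members, weight in zip(members_kept, w):
        for j in members:
            incl[j] += weight
    return incl


def hypergeometric_upper_tail(a, n_children, n_targets, universe):
    """P(overlap >= a) when n_children genes are drawn without replacement."""
    total = 0.0
    hi = min(n_children, n_targets)
    denom = math.comb(universe, n_children)
    for k in range(a, hi + 1):
        total += (
            math.comb(n_targets, k)
            * math.comb(universe - n_targets, n_children - k)
            / denom
        )
    return total
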