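"""Concordance of an inferred network with a reference edge set.

The 2x2 contingency table classifies every candidate regulator-target pair
in the assessment universe as inferred or not and documented (reference) or
not.  Reported statistics follow the conventions of the network-inference
literature:

* TPR — the fraction of inferred edges that are documented (a
  precision-style measure; reference databases are incomplete, so recall
  against them is not meaningful);
* O/E — observed count of recovered documented edges over the count
  expected if the inferred edges were assorted at random over the universe;
* misclassifications — false positives plus false negatives;
* Pearson's chi-square (1 df, no continuity correction) for association
  between inference and documentation.

Per-regulator enrichment of known target sets among a TF's inferred
children uses a one-sided Fisher's exact test with Benjamini-Hochberg FDR
control across TFs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class ContingencyAssessment:
    """2x2 concordance of inferred edges with a reference edge set."""

    tp: int
    fp: int
    fn: int
    tn: int
    universe_size: int
    tpr: float
    oe_ratio: float
    chi_sq_stat: float
    p_value: float
    misclassified: int

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "tn": self.tn,
            "universe_size": self.universe_size,
            "tpr": self.tpr,
            "oe_ratio": self.oe_ratio,
            "chi_sq_stat": self.chi_sq_stat,
            "p_value": self.p_value,
            "misclassified": self.misclassified,
        }


def pearson_chi_square(tp: int, fp: int, fn: int, tn: int):
    """Plain Pearson chi-square (no continuity correction), 1 df.

    Closed form ``N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d))`` on the table
    [[tp, fp], [fn, tn]]; degenerate margins give statistic 0, p = 1.
    """
    n = tp + fp + fn + tn
    margins = (tp + fp) * (fn + tn) * (tp + fn) * (fp + tn)
    if margins == 0:
        return 0.0, 1.0
    stat = n * (tp * tn - fp * fn) ** 2 / margins
    return float(stat), float(stats.chi2.sf(stat, df=1))


def contingency_assess(
    inferred,
    reference,
    universe,
    exclusions=None,
) -> ContingencyAssessment:
    """Score an inferred network against a reference edge set.

    ``inferred`` is a network object or an iterable of (regulator, target)
    pairs; ``universe`` is the set of candidate pairs under consideration.
    ``exclusions`` (e.g. reference pairs already used as training examples)
    are removed from universe, reference and inferred alike before
    counting.
    """
    inferred_edges = (
        inferred.edge_set() if hasattr(inferred, "edge_set") else set(inferred)
    )
    reference = set(reference)
    universe = set(universe)
    if exclusions:
        exclusions = set(exclusions)
        universe -= exclusions
        reference -= exclusions
        inferred_edges -= exclusions
    if not universe:
        raise ValueError("assessment universe is empty")
    stray = (inferred_edges | reference) - universe
    if stray:
        raise ValueError(
            f"{len(stray)} inferred/reference pairs outside the universe, "
            f"e.g. {sorted(stray)[:3]}"
        )
    tp = len(inferred_edges & reference)
    fp = len(inferred_edges - reference)
    fn = len(reference - inferred_edges)
    tn = len(universe) - tp - fp - fn
    n_inferred = tp + fp
    n_reference = tp + fn
    tpr = tp / n_inferred if n_inferred else math.nan
    expected = n_inferred * n_reference / len(universe)
    oe = tp / expected if expected > 0 else math.nan
    chi, p = pearson_chi_square(tp, fp, fn, tn)
    return ContingencyAssessment(
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        universe_size=len(universe),
        tpr=tpr,
        oe_ratio=oe,
        chi_sq_stat=chi,
        p_value=p,
        misclassified=fp + fn,
    )


def all_pairs_universe(gene_ids, include_self: bool = False) -> set:
    """Ordered (regulator, target) pairs over a gene set."""
    return {
        (r, g)
        for r in gene_ids
        for g in gene_ids
        if include_self or r != g
    }


def tf_enrichment(
    inferred,
    tf_target_sets: dict,
    universe,
    fdr: float = 0.10,
) -> pd.DataFrame:
    """Per-TF enrichment of known target sets among inferred children.

    For each transcription factor, a one-sided Fisher's exact test asks
    whether its inferred child nodes over-represent the genes documented to
    carry its binding site, relative to the gene universe.  A TF with no
    inferred children receives p = 1 by convention and stays in the
    Benjamini-Hochberg family.  Returns a per-TF table with a boolean
    ``significant`` column at the requested FDR; the significant count is
    ``result["significant"].sum()``.
    """
    universe = set(universe)
    if hasattr(inferred, "edges"):
        children = {
            tf: {
                t
                for r, t in zip(
                    inferred.edges["regulator_id"], inferred.edges["target_id"]
                )
                if r == tf
            }
            for tf in tf_target_sets
        }
    else:
        children = {tf: set() for tf in tf_target_sets}
        for r, t in inferred:
            if r in children:
                children[r].add(t)
    rows = []
    for tf, targets in tf_target_sets.items():
        if tf not in universe and not set(targets) <= universe:
            raise ValueError(f"TF {tf!r} targets outside the gene universe")
        kids = children[tf] & universe
        tset = set(targets) & universe
        a = len(kids & tset)
        b = len(kids - tset)
        c = len(tset - kids)
        d = len(universe) - a - b - c
        if not kids:
            p = 1.0
        else:
            _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append((tf, a, len(kids), len(tset), float(p)))
    out = pd.DataFrame(
        rows, columns=["tf", "overlap", "n_children", "n_targets", "p_value"]
    )
    out["q_value"] = _benjamini_hochberg(out["p_value"].to_numpy())
    out["significant"] = out["q_value"] <= fdr
    return out


def _benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    m = len(pvals)
    order = np.argsort(pvals, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        adj[i] = running
    return adj
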