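"""Supervised construction of regulatory potentials pi_gr.

External evidence of transcriptional regulation (co-expression across public
experiments, ChIP binding p-values, curated-regulator status, regulator
sequence polymorphism, shared GO annotation) is summarized per
regulator-gene pair into a single prior probability pi_gr ("regulatory
potential") by a BMA logistic regression trained on labeled TF-gene
examples.  Three refinements deal with the realities of such training data:

* missing ChIP evidence is multiply imputed from the empirical distribution
  of the observed values within each label class;
* extreme feature values outside the training range are truncated to the
  training extremes before prediction;
* the heavy over-representation of positive pairs in the training sample
  relative to a sparse network (density tau ~ 2.76 / 6000) is corrected by
  dividing predicted odds by the case-control sampling-rate ratio pi1/pi0,
  the classical offset adjustment of case-control logistic regression.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

from ibmanet.bma import PI_CLIP

logger = logging.getLogger(__name__)

PAIR_COLUMNS = ("regulator_id", "gene_id")

#: Occam's-window odds ratio for the logistic BMA over feature subsets.
LOGISTIC_OR = 20.0

#: Ridge penalty applied when a feature subset exhibits (quasi-)separation.
SEPARATION_RIDGE = 1e-6


@dataclass
class TrainingSet:
    """Labeled regulator-gene training examples with per-pair features.

    ``examples`` is a data frame with columns ``regulator_id``, ``gene_id``,
    ``label`` (1 = documented regulatory relationship, 0 = negative) and one
    column per feature.  The ChIP-evidence feature may contain missing
    values (NaN).
    """

    examples: pd.DataFrame
    feature_names: list[str]
    chip_feature: str = "chip"

    def __post_init__(self) -> None:
        required = set(PAIR_COLUMNS) | {"label"} | set(self.feature_names)
        missing = required - set(self.examples.columns)
        if missing:
            raise ValueError(f"training table lacks columns: {sorted(missing)}")
        labels = set(self.examples["label"].unique())
        if not labels <= {0, 1}:
            raise ValueError("labels must be coded 0/1")
        non_chip = [f for f in self.feature_names if f != self.chip_feature]
        if self.examples[non_chip].isna().any().any():
            raise ValueError("only the ChIP feature may contain missing values")

    @property
    def n_pos(self) -> int:
        return int((self.examples["label"] == 1).sum())

    @property
    def n_neg(self) -> int:
        return int((self.examples["label"] == 0).sum())

    def copy_with(self, examples: pd.DataFrame) -> "TrainingSet":
        return TrainingSet(
            examples=examples,
            feature_names=list(self.feature_names),
            chip_feature=self.chip_feature,
        )


@dataclass
class BiasAdjustment:
    """Case-control sampling rates and the implied odds correction.

    ``pi1`` (``pi0``) is the fraction of all truly positive (negative)
    regulator-gene pairs that entered the training sample; predicted odds
    are divided by ``pi1 / pi0``, equivalent to adding an offset of
    ``-log(pi1/pi0)`` to the logistic model.
    """

    pi1: float
    pi0: float
    tau: float = math.nan

    def __post_init__(self) -> None:
        if not (0 < self.pi1 <= 1) or not (0 < self.pi0 <= 1):
            raise ValueError("sampling rates must lie in (0, 1]")

    @property
    def odds_ratio(self) -> float:
        return self.pi1 / self.pi0

    @property
    def offset(self) -> float:
        return -math.log(self.odds_ratio)

    @classmethod
    def neutral(cls) -> "BiasAdjustment":
        return cls(pi1=1.0, pi0=1.0, tau=math.nan)


@dataclass
class RegulatoryPriorMatrix:
    """Prior probabilities pi_gr that regulator r regulates gene g.

    Stored as a dense data frame with target genes as rows and candidate
    regulators as columns.  ``tau`` records the assumed network density used
    in the sampling-bias calibration.
    """

    pi: pd.DataFrame
    tau: float

    def __post_init__(self) -> None:
        values = self.pi.to_numpy(dtype=float)
        finite = values[np.isfinite(values)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("prior probabilities must lie in [0, 1]")

    @property
    def target_ids(self) -> list[str]:
        return list(self.pi.index)

    @property
    def regulator_ids(self) -> list[str]:
        return list(self.pi.columns)

    @property
    def expected_regulators(self) -> pd.Series:
        """Sum of pi_gr over candidate regulators, per target gene."""
        return self.pi.sum(axis=1)

    def row(self, gene: str, regulators: list[str]) -> np.ndarray:
        """Prior vector for one target over the requested regulators.

        Pairs absent from the matrix (e.g. self-pairs) fall back to tau.
        """
        if gene not in self.pi.index:
            raise KeyError(f"gene {gene!r} not in prior matrix")
        row = self.pi.loc[gene]
        out = np.full(len(regulators), self.tau, dtype=float)
        known = row.index.get_indexer(regulators)
        for i, j in enumerate(known):
            if j >= 0:
                v = row.iloc[j]
                if np.isfinite(v):
                    out[i] = v
        return out

    @classmethod
    def from_long(cls, table: pd.DataFrame, tau: float) -> "RegulatoryPriorMatrix":
        wide = table.pivot(index="gene_id", columns="regulator_id", values="pi")
        return cls(pi=wide, tau=tau)

    def to_long(self) -> pd.DataFrame:
        long = self.pi.stack().rename("pi").reset_index()
        long.columns = ["gene_id", "regulator_id", "pi"]
        return long[["gene_id", "regulator_id", "pi"]]


def compute_sampling_rates(
    n_pos: int, n_neg: int, n_genes: int, mean_in_degree: float
) -> BiasAdjustment:
    """Sampling rates of positive/negative training pairs in a sparse network.

    Out of ``n_genes * mean_in_degree`` truly positive pairs genome-wide,
    ``n_pos`` were sampled; out of ``n_genes * (n_genes - mean_in_degree)``
    negative pairs, ``n_neg`` were sampled.  The network density is
    ``tau = mean_in_degree / n_genes``.
    """
    if min(n_pos, n_neg, n_genes) <= 0 or mean_in_degree <= 0:
        raise ValueError("all inputs must be positive")
    if mean_in_degree >= n_genes:
        raise ValueError("mean in-degree must be smaller than the gene count")
    pi1 = n_pos / (n_genes * mean_in_degree)
    pi0 = n_neg / (n_genes * (n_genes - mean_in_degree))
    return BiasAdjustment(pi1=pi1, pi0=pi0, tau=mean_in_degree / n_genes)


def adjust_probability(raw_prob, adj: BiasAdjustment):
    """Correct a predicted probability for case-control sampling bias.

    The predicted odds are divided by ``pi1 / pi0`` and converted back to a
    probability.  Accepts scalars or arrays; raw values of exactly 0 or 1
    are clipped away from the boundary.
    """
    raw = np.asarray(raw_prob, dtype=float)
    if np.any((raw <= 0) | (raw >= 1)):
        logger.info("raw probabilities at {0,1} clipped before odds adjustment")
    raw = np.clip(raw, 1e-12, 1 - 1e-12)
    odds = raw / (1.0 - raw) / adj.odds_ratio
    out = odds / (1.0 + odds)
    if np.isscalar(raw_prob) or np.ndim(raw_prob) == 0:
        return float(out)
    return out


def impute_missing_chip(
    train: TrainingSet,
    n_imputations: int = 20,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[TrainingSet]:
    """Multiple imputation of missing ChIP evidence, within label class.

    Each missing ChIP value is replaced by a draw with replacement from the
    observed ChIP values of training examples with the same label, producing
    ``n_imputations`` completed copies (20 is a standard choice for ~10%
    missingness).  Non-missing values are untouched.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    chip = train.chip_feature
    df = train.examples
    observed = {
        label: df.loc[(df["label"] == label) & df[chip].notna(), chip].to_numpy()
        for label in (0, 1)
    }
    for label, pool in observed.items():
        if pool.size == 0 and (df["label"] == label).any():
            raise ValueError(
                f"label class {label} has no observed ChIP values to draw from"
            )
    missing = df[chip].isna().to_numpy()
    copies = []
    for _ in range(n_imputations):
        filled = df.copy()
        if missing.any():
            values = filled[chip].to_numpy(dtype=float, copy=True)
            for label in (0, 1):
                mask = missing & (df["label"] == label).to_numpy()
                k = int(mask.sum())
                if k:
                    values[mask] = rng.choice(observed[label], size=k, replace=True)
            filled[chip] = values
        copies.append(train.copy_with(filled))
    return copies


def truncate_extremes(
    features: pd.DataFrame,
    train: TrainingSet,
    lower: bool = True,
) -> pd.DataFrame:
    """Clamp feature values outside the training range.

    Values above the per-feature training maximum are set to that maximum;
    with ``lower=True`` (default) values below the training minimum are
    symmetrically raised to the minimum.  Missing values pass through.
    """
    out = features.copy()
    n_upper = n_lower = 0
    for name in train.feature_names:
        if name not in out.columns:
            continue
        col = out[name]
        obs = train.examples[name].dropna()
        if obs.empty:
            continue
        hi, lo = float(obs.max()), float(obs.min())
        over = col > hi
        n_upper += int(over.sum())
        col = col.where(~over, hi)
        if lower:
            under = col < lo
            n_lower += int(under.sum())
            col = col.where(~under, lo)
        out[name] = col
    logger.info(
        "truncated %d values to training maxima, %d to minima", n_upper, n_lower
    )
    return out


# ---------------------------------------------------------------------------
# BMA logistic regression over feature subsets
# ---------------------------------------------------------------------------


def _logistic_loglik(beta, x, y, ridge):
    eta = x @ beta
    # log(1 + exp(eta)) - y * eta, stably
    ll = np.sum(y * eta - np.logaddexp(0.0, eta))
    if ridge:
        ll -= 0.5 * ridge * float(beta @ beta)
    return ll


def _fit_logistic(x: np.ndarray, y: np.ndarray, ridge: float = 0.0):
    """Maximum-likelihood logistic fit (optionally ridge-penalized)."""

    def negll(beta):
        return -_logistic_loglik(beta, x, y, ridge)

    def grad(beta):
        mu = expit(x @ beta)
        g = x.T @ (mu - y)
        if ridge:
            g = g + ridge * beta
        return g

    beta0 = np.zeros(x.shape[1])
    res = minimize(negll, beta0, jac=grad, method="L-BFGS-B")
    beta = res.x
    ll = _logistic_loglik(beta, x, y, 0.0)
    return beta, float(ll), bool(res.success)


@dataclass
class _ImputationFit:
    masks: list[tuple[int, ...]]
    betas: list[np.ndarray]
    weights: np.ndarray


@dataclass
class RegulatoryPotentialModel:
    """Fitted BMA logistic model over feature subsets, per imputation."""

    feature_names: list[str]
    fits: list[_ImputationFit]
    adjustment: BiasAdjustment
    chip_feature: str
    chip_pool: np.ndarray
    inclusion: pd.Series = field(default=None)
    coefficients: pd.Series = field(default=None)

    @property
    def n_imputations(self) -> int:
        return len(self.fits)


def _bma_logistic(x: np.ndarray, y: np.ndarray, n_features: int) -> _ImputationFit:
    """Fit all 2^F feature subsets, weight by exp(-BIC/2), Occam's window."""
    n = x.shape[0]
    masks, betas, bics = [], [], []
    for subset in itertools.chain.from_iterable(
        itertools.combinations(range(n_features), k)
        for k in range(n_features + 1)
    ):
        cols = [0] + [j + 1 for j in subset]
        xs = x[:, cols]
        beta, ll, ok = _fit_logistic(xs, y)
        if not ok or np.max(np.abs(beta)) > 30.0:
            logger.info(
                "feature subset %s separated or ill-conditioned; ridge refit",
                subset,
            )
            beta, ll, _ = _fit_logistic(xs, y, ridge=SEPARATION_RIDGE)
        masks.append(tuple(subset))
        betas.append(beta)
        bics.append(-2.0 * ll + len(cols) * math.log(n))
    bics = np.asarray(bics)
    logw = -(bics - bics.min()) / 2.0
    w = np.exp(logw)
    w /= w.sum()
    keep = w >= w.max() / LOGISTIC_OR
    w = w[keep]
    w /= w.sum()
    masks = [m for m, k in zip(masks, keep) if k]
    betas = [b for b, k in zip(betas, keep) if k]
    return _ImputationFit(masks=masks, betas=betas, weights=w)


def fit_regulatory_model(
    imputed: list[TrainingSet],
    adj: BiasAdjustment,
) -> RegulatoryPotentialModel:
    """BMA logistic regression of the regulation label on external features.

    For every completed (imputed) training copy, all feature subsets are fit
    by maximum likelihood, weighted by ``exp(-BIC/2)`` and passed through
    Occam's window (OR = 20).  The sampling-bias adjustment is stored and
    applied at prediction time.
    """
    if not imputed:
        raise ValueError("need at least one imputed training set")
    first = imputed[0]
    names = list(first.feature_names)
    if len(names) > 15:
        raise ValueError("exhaustive feature-subset enumeration needs <= 15 features")
    fits = []
    incl = np.zeros(len(names))
    coef = np.zeros(len(names))
    for train in imputed:
        y = train.examples["label"].to_numpy(dtype=float)
        x = np.column_stack(
            [np.ones(len(y))] + [train.examples[f].to_numpy(dtype=float) for f in names]
        )
        if np.isnan(x).any():
            raise ValueError("imputed training sets must be complete")
        fit = _bma_logistic(x, y, len(names))
        fits.append(fit)
        for mask, beta, w in zip(fit.masks, fit.betas, fit.weights):
            for pos, j in enumerate(mask):
                incl[j] += w
                coef[j] += w * beta[pos + 1]
    incl /= len(imputed)
    coef /= len(imputed)
    chip_pool = first.examples[first.chip_feature].dropna().to_numpy()
    return RegulatoryPotentialModel(
        feature_names=names,
        fits=fits,
        adjustment=adj,
        chip_feature=first.chip_feature,
        chip_pool=chip_pool,
        inclusion=pd.Series(incl, index=names),
        coefficients=pd.Series(coef, index=names),
    )


def predict_regulatory_potential(
    model: RegulatoryPotentialModel,
    features: pd.DataFrame,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> RegulatoryPriorMatrix:
    """Predict pi_gr for every regulator-gene pair in the feature table.

    The BMA-predicted probability is averaged across the imputation fits and
    then corrected for sampling bias.  Features missing at prediction time
    (the label being unknown) are imputed unconditionally from the training
    empirical distribution.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    for col in PAIR_COLUMNS:
        if col not in features.columns:
            raise ValueError(f"feature table lacks column {col!r}")
    x = features[model.feature_names].to_numpy(dtype=float, copy=True)
    chip_idx = (
        model.feature_names.index(model.chip_feature)
        if model.chip_feature in model.feature_names
        else None
    )
    missing = np.isnan(x)
    if missing.any():
        if chip_idx is None or missing[:, [j for j in range(x.shape[1]) if j != chip_idx]].any():
            raise ValueError("only the ChIP feature may be missing at prediction")
        k = int(missing[:, chip_idx].sum())
        logger.info("imputing %d missing ChIP values at prediction time", k)
        if model.chip_pool.size == 0:
            raise ValueError("no observed training ChIP values to impute from")
        x[missing[:, chip_idx], chip_idx] = rng.choice(
            model.chip_pool, size=k, replace=True
        )
    design = np.column_stack([np.ones(x.shape[0]), x])
    prob = np.zeros(x.shape[0])
    for fit in model.fits:
        acc = np.zeros(x.shape[0])
        for mask, beta, w in zip(fit.masks, fit.betas, fit.weights):
            cols = [0] + [j + 1 for j in mask]
            acc += w * expit(design[:, cols] @ beta)
        prob += acc
    prob /= model.n_imputations
    adjusted = adjust_probability(prob, model.adjustment)
    adjusted = np.clip(adjusted, PI_CLIP, 1.0 - PI_CLIP)
    long = features[list(PAIR_COLUMNS)].copy()
    long["pi"] = adjusted
    wide = long.pivot(index="gene_id", columns="regulator_id", values="pi")
    tau = model.adjustment.tau
    if not math.isfinite(tau):
        tau = float(np.nanmean(adjusted))
    return RegulatoryPriorMatrix(pi=wide, tau=tau)
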