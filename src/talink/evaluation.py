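"""Item-by-item model evaluation: squared error, cross entropy, R2, paired tests.

Each model is scored against the observed pronoun-prompt NP1 proportions,
one data point per item:

* squared error    (p_i - p^_i)^2, averaged to MSE;
* cross entropy    -[p_i log2 p^_i + (1-p_i) log2(1-p^_i)] in bits,
                   averaged to ACE (lower is better; by Gibbs' inequality
                   ACE is bounded below by the mean binary entropy of the
                   observed proportions, reached only at perfect
                   calibration);
* R2               the squared Pearson correlation of observed and
                   predicted vectors — it rewards covariation and is
                   insensitive to calibration, which is exactly why it is
                   reported alongside MSE/ACE rather than instead of them.

Model pairs are compared with classical paired t-tests on the by-item
error vectors (two-sided).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .estimation import ObservedInterpretation
from .linking_models import LinkingModel, ModelPredictions

__all__ = [
    "EvaluationPair",
    "PairedTestResult",
    "ModelScore",
    "EvaluationReport",
    "squared_error",
    "cross_entropy",
    "summarize",
    "paired_item_test",
    "compare_models",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EvaluationPair:
    item_id: str
    p_obs: float
    p_hat: float


def squared_error(p_obs: float, p_hat: float) -> float:
    """Squared difference between observed and predicted proportion."""
    return (p_obs - p_hat) ** 2


def cross_entropy(p_obs: float, p_hat: float) -> float:
    """Binary cross entropy in bits, with the convention 0*log2(0) = 0.

    Infinite when the model puts probability 0 on an outcome the data
    contain (p_obs > 0 with p_hat = 0, or p_obs < 1 with p_hat = 1);
    returned as ``math.inf``, never raised, since smoothing upstream makes
    the case unreachable in the standard pipeline.
    """
    total = 0.0
    for p, q in ((p_obs, p_hat), (1.0 - p_obs, 1.0 - p_hat)):
        if p > 0.0:
            total -= p * math.log2(q) if q > 0.0 else -math.inf
    return total


def summarize(pairs: Sequence[EvaluationPair]) -> tuple[float, float, float]:
    """(R2, MSE, ACE) over a collection of observed/predicted pairs.

    MSE and ACE are plain means of the per-item quantities, every item
    weighted equally.  R2 is the squared Pearson correlation; it is
    undefined (returned as NaN, with a warning) when either vector has
    zero variance, and requires at least 3 pairs.
    """
    if not pairs:
        raise ValueError("summarize needs at least one pair")
    obs = np.array([p.p_obs for p in pairs])
    hat = np.array([p.p_hat for p in pairs])
    mse = float(np.mean((obs - hat) ** 2))
    ace = float(np.mean([cross_entropy(p.p_obs, p.p_hat) for p in pairs]))
    if len(pairs) < 3 or obs.std() == 0.0 or hat.std() == 0.0:
        logger.warning(
            "R2 undefined (n=%d, degenerate variance); reported as NaN", len(pairs)
        )
        r2 = float("nan")
    else:
        r2 = float(stats.pearsonr(obs, hat).statistic ** 2)
    return r2, mse, ace


@dataclass(frozen=True)
class PairedTestResult:
    t: float  # NaN when the differences are degenerate
    df: int
    p_value: float


def paired_item_test(
    errors_a: Sequence[float], errors_b: Sequence[float]
) -> PairedTestResult:
    """Classical paired t-test on aligned by-item error vectors.

    Degenerate inputs (all differences identical, hence zero variance) have
    no defined t statistic; t and p are then NaN, with a warning.
    """
    a = np.asarray(errors_a, dtype=float)
    b = np.asarray(errors_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("paired test needs two aligned vectors of length >= 2")
    df = len(a) - 1
    if np.ptp(a - b) == 0.0:
        logger.warning("paired t-test degenerate: zero-variance differences")
        return PairedTestResult(t=float("nan"), df=df, p_value=float("nan"))
    res = stats.ttest_rel(a, b)
    return PairedTestResult(t=float(res.statistic), df=df, p_value=float(res.pvalue))


@dataclass(frozen=True)
class ModelScore:
    model_name: LinkingModel
    r_squared: float
    mse: float
    ace: float
    n_items: int


@dataclass(frozen=True)
class EvaluationReport:
    """Machine twin of a model-comparison table plus its scatter data."""

    scores: Mapping[LinkingModel, ModelScore]
    # (model_a, model_b, metric) -> paired test; metric in {"squared_error",
    # "cross_entropy"}
    paired_tests: Mapping[tuple, PairedTestResult]
    scatter: pd.DataFrame  # columns: item key fields, model_name, p_obs, p_hat

    def to_table(self) -> pd.DataFrame:
        rows = [
            {
                "model_name": s.model_name.value,
                "r_squared": s.r_squared,
                "mse": s.mse,
                "ace": s.ace,
                "n_items": s.n_items,
            }
            for s in self.scores.values()
        ]
        return pd.DataFrame(rows)

    def tests_table(self) -> pd.DataFrame:
        rows = [
            {
                "model_a": a.value,
                "model_b": b.value,
                "metric": metric,
                "t": res.t,
                "df": res.df,
                "p_value": res.p_value,
            }
            for (a, b, metric), res in self.paired_tests.items()
        ]
        return pd.DataFrame(rows)


def _observed_key(obs: ObservedInterpretation) -> tuple:
    c = obs.condition
    return (c.experiment, obs.item_id, c.verb_type.value, c.construction.value)


def compare_models(
    observed: Sequence[ObservedInterpretation],
    predictions: Sequence[ModelPredictions],
    drop_unmatched: bool = True,
) -> EvaluationReport:
    """Score every model on the common item set and run pairwise t-tests.

    Items present in only one of the two data sources are dropped with a
    warning when ``drop_unmatched`` (the default); prediction items missing
    an observation are always an error, since predictions exist only to be
    scored.
    """
    obs_by_key = {_observed_key(o): o for o in observed}
    common_keys = None
    for pred in predictions:
        missing = set(pred.p_hat) - set(obs_by_key)
        if missing:
            raise KeyError(
                f"{pred.model_name.value} predictions lack observed pairs for: "
                f"{sorted(missing)[:5]}"
            )
        keys = set(pred.p_hat)
        common_keys = keys if common_keys is None else common_keys & keys
    common_keys = common_keys or set()
    unpredicted = set(obs_by_key) - common_keys
    if unpredicted and drop_unmatched:
        logger.warning(
            "%d observed items have no prediction and are dropped from evaluation",
            len(unpredicted),
        )
    ordered = sorted(common_keys)

    scores: dict[LinkingModel, ModelScore] = {}
    errors: dict[LinkingModel, dict[str, np.ndarray]] = {}
    scatter_rows = []
    for pred in predictions:
        pairs = [
            EvaluationPair(item_id=key[1], p_obs=obs_by_key[key].p_obs, p_hat=pred.p_hat[key])
            for key in ordered
        ]
        r2, mse, ace = summarize(pairs)
        scores[pred.model_name] = ModelScore(
            model_name=pred.model_name, r_squared=r2, mse=mse, ace=ace, n_items=len(pairs)
        )
        errors[pred.model_name] = {
            "squared_error": np.array([squared_error(p.p_obs, p.p_hat) for p in pairs]),
            "cross_entropy": np.array([cross_entropy(p.p_obs, p.p_hat) for p in pairs]),
        }
        for key, pair in zip(ordered, pairs):
            scatter_rows.append(
                {
                    "experiment": key[0],
                    "item_id": key[1],
                    "verb_type": key[2],
                    "construction": key[3],
                    "model_name": pred.model_name.value,
                    "p_obs": pair.p_obs,
                    "p_hat": pair.p_hat,
                }
            )

    paired: dict[tuple, PairedTestResult] = {}
    if len(ordered) >= 2:
        for other in (LinkingModel.EXPECTANCY, LinkingModel.MIRROR):
            if LinkingModel.BAYESIAN in errors and other in errors:
                for metric in ("squared_error", "cross_entropy"):
                    paired[(LinkingModel.BAYESIAN, other, metric)] = paired_item_test(
                        errors[LinkingModel.BAYESIAN][metric], errors[other][metric]
                    )
    return EvaluationReport(
        scores=scores, paired_tests=paired, scatter=pd.DataFrame(scatter_rows)
    )
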