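"""Linking models: from (prior, production likelihood) to interpretation bias.

Three competing accounts of how a comprehender resolves the overt pronoun
'ta' between the two candidate referents NP1 and NP2:

* Bayesian — the normative posterior,
  P(NP1 | 'ta') = P('ta'|NP1) P(NP1) / sum_j P('ta'|NPj) P(NPj);
* Expectancy — interpretation bias equals the next-mention prior P(NP1);
* Mirror — interpretation bias equals the normalized production
  likelihoods, P('ta'|NP1) / sum_j P('ta'|NPj).

A fourth, counterfactual variant re-runs the Bayesian formula with the
prior of the matched item in an alternate construction substituted (used to
unconfound prior and likelihood effects of passivization): the likelihoods
stay item-specific, only the prior term is swapped.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .estimation import ItemEstimates

__all__ = [
    "LinkingModel",
    "ModelPredictions",
    "UndefinedPredictionError",
    "PairingError",
    "predict_bayesian",
    "predict_expectancy",
    "predict_mirror",
    "predict_bayesian_counterfactual_prior",
    "predict_all",
]


class LinkingModel(str, enum.Enum):
    BAYESIAN = "BAYESIAN"
    EXPECTANCY = "EXPECTANCY"
    MIRROR = "MIRROR"
    BAYESIAN_CF_PRIOR = "BAYESIAN_CF_PRIOR"


class UndefinedPredictionError(ZeroDivisionError):
    """The model's normalizing denominator is zero (unsmoothed inputs only)."""


class PairingError(KeyError):
    """No matched alternate-construction item for the counterfactual prior."""


def predict_bayesian(prior_np1: float, lik_ta_np1: float, lik_ta_np2: float) -> float:
    """Normative posterior P(NP1 | 'ta') by Bayes' rule over {NP1, NP2}."""
    num = lik_ta_np1 * prior_np1
    denom = num + lik_ta_np2 * (1.0 - prior_np1)
    if denom == 0.0:
        raise UndefinedPredictionError(
            "Bayesian prediction undefined: both posterior terms are zero"
        )
    return num / denom


def predict_expectancy(prior_np1: float) -> float:
    """Expectancy account: interpretation bias is the next-mention prior."""
    return prior_np1


def predict_mirror(lik_ta_np1: float, lik_ta_np2: float) -> float:
    """Mirror account: normalized pronoun-production likelihoods."""
    denom = lik_ta_np1 + lik_ta_np2
    if denom == 0.0:
        raise UndefinedPredictionError(
            "Mirror prediction undefined: both production likelihoods are zero"
        )
    return lik_ta_np1 / denom


def predict_bayesian_counterfactual_prior(
    prior_np1_substitute: float, lik_ta_np1: float, lik_ta_np2: float
) -> float:
    """Bayesian formula with a substituted (alternate-construction) prior."""
    return predict_bayesian(prior_np1_substitute, lik_ta_np1, lik_ta_np2)


@dataclass(frozen=True)
class ModelPredictions:
    """Per-item predicted P(NP1 | 'ta') for one linking model."""

    model_name: LinkingModel
    # item key -> predicted probability; keys are (experiment, item_id,
    # verb_type value, construction value) so predictions align with
    # observations across experiments
    p_hat: Mapping[tuple, float]


def item_key(estimate: ItemEstimates) -> tuple:
    c = estimate.condition
    return (c.experiment, estimate.item_id, c.verb_type.value, c.construction.value)


def pairing_key(estimate: ItemEstimates) -> tuple:
    """Counterfactual pairing ignores construction: same experiment, item, verb."""
    c = estimate.condition
    return (c.experiment, estimate.item_id, c.verb_type.value)


def predict_all(
    estimates: Sequence[ItemEstimates],
    pairing: Mapping[tuple, ItemEstimates] | None = None,
) -> list[ModelPredictions]:
    """Item-by-item predictions for every linking model.

    Parameters
    ----------
    estimates
        Smoothed item estimates (typically from a single construction when
        a counterfactual pairing is supplied).
    pairing
        Optional map from :func:`pairing_key` to the matched item's
        estimates in the alternate construction, whose prior replaces the
        item's own in the counterfactual model.  When omitted only the
        three standard models are emitted.
    """
    bayes, expect, mirror, cf = {}, {}, {}, {}
    for e in estimates:
        key = item_key(e)
        bayes[key] = predict_bayesian(e.prior_np1, e.lik_ta_np1, e.lik_ta_np2)
        expect[key] = predict_expectancy(e.prior_np1)
        mirror[key] = predict_mirror(e.lik_ta_np1, e.lik_ta_np2)
        if pairing is not None:
            pk = pairing_key(e)
            if pk not in pairing:
                raise PairingError(
                    f"no matched alternate-construction item for {pk}"
                )
            cf[key] = predict_bayesian_counterfactual_prior(
                pairing[pk].prior_np1, e.lik_ta_np1, e.lik_ta_np2
            )
    out = [
        ModelPredictions(LinkingModel.BAYESIAN, bayes),
        ModelPredictions(LinkingModel.EXPECTANCY, expect),
        ModelPredictions(LinkingModel.MIRROR, mirror),
    ]
    if pairing is not None:
        out.append(ModelPredictions(LinkingModel.BAYESIAN_CF_PRIOR, cf))
    return out


def predictions_to_frame(
    predictions: Iterable[ModelPredictions],
    estimates: Sequence[ItemEstimates] | None = None,
) -> pd.DataFrame:
    """Long-format predictions table, with model inputs for auditability."""
    inputs = {item_key(e): e for e in estimates} if estimates else {}
    rows = []
    for pred in predictions:
        for key, p in pred.p_hat.items():
            experiment, item_id, verb_type, construction = key
            row = {
                "experiment": experiment,
                "item_id": item_id,
                "verb_type": verb_type,
                "construction": construction,
                "model_name": pred.model_name.value,
                "p_hat": p,
            }
            if key in inputs:
                e = inputs[key]
                row.update(
                    prior_np1=e.prior_np1,
                    lik_ta_np1=e.lik_ta_np1,
                    lik_ta_np2=e.lik_ta_np2,
                )
            rows.append(row)
    return pd.DataFrame(rows)
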