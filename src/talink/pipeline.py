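"""One-call in-memory pipeline: coded records -> evaluated linking models."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .core_data import CodedDataset, ExclusionReport, filter_analyzable
from .estimation import (
    ItemEstimates,
    ObservedInterpretation,
    SmoothingConfig,
    estimate_items,
    observed_interpretations,
)
from .evaluation import EvaluationReport, compare_models
from .linking_models import ModelPredictions, predict_all


@dataclass
class PipelineResult:
    exclusion: ExclusionReport
    estimates: Sequence[ItemEstimates]
    observed: Sequence[ObservedInterpretation]
    predictions: Sequence[ModelPredictions]
    report: EvaluationReport | None  # None when no pronoun-prompt data


def evaluate_dataset(
    dataset: CodedDataset, cfg: SmoothingConfig = SmoothingConfig()
) -> PipelineResult:
    """Filter, estimate, predict and score a coded dataset in memory.

    Prediction cells without pronoun-prompt observations are dropped from
    the model comparison (they still appear in ``estimates`` and
    ``predictions``), matching the file-based ``talink analyze`` command.
    """
    kept, exclusion = filter_analyzable(dataset)
    estimates = estimate_items(kept.free_prompt(), cfg)
    observed = observed_interpretations(kept.pronoun_prompt())
    predictions = predict_all(estimates)
    report = None
    if observed:
        obs_keys = {
            (
                o.condition.experiment,
                o.item_id,
                o.condition.verb_type.value,
                o.condition.construction.value,
            )
            for o in observed
        }
        evaluable = [
            ModelPredictions(p.model_name, {k: v for k, v in p.p_hat.items() if k in obs_keys})
            for p in predictions
        ]
        report = compare_models(observed, evaluable)
    return PipelineResult(
        exclusion=exclusion,
        estimates=estimates,
        observed=observed,
        predictions=predictions,
        report=report,
    )
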