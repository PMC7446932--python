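"""Item-level tallies, additively smoothed estimates, condition proportions.

Free-prompt continuations identify two quantities per item: the
next-mention prior P(NP1) and the overt-pronoun production likelihoods
P('ta' | NPj).  Both are estimated with one pseudo-count per logically
possible (referent, form) cell: with V = 2 candidate referents and W = 3
analyzable forms (name, overt pronoun 'ta', null pronoun),

    prior:       P^(NPj)       = (Count(NPj) + W) / (Count(NP1) + Count(NP2) + V*W)
    likelihood:  P^('ta'|NPj)  = (Count(NPj and 'ta') + 1) / (Count(NPj) + W)

Smoothing keeps every estimate strictly inside (0, 1), so downstream
posterior predictions and cross entropies are always finite.  Observed
pronoun-prompt interpretation proportions are deliberately left
unsmoothed: they are the behavioral target, not a model input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .core_data import (
    CodedDataset,
    Condition,
    Construction,
    FormCode,
    PromptType,
    ReferentCode,
)

__all__ = [
    "SmoothingConfig",
    "ItemCounts",
    "ItemEstimates",
    "ObservedInterpretation",
    "tally_item",
    "smoothed_prior",
    "smoothed_likelihood_ta",
    "estimate_items",
    "observed_interpretations",
    "condition_proportions",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SmoothingConfig:
    """Pseudo-count structure: V candidate referents, W analyzable forms."""

    V: int = 2
    W: int = 3

    def __post_init__(self) -> None:
        if self.V < 2:
            raise ValueError("V must be >= 2 (two candidate referents)")
        if self.W < 1:
            raise ValueError("W must be >= 1")


_FORM_SLOT = {
    FormCode.OVERT_PRONOUN: "ta",
    FormCode.NULL_PRONOUN: "null",
    FormCode.NAME: "name",
}


@dataclass(frozen=True)
class ItemCounts:
    """Raw free-prompt tallies for one (item, condition) cell."""

    item_id: str
    condition: Condition
    count_np1: int = 0
    count_np2: int = 0
    count_np1_ta: int = 0
    count_np2_ta: int = 0
    count_np1_null: int = 0
    count_np2_null: int = 0
    count_np1_name: int = 0
    count_np2_name: int = 0

    def __post_init__(self) -> None:
        if self.count_np1_ta + self.count_np1_null + self.count_np1_name != self.count_np1:
            raise ValueError("NP1 form tallies do not sum to the NP1 total")
        if self.count_np2_ta + self.count_np2_null + self.count_np2_name != self.count_np2:
            raise ValueError("NP2 form tallies do not sum to the NP2 total")
        if min(self.count_np1, self.count_np2) < 0:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class ItemEstimates:
    """Smoothed prior and production likelihoods for one (item, condition)."""

    item_id: str
    condition: Condition
    prior_np1: float
    lik_ta_np1: float
    lik_ta_np2: float

    @property
    def prior_np2(self) -> float:
        return 1.0 - self.prior_np1


@dataclass(frozen=True)
class ObservedInterpretation:
    """Unsmoothed pronoun-prompt NP1 proportion for one (item, condition)."""

    item_id: str
    condition: Condition
    p_obs: float
    n_obs: int


def tally_item(
    free_records: CodedDataset,
    item_id: str | None = None,
    condition: Condition | None = None,
) -> ItemCounts:
    """Tally analyzable free-prompt records of a single (item, condition).

    The input must already have passed :func:`filter_analyzable` and be
    restricted to one item under one free-prompt condition; mixed input is
    a contract violation and raises.  An empty cell yields all-zero counts,
    provided ``item_id`` and ``condition`` identify it.
    """
    keys = {(r.item_id, r.condition) for r in free_records}
    if len(keys) > 1:
        raise ValueError(f"mixed items/conditions in tally input: {sorted(str(k) for k in keys)}")
    if not keys:
        if item_id is None or condition is None:
            raise ValueError("empty cell needs explicit item_id and condition")
        keys = {(item_id, condition)}
    item_id, condition = next(iter(keys))
    if condition.prompt_type is not PromptType.FREE:
        raise ValueError("tally_item expects FREE-prompt records")
    counts = {f"count_np{j}_{slot}": 0 for j in (1, 2) for slot in ("ta", "null", "name")}
    for r in free_records:
        if r.referent not in (ReferentCode.NP1, ReferentCode.NP2):
            raise ValueError("unfiltered record in tally input")
        j = 1 if r.referent is ReferentCode.NP1 else 2
        counts[f"count_np{j}_{_FORM_SLOT[r.form]}"] += 1
    np1 = sum(counts[f"count_np1_{s}"] for s in ("ta", "null", "name"))
    np2 = sum(counts[f"count_np2_{s}"] for s in ("ta", "null", "name"))
    return ItemCounts(item_id=item_id, condition=condition, count_np1=np1, count_np2=np2, **counts)


def smoothed_prior(counts: ItemCounts, cfg: SmoothingConfig = SmoothingConfig()) -> float:
    """Additively smoothed next-mention prior P^(NP1)."""
    return (counts.count_np1 + cfg.W) / (
        counts.count_np1 + counts.count_np2 + cfg.V * cfg.W
    )


def smoothed_likelihood_ta(
    counts: ItemCounts,
    referent: ReferentCode,
    cfg: SmoothingConfig = SmoothingConfig(),
) -> float:
    """Additively smoothed overt-pronoun production likelihood P^('ta'|NPj)."""
    if referent is ReferentCode.NP1:
        return (counts.count_np1_ta + 1) / (counts.count_np1 + cfg.W)
    if referent is ReferentCode.NP2:
        return (counts.count_np2_ta + 1) / (counts.count_np2 + cfg.W)
    raise ValueError(f"likelihood defined only for NP1/NP2, got {referent}")


def estimates_from_counts(
    counts: ItemCounts, cfg: SmoothingConfig = SmoothingConfig()
) -> ItemEstimates:
    return ItemEstimates(
        item_id=counts.item_id,
        condition=counts.condition,
        prior_np1=smoothed_prior(counts, cfg),
        lik_ta_np1=smoothed_likelihood_ta(counts, ReferentCode.NP1, cfg),
        lik_ta_np2=smoothed_likelihood_ta(counts, ReferentCode.NP2, cfg),
    )


def _group_by_cell(data: CodedDataset) -> dict[tuple[str, Condition], list]:
    cells: dict[tuple[str, Condition], list] = {}
    for r in data:
        cells.setdefault((r.item_id, r.condition), []).append(r)
    return cells


def estimate_items(
    free_data: CodedDataset, cfg: SmoothingConfig = SmoothingConfig()
) -> list[ItemEstimates]:
    """Smoothed estimates for every (item, condition) cell in the free-prompt data.

    Record order within the input is irrelevant: estimates are functions of
    counts only.  Output is sorted by (experiment, item, condition) for
    stable downstream tables.
    """
    free_data = free_data.free_prompt()
    out = []
    for (item_id, condition), records in _group_by_cell(free_data).items():
        counts = tally_item(CodedDataset(records))
        out.append(estimates_from_counts(counts, cfg))
    out.sort(key=lambda e: (e.condition.experiment, e.item_id, e.condition.verb_type.value, e.condition.construction.value))
    return out


def observed_interpretations(pronoun_data: CodedDataset) -> list[ObservedInterpretation]:
    """Per-item observed NP1 proportion under the pronoun prompt, unsmoothed.

    Cells with no analyzable records are simply absent from the output.
    """
    pronoun_data = pronoun_data.pronoun_prompt()
    out = []
    for (item_id, condition), records in _group_by_cell(pronoun_data).items():
        n_np1 = sum(1 for r in records if r.referent is ReferentCode.NP1)
        n = len(records)
        out.append(
            ObservedInterpretation(
                item_id=item_id, condition=condition, p_obs=n_np1 / n, n_obs=n
            )
        )
    out.sort(key=lambda o: (o.condition.experiment, o.item_id, o.condition.verb_type.value, o.condition.construction.value))
    return out


_CONDITION_COLS = ["experiment", "verb_type", "prompt_type", "construction"]


def condition_proportions(
    data: CodedDataset,
    by: Sequence[str] = ("experiment", "verb_type", "prompt_type", "construction"),
    per_participant: bool = False,
) -> pd.DataFrame:
    """Descriptive proportions per condition cell, with their counts.

    Returns one row per group with columns:

    ``n``                    analyzable records in the cell
    ``p_np1``                proportion of NP1 first mentions
    ``p_logical_object``     proportion of logical-object mentions (NP2 in
                             actives, NP1 in the bei passive)
    ``p_pronoun_np1/np2``    pronominalization rate given re-mentioned NP,
                             null and overt collapsed
    ``p_overt_given_pronoun_np1/np2``  overt share among pronouns
    ``se_np1``               standard error over by-participant NP1 means
                             (NaN when a single participant)

    With ``per_participant=True`` the grouping additionally includes the
    participant, and only ``n``/``p_np1``/``p_logical_object`` are emitted.
    """
    frame = data.to_frame()
    if frame.empty:
        return pd.DataFrame()
    frame["is_np1"] = frame["referent"] == ReferentCode.NP1.value
    frame["is_logical_object"] = frame["is_np1"] == (
        frame["construction"] == Construction.BEI.value
    )
    frame["is_pronoun"] = frame["form"].isin(
        [FormCode.OVERT_PRONOUN.value, FormCode.NULL_PRONOUN.value]
    )
    frame["is_overt"] = frame["form"] == FormCode.OVERT_PRONOUN.value

    keys = list(by) + (["participant_id"] if per_participant else [])
    rows = []
    for key, g in frame.groupby(keys, sort=True):
        if g.empty:  # pragma: no cover - groupby never yields empty groups
            logger.warning("empty group %s omitted", key)
            continue
        row = dict(zip(keys, key if isinstance(key, tuple) else (key,)))
        row["n"] = len(g)
        row["p_np1"] = g["is_np1"].mean()
        row["p_logical_object"] = g["is_logical_object"].mean()
        if not per_participant:
            for j, mask in (("np1", g["is_np1"]), ("np2", ~g["is_np1"])):
                sub = g[mask]
                row[f"n_{j}"] = len(sub)
                row[f"p_pronoun_{j}"] = sub["is_pronoun"].mean() if len(sub) else float("nan")
                pron = sub[sub["is_pronoun"]]
                row[f"p_overt_given_pronoun_{j}"] = (
                    pron["is_overt"].mean() if len(pron) else float("nan")
                )
            by_part = g.groupby("participant_id")["is_np1"].mean()
            row["se_np1"] = (
                by_part.std(ddof=1) / len(by_part) ** 0.5 if len(by_part) > 1 else float("nan")
            )
        rows.append(row)
    return pd.DataFrame(rows)


def estimates_to_frame(estimates: Iterable[ItemEstimates]) -> pd.DataFrame:
    rows = [
        {
            "experiment": e.condition.experiment,
            "item_id": e.item_id,
            "verb_type": e.condition.verb_type.value,
            "construction": e.condition.construction.value,
            "prior_np1": e.prior_np1,
            "lik_ta_np1": e.lik_ta_np1,
            "lik_ta_np2": e.lik_ta_np2,
        }
        for e in estimates
    ]
    return pd.DataFrame(rows)


def observed_to_frame(observed: Iterable[ObservedInterpretation]) -> pd.DataFrame:
    rows = [
        {
            "experiment": o.condition.experiment,
            "item_id": o.item_id,
            "verb_type": o.condition.verb_type.value,
            "construction": o.condition.construction.value,
            "p_obs": o.p_obs,
            "n_obs": o.n_obs,
        }
        for o in observed
    ]
    return pd.DataFrame(rows)
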