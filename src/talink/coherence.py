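"""Coherence-relation tables and the mediation decompositions.

Free-prompt continuations coded for coherence relation support three
descriptive views per experimental condition:

* the distribution of relations (restricted by default to Explanation and
  Result, the only relations frequent enough to analyze);
* P(next mention = NP1 | relation) — if a syntactic manipulation's effect
  on next mention is mediated by coherence, this conditional should show
  no construction effect;
* P(relation | next mention) — the converse conditional, which should
  carry the construction effect under mediation.

All tables are empirical proportions with their cell counts, so every
number is re-derivable; no significance testing happens here.
"""

from __future__ import annotations

import logging
from typing import Iterable

import pandas as pd

from .core_data import CodedDataset, CoherenceCode, ReferentCode

__all__ = [
    "DEFAULT_RELATIONS",
    "relation_distribution",
    "next_mention_given_relation",
    "relation_given_next_mention",
]

logger = logging.getLogger(__name__)

DEFAULT_RELATIONS = frozenset({CoherenceCode.EXPLANATION, CoherenceCode.RESULT})

_CONDITION_COLS = ["experiment", "verb_type", "construction"]


def _coded_free_frame(
    data: CodedDataset, restrict: Iterable[CoherenceCode]
) -> pd.DataFrame:
    """Free-prompt records with a relation inside the restriction set."""
    wanted = {CoherenceCode(r).value for r in restrict}
    if CoherenceCode.UNCODED.value in wanted:
        raise ValueError("UNCODED is not an analyzable relation")
    frame = data.free_prompt().to_frame()
    if frame.empty:
        return frame
    frame = frame[frame["coherence"].isin(wanted)].copy()
    frame["next_mention"] = frame["referent"]
    return frame


def relation_distribution(
    data: CodedDataset, restrict: Iterable[CoherenceCode] = DEFAULT_RELATIONS
) -> pd.DataFrame:
    """Proportion of each relation within each condition.

    Records whose relation falls outside ``restrict`` are dropped from the
    denominator, so proportions within a condition sum to one over the
    restricted set.
    """
    frame = _coded_free_frame(data, restrict)
    if frame.empty:
        logger.warning("no coherence-coded free-prompt records; empty table")
        return pd.DataFrame()
    counts = (
        frame.groupby(_CONDITION_COLS + ["coherence"], sort=True)
        .size()
        .rename("count")
        .reset_index()
    )
    counts["proportion"] = counts["count"] / counts.groupby(_CONDITION_COLS)[
        "count"
    ].transform("sum")
    return counts


def next_mention_given_relation(
    data: CodedDataset, restrict: Iterable[CoherenceCode] = DEFAULT_RELATIONS
) -> pd.DataFrame:
    """P(next mention = NP1 | relation, condition), with cell counts.

    Cells with no records are omitted rather than reported as 0/0.
    """
    frame = _coded_free_frame(data, restrict)
    if frame.empty:
        logger.warning("no coherence-coded free-prompt records; empty table")
        return pd.DataFrame()
    grouped = frame.groupby(_CONDITION_COLS + ["coherence"], sort=True)
    out = grouped.agg(
        count=("next_mention", "size"),
        p_np1=("next_mention", lambda s: (s == ReferentCode.NP1.value).mean()),
    ).reset_index()
    return out


def relation_given_next_mention(
    data: CodedDataset, restrict: Iterable[CoherenceCode] = DEFAULT_RELATIONS
) -> pd.DataFrame:
    """P(relation | next mention, condition), with cell counts."""
    frame = _coded_free_frame(data, restrict)
    if frame.empty:
        logger.warning("no coherence-coded free-prompt records; empty table")
        return pd.DataFrame()
    counts = (
        frame.groupby(_CONDITION_COLS + ["next_mention", "coherence"], sort=True)
        .size()
        .rename("count")
        .reset_index()
    )
    counts["proportion"] = counts["count"] / counts.groupby(
        _CONDITION_COLS + ["next_mention"]
    )["count"].transform("sum")
    return counts
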