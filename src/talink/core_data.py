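"""Coded passage-completion records: domain types, CSV I/O, exclusion filter.

The unit of observation is one continuation written by one participant for
one item, already coded into closed category vocabularies: which referent
was mentioned first (NP1 = surface subject, NP2 = surface non-subject, or
an unanalyzable code), with which referring-expression form, and optionally
under which coherence relation.  Raw text never enters this package.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

__all__ = [
    "ReferentCode",
    "FormCode",
    "CoherenceCode",
    "VerbType",
    "PromptType",
    "Construction",
    "Condition",
    "ContinuationRecord",
    "CodedDataset",
    "ExclusionReport",
    "SchemaError",
    "ParseError",
    "read_dataset",
    "write_dataset",
    "filter_analyzable",
    "DEFAULT_SCHEMA",
]


class ReferentCode(str, enum.Enum):
    """First-mentioned referent of a continuation (five-way coding)."""

    NP1 = "NP1"
    NP2 = "NP2"
    BOTH = "BOTH"
    UNCLEAR = "UNCLEAR"
    OTHER = "OTHER"


class FormCode(str, enum.Enum):
    """Referring-expression form used for the first mention."""

    NAME = "NAME"
    OVERT_PRONOUN = "OVERT_PRONOUN"
    NULL_PRONOUN = "NULL_PRONOUN"
    OTHER_FORM = "OTHER_FORM"


class CoherenceCode(str, enum.Enum):
    """Coherence relation of the continuation clause to the context clause."""

    EXPLANATION = "EXPLANATION"
    RESULT = "RESULT"
    ELABORATION = "ELABORATION"
    OCCASION = "OCCASION"
    OTHER_REL = "OTHER_REL"
    UNCODED = "UNCODED"


class VerbType(str, enum.Enum):
    """Implicit-causality class: IC1 = subject-biased, IC2 = object-biased."""

    IC1 = "IC1"
    IC2 = "IC2"


class PromptType(str, enum.Enum):
    FREE = "FREE"
    PRONOUN = "PRONOUN"


class Construction(str, enum.Enum):
    """Syntactic construction of the context sentence.

    CANONICAL and BA are actives (NP1 is the logical subject); BEI is the
    Mandarin passive, whose surface subject NP1 is the logical object.
    """

    CANONICAL = "CANONICAL"
    BEI = "BEI"
    BA = "BA"


@dataclass(frozen=True)
class Condition:
    """Experimental cell: verb type x prompt type x syntactic construction."""

    experiment: str
    verb_type: VerbType
    prompt_type: PromptType
    construction: Construction

    def logical_object_is_np1(self) -> bool:
        """In the bei passive the surface subject NP1 is the logical object."""
        return self.construction is Construction.BEI


@dataclass(frozen=True)
class ContinuationRecord:
    participant_id: str
    item_id: str
    condition: Condition
    referent: ReferentCode
    form: FormCode
    coherence: CoherenceCode = CoherenceCode.UNCODED

    def __post_init__(self) -> None:
        if not self.participant_id or not self.item_id:
            raise ValueError("participant_id and item_id must be non-empty")
        if (
            self.condition.prompt_type is PromptType.PRONOUN
            and self.form is not FormCode.OVERT_PRONOUN
        ):
            raise ValueError(
                "pronoun-prompt records must have form=OVERT_PRONOUN "
                "(the prompt supplies the pronoun)"
            )


@dataclass
class CodedDataset:
    """Ordered collection of coded continuations plus a provenance label."""

    records: list[ContinuationRecord] = field(default_factory=list)
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def subset(self, predicate) -> "CodedDataset":
        return CodedDataset(
            records=[r for r in self.records if predicate(r)],
            provenance=self.provenance,
        )

    def free_prompt(self) -> "CodedDataset":
        return self.subset(lambda r: r.condition.prompt_type is PromptType.FREE)

    def pronoun_prompt(self) -> "CodedDataset":
        return self.subset(lambda r: r.condition.prompt_type is PromptType.PRONOUN)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "experiment": r.condition.experiment,
                "participant_id": r.participant_id,
                "item_id": r.item_id,
                "verb_type": r.condition.verb_type.value,
                "prompt_type": r.condition.prompt_type.value,
                "construction": r.condition.construction.value,
                "referent": r.referent.value,
                "form": r.form.value,
                "coherence": r.coherence.value,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=list(DEFAULT_SCHEMA))


# canonical column order of the CSV contract
DEFAULT_SCHEMA: tuple[str, ...] = (
    "experiment",
    "participant_id",
    "item_id",
    "verb_type",
    "prompt_type",
    "construction",
    "referent",
    "form",
    "coherence",
)

_CATEGORY_COLUMNS = {
    "verb_type": VerbType,
    "prompt_type": PromptType,
    "construction": Construction,
    "referent": ReferentCode,
    "form": FormCode,
    "coherence": CoherenceCode,
}


@dataclass(frozen=True)
class ExclusionReport:
    """Accounting of the analyzability filter; totals always conserve."""

    n_total: int
    n_kept: int
    n_excluded_by_reason: Mapping[str, int]

    def __post_init__(self) -> None:
        if self.n_kept + sum(self.n_excluded_by_reason.values()) != self.n_total:
            raise ValueError("exclusion counts do not sum to total")


class SchemaError(ValueError):
    """A required column is missing from the input file."""


class ParseError(ValueError):
    """A cell holds a label outside the closed category vocabulary."""


def _parse_enum(enum_cls, raw: str, column: str, row_number: int):
    try:
        return enum_cls(raw)
    except ValueError:
        valid = ", ".join(m.value for m in enum_cls)
        raise ParseError(
            f"row {row_number}: unknown {column} label {raw!r} "
            f"(expected one of: {valid})"
        ) from None


def read_dataset(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    provenance: str | None = None,
) -> CodedDataset:
    """Read a coded dataset from comma-delimited UTF-8 text.

    Parameters
    ----------
    path
        CSV file with a header row.
    schema
        Optional map from canonical column name to the name used in the
        file, for ingesting externally coded data with different headers.
    provenance
        Label stored on the dataset; defaults to the file path.

    Raises
    ------
    SchemaError
        If a required column is absent.
    ParseError
        If any cell holds a label outside its closed vocabulary; labels
        are never silently coerced.
    """
    path = Path(path)
    colmap = {c: c for c in DEFAULT_SCHEMA}
    if schema:
        colmap.update(schema)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    for canonical, actual in colmap.items():
        if actual not in frame.columns:
            raise SchemaError(f"missing required column {actual!r} ({canonical})")
    records: list[ContinuationRecord] = []
    for pos, row in enumerate(frame.itertuples(index=False), start=2):
        row = row._asdict()
        parsed = {
            col: _parse_enum(cls, row[colmap[col]], col, pos)
            for col, cls in _CATEGORY_COLUMNS.items()
        }
        if parsed["prompt_type"] is PromptType.PRONOUN:
            # the prompt supplies the pronoun; form is not a participant choice
            parsed["form"] = FormCode.OVERT_PRONOUN
        condition = Condition(
            experiment=row[colmap["experiment"]],
            verb_type=parsed["verb_type"],
            prompt_type=parsed["prompt_type"],
            construction=parsed["construction"],
        )
        records.append(
            ContinuationRecord(
                participant_id=row[colmap["participant_id"]],
                item_id=row[colmap["item_id"]],
                condition=condition,
                referent=parsed["referent"],
                form=parsed["form"],
                coherence=parsed["coherence"],
            )
        )
    return CodedDataset(records=records, provenance=provenance or str(path))


def write_dataset(dataset: CodedDataset, path: str | Path) -> Path:
    """Write the dataset as UTF-8 CSV; ``read_dataset`` inverts it."""
    path = Path(path)
    dataset.to_frame().to_csv(path, index=False, encoding="utf-8")
    return path


# reasons keyed referent-first: an unanalyzable referent code trumps form
_REFERENT_REASONS = {
    ReferentCode.BOTH: "referent BOTH",
    ReferentCode.UNCLEAR: "referent UNCLEAR",
    ReferentCode.OTHER: "referent OTHER",
}
_FORM_REASON = "form OTHER_FORM"
EXCLUSION_REASONS = (*_REFERENT_REASONS.values(), _FORM_REASON)


def filter_analyzable(dataset: CodedDataset) -> tuple[CodedDataset, ExclusionReport]:
    """Keep continuations whose first mention is NP1/NP2 in an analyzable form.

    A record is kept iff its referent is NP1 or NP2 AND its form is a name,
    an overt pronoun or a null pronoun.  A record failing on both counts is
    tallied once, under its referent reason.
    """
    kept: list[ContinuationRecord] = []
    reasons = {reason: 0 for reason in EXCLUSION_REASONS}
    for record in dataset.records:
        if record.referent in _REFERENT_REASONS:
            reasons[_REFERENT_REASONS[record.referent]] += 1
        elif record.form is FormCode.OTHER_FORM:
            reasons[_FORM_REASON] += 1
        else:
            kept.append(record)
    report = ExclusionReport(
        n_total=len(dataset.records),
        n_kept=len(kept),
        n_excluded_by_reason=reasons,
    )
    return CodedDataset(records=kept, provenance=dataset.provenance), report
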