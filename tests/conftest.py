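import pytest

from talink.core_data import (
    CodedDataset,
    CoherenceCode,
    Condition,
    ContinuationRecord,
    Construction,
    FormCode,
    PromptType,
    ReferentCode,
    VerbType,
)


def make_record(
    referent=ReferentCode.NP1,
    form=FormCode.NAME,
    participant="p1",
    item="i1",
    experiment="expt1",
    verb_type=VerbType.IC1,
    prompt=PromptType.FREE,
    construction=Construction.CANONICAL,
    coherence=CoherenceCode.UNCODED,
) -> ContinuationRecord:
    return ContinuationRecord(
        participant_id=participant,
        item_id=item,
        condition=Condition(experiment, verb_type, prompt, construction),
        referent=referent,
        form=form,
        coherence=coherence,
    )


@pytest.fixture
def ten_record_dataset() -> CodedDataset:
    """Hand-enumerable mix: 7 analyzable, one each of BOTH/UNCLEAR/OTHER_FORM."""
    records = [
        make_record(ReferentCode.NP1, FormCode.NAME, participant=f"p{i}")
        for i in range(6)
    ]
    records.append(make_record(ReferentCode.NP2, FormCode.OVERT_PRONOUN, participant="p6"))
    records.append(make_record(ReferentCode.BOTH, FormCode.NAME, participant="p7"))
    records.append(make_record(ReferentCode.UNCLEAR, FormCode.NAME, participant="p8"))
    records.append(make_record(ReferentCode.NP1, FormCode.OTHER_FORM, participant="p9"))
    return CodedDataset(records=records, provenance="fixture")
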