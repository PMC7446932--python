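"""Tallies, additive smoothing, and condition-level descriptive proportions."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from talink.core_data import (
    CodedDataset,
    Condition,
    Construction,
    FormCode,
    PromptType,
    ReferentCode,
    VerbType,
)
from talink.estimation import (
    ItemCounts,
    SmoothingConfig,
    condition_proportions,
    estimate_items,
    observed_interpretations,
    smoothed_likelihood_ta,
    smoothed_prior,
    tally_item,
)

from conftest import make_record

FREE = Condition("expt1", VerbType.IC1, PromptType.FREE, Construction.CANONICAL)


def counts(np1=0, np2=0, np1_ta=0, np2_ta=0, np1_null=0, np2_null=0):
    return ItemCounts(
        item_id="i1",
        condition=FREE,
        count_np1=np1,
        count_np2=np2,
        count_np1_ta=np1_ta,
        count_np2_ta=np2_ta,
        count_np1_null=np1_null,
        count_np2_null=np2_null,
        count_np1_name=np1 - np1_ta - np1_null,
        count_np2_name=np2 - np2_ta - np2_null,
    )


class TestTally:
    def test_hand_counted_example(self):
        records = (
            [make_record(ReferentCode.NP1, FormCode.OVERT_PRONOUN, participant=f"p{i}") for i in range(3)]
            + [make_record(ReferentCode.NP1, FormCode.NAME, participant="p3")]
            + [make_record(ReferentCode.NP2, FormCode.NULL_PRONOUN, participant="p4")]
        )
        c = tally_item(CodedDataset(records))
        assert (c.count_np1, c.count_np2) == (4, 1)
        assert (c.count_np1_ta, c.count_np2_ta) == (3, 0)
        assert (c.count_np1_name, c.count_np2_null) == (1, 1)

    def test_empty_cell_is_all_zeros(self):
        c = tally_item(CodedDataset(), item_id="i1", condition=FREE)
        assert c.count_np1 == c.count_np2 == 0

    def test_all_np2_leaves_np1_zero(self):
        records = [make_record(ReferentCode.NP2, participant=f"p{i}") for i in range(3)]
        c = tally_item(CodedDataset(records))
        assert c.count_np1 == 0 and c.count_np2 == 3

    def test_mixed_items_rejected(self):
        ds = CodedDataset([make_record(item="i1"), make_record(item="i2")])
        with pytest.raises(ValueError, match="mixed"):
            tally_item(ds)

    def test_pronoun_prompt_rejected(self):
        ds = CodedDataset([make_record(prompt=PromptType.PRONOUN, form=FormCode.OVERT_PRONOUN)])
        with pytest.raises(ValueError, match="FREE"):
            tally_item(ds)


class TestSmoothing:
    @pytest.mark.parametrize(
        "np1, np2, expected",
        [(0, 0, 0.5), (14, 0, 17 / 20), (10, 4, 13 / 20)],
    )
    def test_prior_exact_rationals(self, np1, np2, expected):
        assert smoothed_prior(counts(np1=np1, np2=np2)) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "referent, kw, expected",
        [
            (ReferentCode.NP1, dict(np1=0, np1_ta=0), 1 / 3),
            (ReferentCode.NP1, dict(np1=10, np1_ta=5), 6 / 13),
            (ReferentCode.NP2, dict(np2=12, np2_ta=0), 1 / 15),
        ],
    )
    def test_likelihood_exact_rationals(self, referent, kw, expected):
        assert smoothed_likelihood_ta(counts(**kw), referent) == pytest.approx(
            expected, abs=1e-12
        )

    @settings(derandomize=True, max_examples=300)
    @given(
        np1=st.integers(0, 10_000),
        np2=st.integers(0, 10_000),
        ta1=st.integers(0, 10_000),
        ta2=st.integers(0, 10_000),
    )
    def test_estimates_strictly_inside_unit_interval(self, np1, np2, ta1, ta2):
        c = counts(np1=np1 + ta1, np2=np2 + ta2, np1_ta=ta1, np2_ta=ta2)
        cfg = SmoothingConfig()
        for v in (
            smoothed_prior(c, cfg),
            smoothed_likelihood_ta(c, ReferentCode.NP1, cfg),
            smoothed_likelihood_ta(c, ReferentCode.NP2, cfg),
        ):
            assert 0.0 < v < 1.0

    def test_consistency_in_the_large_count_limit(self):
        k = 100_000
        c = counts(np1=10 * k, np2=4 * k, np1_ta=3 * k, np2_ta=1 * k)
        assert abs(smoothed_prior(c) - 10 / 14) < 1e-3
        assert abs(smoothed_likelihood_ta(c, ReferentCode.NP1) - 3 / 10) < 1e-3
        assert abs(smoothed_likelihood_ta(c, ReferentCode.NP2) - 1 / 4) < 1e-3


class TestEstimateItems:
    def test_composition_on_hand_tallied_item(self):
        records = (
            [make_record(ReferentCode.NP1, FormCode.OVERT_PRONOUN, participant=f"p{i}") for i in range(3)]
            + [make_record(ReferentCode.NP1, FormCode.NAME, participant="p3")]
            + [make_record(ReferentCode.NP2, FormCode.NULL_PRONOUN, participant="p4")]
        )
        (est,) = estimate_items(CodedDataset(records))
        assert est.prior_np1 == pytest.approx(7 / 11, abs=1e-12)
        assert est.lik_ta_np1 == pytest.approx(4 / 7, abs=1e-12)
        assert est.lik_ta_np2 == pytest.approx(1 / 4, abs=1e-12)
        assert est.prior_np2 == pytest.approx(4 / 11, abs=1e-12)

    def test_order_invariance(self):
        records = [
            make_record(ReferentCode.NP1, FormCode.OVERT_PRONOUN, participant="p0"),
            make_record(ReferentCode.NP2, FormCode.NAME, participant="p1"),
            make_record(ReferentCode.NP1, FormCode.NULL_PRONOUN, participant="p2"),
        ]
        a = estimate_items(CodedDataset(records))
        b = estimate_items(CodedDataset(records[::-1]))
        assert a == b

    def test_one_estimate_per_item_condition_cell(self):
        records = [
            make_record(item="i1", participant="p0"),
            make_record(item="i2", participant="p0"),
            make_record(item="i1", participant="p1", verb_type=VerbType.IC2),
        ]
        ests = estimate_items(CodedDataset(records))
        assert len(ests) == 3


class TestObservedInterpretations:
    def test_hand_counted_proportion(self):
        records = [
            make_record(
                ReferentCode.NP1 if i < 4 else ReferentCode.NP2,
                FormCode.OVERT_PRONOUN,
                prompt=PromptType.PRONOUN,
                participant=f"p{i}",
            )
            for i in range(5)
        ]
        (obs,) = observed_interpretations(CodedDataset(records))
        assert obs.p_obs == pytest.approx(0.8)
        assert obs.n_obs == 5

    def test_unsmoothed_extremes_allowed(self):
        records = [
            make_record(ReferentCode.NP1, FormCode.OVERT_PRONOUN, prompt=PromptType.PRONOUN, participant=f"p{i}")
            for i in range(3)
        ]
        (obs,) = observed_interpretations(CodedDataset(records))
        assert obs.p_obs == 1.0

    def test_absent_items_omitted(self):
        assert observed_interpretations(CodedDataset()) == []


class TestConditionProportions:
    def test_np1_proportion(self):
        records = [
            make_record(ReferentCode.NP1 if i < 8 else ReferentCode.NP2, participant=f"p{i}")
            for i in range(10)
        ]
        table = condition_proportions(CodedDataset(records))
        assert len(table) == 1
        assert table.iloc[0]["p_np1"] == pytest.approx(0.8)
        assert table.iloc[0]["n"] == 10

    def test_bei_maps_np1_to_logical_object(self):
        records = [
            make_record(ReferentCode.NP1, construction=Construction.BEI, participant=f"p{i}")
            for i in range(3)
        ]
        table = condition_proportions(CodedDataset(records))
        assert table.iloc[0]["p_logical_object"] == pytest.approx(1.0)

    def test_pronominalization_collapses_null_and_overt(self):
        forms = [
            FormCode.OVERT_PRONOUN,
            FormCode.OVERT_PRONOUN,
            FormCode.NULL_PRONOUN,
            FormCode.NAME,
        ]
        records = [
            make_record(ReferentCode.NP1, f, participant=f"p{i}") for i, f in enumerate(forms)
        ]
        table = condition_proportions(CodedDataset(records))
        assert table.iloc[0]["p_pronoun_np1"] == pytest.approx(0.75)
        assert table.iloc[0]["p_overt_given_pronoun_np1"] == pytest.approx(2 / 3)
        assert math.isnan(table.iloc[0]["p_pronoun_np2"])

    def test_participant_means_average_back_to_pooled(self):
        # p1 contributes 2 records, p2 contributes 2: weighted mean of
        # per-participant proportions equals the pooled proportion
        records = [
            make_record(ReferentCode.NP1, participant="p1", item="i1"),
            make_record(ReferentCode.NP2, participant="p1", item="i2"),
            make_record(ReferentCode.NP1, participant="p2", item="i1"),
            make_record(ReferentCode.NP1, participant="p2", item="i2"),
        ]
        pooled = condition_proportions(CodedDataset(records)).iloc[0]
        per_part = condition_proportions(CodedDataset(records), per_participant=True)
        weighted = (per_part["p_np1"] * per_part["n"]).sum() / per_part["n"].sum()
        assert weighted == pytest.approx(pooled["p_np1"])

    def test_empty_input_gives_empty_table(self):
        assert condition_proportions(CodedDataset()).empty
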