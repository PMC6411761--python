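"""Structure and scoring of the 34-item instrument."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bhsii import (
    InstrumentDefinition,
    MissingItemError,
    ResponseSheet,
    ValidationError,
    load_default_instrument,
    score_domain,
    score_sheet,
)
from conftest import make_sheet

DOMAIN_EXPECTATIONS = {
    "P": ("OQ", 12, 48),
    "S": ("OQ", 5, 20),
    "F": ("OQ", 7, 28),
    "V": ("CR", 3, 12),
    "M": ("CR", 7, 28),
}


class TestStructure:
    def test_item_and_section_counts(self, instrument):
        assert len(instrument.items) == 34
        oq = [i for d in instrument.section_domains("OQ") for i in d.items]
        cr = [i for d in instrument.section_domains("CR") for i in d.items]
        assert len(oq) == 24
        assert len(cr) == 10

    @pytest.mark.parametrize("code", list(DOMAIN_EXPECTATIONS))
    def test_domain_layout(self, instrument, code):
        section, n_items, max_raw = DOMAIN_EXPECTATIONS[code]
        domain = instrument.domain(code)
        assert domain.section == section
        assert len(domain.items) == n_items
        assert domain.max_raw == max_raw
        # consecutive numbering within the domain
        assert domain.item_ids == tuple(f"{code}{i}" for i in range(1, n_items + 1))

    def test_total_and_section_maxima(self, instrument):
        assert instrument.total_max_raw == 136
        assert instrument.section_max_raw("OQ") == 96
        assert instrument.section_max_raw("CR") == 40

    def test_likert_bounds(self, instrument):
        assert all(i.min_value == 0 and i.max_value == 4 for i in instrument.items)

    def test_json_round_trip(self, instrument):
        restored = InstrumentDefinition.from_json(instrument.to_json())
        assert restored == instrument

    def test_duplicate_item_rejected(self, instrument):
        domains = instrument.domains
        with pytest.raises(ValidationError, match="duplicate"):
            InstrumentDefinition(name="bad", domains=domains + (domains[0],))


class TestScoring:
    @pytest.mark.parametrize(
        "fill, expected_total",
        [(0, 100.0), (1, 75.0), (4, 0.0)],
    )
    def test_uniform_sheets(self, instrument, fill, expected_total):
        scores = score_sheet(make_sheet(instrument, fill=fill), instrument)
        assert scores.total_score == pytest.approx(expected_total)
        for code in DOMAIN_EXPECTATIONS:
            expected = 100.0 - fill * 100.0 / 4.0
            assert scores.domain_score[code] == pytest.approx(expected)

    def test_pain_domain_midpoint(self, instrument):
        sheet = make_sheet(instrument, fill=0)
        for i in range(1, 13):
            sheet.values[f"P{i}"] = 2
        raw, norm = score_domain(sheet, instrument.domain("P"))
        assert (raw, norm) == (24, pytest.approx(50.0))

    def test_section_formulas(self, instrument):
        # all OQ items at 1, all CR at 3
        sheet = make_sheet(instrument, fill=1)
        for d in instrument.section_domains("CR"):
            for item_id in d.item_ids:
                sheet.values[item_id] = 3
        scores = score_sheet(sheet, instrument)
        assert scores.oq_score == pytest.approx(100 - 24 * 100 / 96)
        assert scores.cr_score == pytest.approx(100 - 30 * 100 / 40)
        assert scores.total_score == pytest.approx(100 - 54 * 100 / 136)

    def test_out_of_range_value_rejected(self, instrument):
        sheet = make_sheet(instrument, fill=0, P1=5)
        with pytest.raises(ValidationError, match="P1"):
            score_sheet(sheet, instrument)

    def test_non_integer_value_rejected(self, instrument):
        sheet = make_sheet(instrument, fill=0)
        sheet.values["S1"] = 1.5
        with pytest.raises(ValidationError, match="S1"):
            score_sheet(sheet, instrument)

    def test_strict_policy_names_missing_item(self, instrument):
        sheet = make_sheet(instrument, fill=2)
        del sheet.values["F3"]
        with pytest.raises(MissingItemError, match="F3"):
            score_sheet(sheet, instrument, missing_policy="strict")

    def test_prorate_substitutes_mean_of_answered(self, instrument):
        sheet = make_sheet(instrument, fill=0)
        # pain: 6 of 12 items answered with 2, six missing -> mean 2 imputed
        for i in range(1, 7):
            sheet.values[f"P{i}"] = 2
        for i in range(7, 13):
            del sheet.values[f"P{i}"]
        raw, norm = score_domain(sheet, instrument.domain("P"), "prorate")
        assert raw == pytest.approx(24.0)
        assert norm == pytest.approx(50.0)

    def test_prorate_undefined_below_half(self, instrument):
        sheet = make_sheet(instrument, fill=1)
        for i in range(1, 3):  # keep only V3 -> 1/3 answered
            del sheet.values[f"V{i}"]
        scores = score_sheet(sheet, instrument, missing_policy="prorate")
        assert math.isnan(scores.domain_score["V"])
        # aggregates containing V undefined, others intact
        assert math.isnan(scores.cr_score)
        assert math.isnan(scores.total_score)
        assert scores.oq_score == pytest.approx(75.0)


@st.composite
def complete_values(draw):
    instrument = load_default_instrument()
    return {
        item_id: draw(st.integers(min_value=0, max_value=4))
        for item_id in instrument.item_ids
    }


class TestScoringProperties:
    @settings(max_examples=50, derandomize=True)
    @given(values=complete_values())
    def test_scores_in_range_and_additive(self, values):
        instrument = load_default_instrument()
        sheet = ResponseSheet("x", "T0", values)
        scores = score_sheet(sheet, instrument)
        all_scores = list(scores.domain_score.values()) + [
            scores.oq_score, scores.cr_score, scores.total_score
        ]
        assert all(0.0 <= s <= 100.0 for s in all_scores)
        assert scores.total_raw == sum(scores.domain_raw.values())
        assert scores.total_raw == sum(values.values())

    @settings(max_examples=30, derandomize=True)
    @given(
        values=complete_values(),
        item_idx=st.integers(min_value=0, max_value=33),
    )
    def test_single_item_increase_strictly_lowers_scores(self, values, item_idx):
        instrument = load_default_instrument()
        item = instrument.items[item_idx]
        if values[item.item_id] == 4:
            values[item.item_id] = 3
        bumped = dict(values)
        bumped[item.item_id] += 1
        lo = score_sheet(ResponseSheet("x", "T0", values), instrument)
        hi = score_sheet(ResponseSheet("x", "T0", bumped), instrument)
        code = item.domain_code
        section_lo = lo.oq_score if code in "PSF" else lo.cr_score
        section_hi = hi.oq_score if code in "PSF" else hi.cr_score
        assert hi.domain_score[code] < lo.domain_score[code]
        assert section_hi < section_lo
        assert hi.total_score < lo.total_score

    @settings(max_examples=20, derandomize=True)
    @given(values=complete_values(), seed=st.integers(0, 2**16))
    def test_permutation_within_domain_invariant(self, values, seed):
        instrument = load_default_instrument()
        rng = np.random.default_rng(seed)
        permuted = dict(values)
        for domain in instrument.domains:
            ids = list(domain.item_ids)
            vals = [values[i] for i in ids]
            rng.shuffle(vals)
            permuted.update(zip(ids, vals))
        a = score_sheet(ResponseSheet("x", "T0", values), instrument)
        b = score_sheet(ResponseSheet("x", "T0", permuted), instrument)
        assert a.domain_score == b.domain_score
        assert a.total_score == b.total_score
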