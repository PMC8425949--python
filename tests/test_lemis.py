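"""Shipment filtering, source/commerciality coding, staged purpose
classification, and wild-sourcing summaries."""

from __future__ import annotations

import random

import pytest
from hypothesis import given, settings, strategies as st

from tradeweave.lemis import (
    PurposeKeywordTable,
    ShipmentRecord,
    classify_commercial,
    classify_purpose,
    classify_source,
    filter_individual_units,
    format_percentage,
    genus_wild_summary,
    source_totals,
)


def _rec(**kw) -> ShipmentRecord:
    base = dict(
        listed_name="Hyla alpha",
        genus_field="Hyla",
        description_code="LIV",
        source_code="W",
        purpose_code="T",
        importer_name="import co",
        exporter_name="seller a",
        importer_is_individual=False,
        quantity=1,
        year=2010,
        seized=False,
    )
    base.update(kw)
    return ShipmentRecord(**base)


TABLE = PurposeKeywordTable(
    keyword_to_category={
        "petshop": "pet",
        "frogmeat": "meat",
        "gourmet": "meat",
        "pharma": "medicinal_pharma",
        "university": "research_zoo",
    },
    zoo_registry=frozenset({"municipal zoo garden"}),
)


class TestFilterIndividualUnits:
    def test_live_specimen_retained(self):
        assert filter_individual_units([_rec(description_code="LIV")])

    def test_non_unit_code_excluded(self):
        assert filter_individual_units([_rec(description_code="SHO")]) == []

    def test_hand_counted_fixture(self):
        codes = ["BOD", "EGL", "DEA", "LIV", "SPE", "SKI", "SHO", "GAR", "CAL", "TRO"]
        records = [_rec(description_code=c) for c in codes]
        kept = filter_individual_units(records)
        assert len(kept) == 7
        assert {r.description_code for r in kept} == {
            "BOD", "EGL", "DEA", "LIV", "SPE", "SKI", "TRO"
        }


class TestSourceAndCommercial:
    @pytest.mark.parametrize(
        "code, expected",
        [("W", "wild"), ("C", "captive"), ("F", "captive"), ("D", "captive"),
         ("R", "captive"), ("U", "other_ambiguous"), ("", "other_ambiguous")],
    )
    def test_source_categories(self, code, expected):
        assert classify_source(_rec(source_code=code)) == expected

    @pytest.mark.parametrize(
        "code, expected",
        [("M", "non_commercial"), ("S", "non_commercial"), ("Y", "non_commercial"),
         ("T", "commercial"), ("P", "commercial"), ("", "commercial")],
    )
    def test_commerciality(self, code, expected):
        assert classify_commercial(_rec(purpose_code=code)) == expected


class TestClassifyPurpose:
    def test_stage1_keyword_on_importer(self):
        rec = _rec(description_code="BOD", importer_name="frogmeat trading corp")
        (a,) = classify_purpose([rec], TABLE)
        assert (a.category, a.provenance) == ("meat", "keyword")

    def test_zoo_token_outside_registry_is_pet(self):
        rec = _rec(importer_name="exotic zoo supplies")
        (a,) = classify_purpose([rec], TABLE)
        assert (a.category, a.provenance) == ("pet", "keyword")

    def test_zoo_registry_member_is_research(self):
        rec = _rec(importer_name="Municipal Zoo Garden")
        (a,) = classify_purpose([rec], TABLE)
        assert (a.category, a.provenance) == ("research_zoo", "keyword")

    def test_stage2_unanimous_seller_propagation(self):
        seller = "big exporter ltd"
        keyworded = [
            _rec(exporter_name=seller, importer_name=f"gourmet kitchen {i}",
                 description_code="BOD")
            for i in range(3)
        ]
        blank = _rec(exporter_name=seller, importer_name="no hints here",
                     description_code="LIV")
        assignments = classify_purpose(keyworded + [blank], TABLE)
        assert assignments[3].category == "meat"
        assert assignments[3].provenance == "seller_propagated"

    def test_stage3_conflicting_seller_with_dead_items_resolves_to_meat(self):
        seller = "split seller"
        records = [
            _rec(exporter_name=seller, importer_name="petshop one"),
            _rec(exporter_name=seller, importer_name="gourmet two",
                 description_code="BOD"),
            _rec(exporter_name=seller, importer_name="mystery",
                 description_code="DEA"),
        ]
        assignments = classify_purpose(records, TABLE)
        assert assignments[2].category == "meat"
        assert assignments[2].provenance == "dead_default"

    def test_stage3_prefers_medicinal_when_keyword_present(self):
        seller = "split seller"
        records = [
            _rec(exporter_name=seller, importer_name="petshop one"),
            _rec(exporter_name=seller, importer_name="pharma two",
                 description_code="SPE"),
            _rec(exporter_name=seller, importer_name="mystery",
                 description_code="DEA"),
        ]
        assignments = classify_purpose(records, TABLE)
        assert assignments[2].category == "medicinal_pharma"

    def test_stage4_individual_importer_defaults_to_pet(self):
        rec = _rec(importer_name="jane doe", importer_is_individual=True,
                   purpose_code="T", exporter_name="quiet seller")
        (a,) = classify_purpose([rec], TABLE)
        assert (a.category, a.provenance) == ("pet", "individual_default")

    def test_stage4_individual_with_research_code(self):
        rec = _rec(importer_name="jane doe", importer_is_individual=True,
                   purpose_code="S", exporter_name="quiet seller")
        (a,) = classify_purpose([rec], TABLE)
        assert (a.category, a.provenance) == ("research_zoo", "individual_default")

    def test_stage5_unresolved_counted_separately(self):
        rec = _rec(importer_name="opaque co", exporter_name="quiet seller")
        (a,) = classify_purpose([rec], TABLE)
        assert a.category is None and a.provenance == "unresolved"

    def test_empty_keyword_table_warns_and_skips_stage1(self):
        rec = _rec(importer_name="frogmeat trading corp")
        with pytest.warns(UserWarning, match="empty purpose keyword table"):
            (a,) = classify_purpose([rec], PurposeKeywordTable(keyword_to_category={}))
        assert a.provenance != "keyword"

    def test_order_independence(self):
        records = [
            _rec(exporter_name="s1", importer_name="gourmet a", description_code="BOD"),
            _rec(exporter_name="s1", importer_name="blank", description_code="LIV",
                 listed_name="Hyla beta"),
            _rec(exporter_name="s2", importer_name="petshop b"),
            _rec(exporter_name="s2", importer_name="jane", importer_is_individual=True,
                 listed_name="Hyla gamma"),
            _rec(exporter_name="s3", importer_name="opaque", description_code="DEA",
                 listed_name="Hyla delta"),
        ]
        baseline = {
            (r.listed_name, r.importer_name): a.category
            for r, a in zip(records, classify_purpose(records, TABLE))
        }
        rng = random.Random(7)
        for _ in range(5):
            shuffled = records[:]
            rng.shuffle(shuffled)
            got = {
                (r.listed_name, r.importer_name): a.category
                for r, a in zip(shuffled, classify_purpose(shuffled, TABLE))
            }
            assert got == baseline


class TestGenusWildSummary:
    def test_all_wild_single_genus(self):
        frame, mean, median = genus_wild_summary([_rec(quantity=5), _rec(quantity=2)])
        assert frame.iloc[0]["pct_wild"] == 100.0
        assert mean == 100.0 and median == 100.0

    def test_hand_arithmetic_mean_and_median(self):
        records = [
            _rec(genus_field="A", source_code="W", quantity=10),
            _rec(genus_field="B", source_code="W", quantity=4),
            _rec(genus_field="C", source_code="W", quantity=5),
            _rec(genus_field="C", source_code="C", quantity=5),
        ]
        frame, mean, median = genus_wild_summary(records)
        assert sorted(frame["pct_wild"]) == [50.0, 100.0, 100.0]
        assert mean == pytest.approx(83.33, abs=0.01)
        assert median == 100.0

    def test_zero_quantity_genus_excluded(self):
        frame, mean, median = genus_wild_summary([_rec(genus_field="Z", quantity=0)])
        assert frame.empty

    def test_non_genus_placeholders_excluded(self):
        records = [_rec(genus_field="Non-CITES entry"), _rec(genus_field="Tadpole")]
        frame, _, _ = genus_wild_summary(records)
        assert frame.empty


class TestSourceTotals:
    def test_all_wild(self):
        totals = source_totals([_rec(quantity=10)])
        assert totals["pct_wild"] == 100.0

    def test_printed_ledger_quadruple(self):
        """The published LEMIS 2000-2014 totals reproduce the printed
        percentages: wild 42.3, captive 57.2, other 0.47, commercial 99.6,
        non-seizure 99.9."""
        records = [
            _rec(source_code="W", purpose_code="T", quantity=29_522_128),
            _rec(source_code="C", purpose_code="T", quantity=39_558_750),
            _rec(source_code="C", purpose_code="S", quantity=279_199),
            _rec(source_code="C", purpose_code="T", quantity=83_340, seized=True),
            _rec(source_code="U", purpose_code="T", quantity=328_260),
        ]
        totals = source_totals(records)
        assert totals["n_total"] == 69_771_677
        assert totals["n_wild"] == 29_522_128
        assert totals["n_captive"] == 39_921_289
        assert totals["n_other"] == 328_260
        assert totals["pct_wild"] == 42.3
        assert totals["pct_captive"] == 57.2
        assert totals["pct_other"] == 0.47
        assert totals["pct_commercial"] == 99.6
        assert totals["pct_nonseized"] == 99.9

    def test_generator_ground_truth_fraction(self):
        records = [_rec(source_code="W", quantity=1) for _ in range(400)] + [
            _rec(source_code="C", quantity=1) for _ in range(600)
        ]
        assert source_totals(records)["pct_wild"] == 40.0

    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["W", "C", "F", "D", "R", "U", ""]),
                st.integers(min_value=0, max_value=1000),
            ),
            min_size=1,
            max_size=30,
        )
    )
    @settings(derandomize=True, max_examples=60)
    def test_partition_invariant(self, rows):
        records = [_rec(source_code=s, quantity=q) for s, q in rows]
        totals = source_totals(records)
        assert totals["n_wild"] + totals["n_captive"] + totals["n_other"] == totals["n_total"]


def test_mixed_precision_percentage_formatting():
    assert format_percentage(0.423125) == 42.3
    assert format_percentage(0.0047048) == 0.47
    assert format_percentage(1.0) == 100.0
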