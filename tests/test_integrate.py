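"""Five-source merging, upset partitioning, status tabulation, and national
summaries."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest

from tradeweave.external_sources import EvidenceRecord
from tradeweave.integrate import (
    SOURCES,
    SpeciesTradeProfile,
    intersect_sources,
    merge_sources,
    national_summary,
    percent_of_described,
    status_crosstab,
)


def _ev(name, source, uses=(), year=None):
    return EvidenceRecord(name, source, frozenset(uses), year)


class TestMergeSources:
    def test_set_union_of_two_sources(self, index):
        evidence = {
            "online": [_ev("Hyla alpha", "online", ["pet"], 2010)],
            "lemis": [_ev("Hyla alpha", "lemis", ["meat"], 2008),
                      _ev("Hyla beta", "lemis", [], 2012)],
        }
        profiles, unmatched = merge_sources(evidence, index)
        assert set(profiles) == {"Hyla alpha", "Hyla beta"}
        assert profiles["Hyla alpha"].sources == {"online", "lemis"}
        assert profiles["Hyla alpha"].uses == {"pet", "meat"}
        assert profiles["Hyla alpha"].first_trade_year == 2008
        assert unmatched == []

    def test_synonym_and_accepted_name_land_on_one_profile(self, index):
        evidence = {
            "online": [_ev("Rana alpha", "online", ["pet"], 2015)],
            "cites": [_ev("Hyla alpha", "cites", [], 2009)],
        }
        profiles, _ = merge_sources(evidence, index)
        assert set(profiles) == {"Hyla alpha"}
        assert profiles["Hyla alpha"].sources == {"online", "cites"}

    def test_all_sources_empty(self, index):
        profiles, unmatched = merge_sources({s: [] for s in SOURCES}, index)
        assert profiles == {} and unmatched == []

    def test_undated_sources_never_set_first_trade_year(self, index):
        evidence = {"iucn": [_ev("Hyla alpha", "iucn", ["meat"], 2001)],
                    "literature": [_ev("Hyla beta", "literature", ["other"])]}
        profiles, _ = merge_sources(evidence, index)
        assert profiles["Hyla alpha"].first_trade_year is None
        assert profiles["Hyla beta"].first_trade_year is None

    def test_unmatched_names_reported(self, index):
        profiles, unmatched = merge_sources(
            {"online": [_ev("Ignotus nemo", "online", [], 2010)]}, index
        )
        assert profiles == {}
        assert unmatched == [("online", "Ignotus nemo")]

    def test_superset_input_is_monotone(self, index):
        small = {"online": [_ev("Hyla alpha", "online", ["pet"], 2010)]}
        big = {
            "online": small["online"] + [_ev("Hyla alpha", "online", [], 2005)],
            "lemis": [_ev("Rana alpha", "lemis", ["meat"], 2012)],
        }
        p_small, _ = merge_sources(small, index)
        p_big, _ = merge_sources(big, index)
        a, b = p_small["Hyla alpha"], p_big["Hyla alpha"]
        assert a.sources <= b.sources
        assert a.uses <= b.uses
        assert b.first_trade_year <= a.first_trade_year


def _profile(name, sources, iucn="LC", appendix="none", uses=()):
    return SpeciesTradeProfile(
        accepted_name=name, sources=set(sources), uses=set(uses),
        iucn_category=iucn, cites_appendix=appendix,
    )


def _brute_force_partition(profiles):
    """Independent oracle: enumerate every source combination and count
    members exactly."""
    source_universe = sorted({s for p in profiles for s in p.sources})
    cells = {}
    for r in range(1, len(source_universe) + 1):
        for combo in combinations(source_universe, r):
            n = sum(1 for p in profiles if set(p.sources) == set(combo))
            if n:
                cells["+".join(combo)] = n
    return cells


class TestIntersectSources:
    def test_single_source(self):
        profiles = [_profile(f"S {i}", ["online"]) for i in range(4)]
        result = intersect_sources(profiles)
        assert result["combinations"] == {"online": 4}
        assert result["per_source"]["online"] == {"n_species": 4, "n_unique": 4}

    def test_three_source_fixture_matches_brute_force(self):
        profiles = [
            _profile("A a", ["online"]),
            _profile("B b", ["online", "lemis"]),
            _profile("C c", ["lemis"]),
            _profile("D d", ["online", "lemis", "cites"]),
            _profile("E e", ["cites"]),
            _profile("F f", ["online", "cites"]),
            _profile("G g", ["online"]),
        ]
        result = intersect_sources(profiles)
        assert result["combinations"] == _brute_force_partition(profiles)

    def test_cells_partition_random_fixtures(self):
        rng = np.random.default_rng(11)
        for trial in range(10):
            n_sources = int(rng.integers(2, 7))
            universe = [f"src{k}" for k in range(n_sources)]
            profiles = []
            for i in range(int(rng.integers(1, 200))):
                k = int(rng.integers(1, n_sources + 1))
                srcs = list(rng.choice(universe, size=k, replace=False))
                profiles.append(_profile(f"Sp {trial} {i}", srcs))
            result = intersect_sources(profiles)
            assert result["combinations"] == _brute_force_partition(profiles)
            assert sum(result["combinations"].values()) == len(profiles)


class TestStatusCrosstab:
    def test_all_least_concern_has_zero_threatened(self):
        frame = status_crosstab([_profile(f"S {i}", ["online"]) for i in range(3)])
        all_row = frame.set_index("stratum").loc["all"]
        assert all_row["n_threatened"] == 0

    def test_hand_tally(self):
        profiles = [
            _profile("A a", ["online"], iucn="VU", uses=["pet"]),
            _profile("B b", ["online"], iucn="LC", uses=["pet"]),
            _profile("C c", ["lemis"], iucn="DD"),
            _profile("D d", ["lemis"], iucn="NE", appendix="II"),
            _profile("E e", ["lemis", "online"], iucn="CR"),
        ]
        frame = status_crosstab(profiles).set_index("stratum")
        assert frame.loc["all", "n_threatened"] == 2
        assert frame.loc["all", "n_dd"] == 1
        assert frame.loc["all", "n_unassessed"] == 1
        assert frame.loc["all", "n_cites_listed"] == 1
        assert frame.loc["source:online", "n_threatened"] == 2
        assert frame.loc["use:pet", "n_species"] == 2

    def test_threatened_percentages_sum_to_100(self):
        profiles = [_profile("A a", ["online"], iucn="VU"),
                    _profile("B b", ["online"], iucn="LC")]
        frame = status_crosstab(profiles)
        for _, row in frame.iterrows():
            assert row["pct_threatened"] + row["pct_not_threatened"] == pytest.approx(100.0)


class TestPercentOfDescribed:
    def test_zero_numerator(self):
        assert percent_of_described(0, 8212) == 0.0

    def test_truncation_never_rounds_up(self):
        assert percent_of_described(909, 8212, mode="truncate", decimals=2) == 11.06

    def test_half_even_rounding(self):
        assert percent_of_described(38, 2747, mode="round", decimals=2) == 1.38

    def test_bad_mode_rejected(self):
        with pytest.raises(ValueError):
            percent_of_described(1, 10, mode="ceiling")


class TestNationalSummary:
    def test_species_counts_in_every_occurrence_country(self):
        profiles = {"Hyla alpha": _profile("Hyla alpha", ["online"])}
        occurrence = {"Hyla alpha": {"TH", "VN"}}
        frame = national_summary(profiles, occurrence).set_index("country")
        assert frame.loc["TH", "n_traded"] == 1
        assert frame.loc["VN", "n_traded"] == 1

    def test_country_with_no_species_excluded(self):
        frame = national_summary({}, {})
        assert frame.empty

    def test_four_country_fixture_hand_enumeration(self):
        profiles = {
            "A a": _profile("A a", ["online"], iucn="VU"),
            "B b": _profile("B b", ["lemis"], iucn="DD", appendix="II"),
            "C c": _profile("C c", ["cites"], iucn="LC"),
        }
        occurrence = {
            "A a": {"TH", "VN"},
            "B b": {"TH"},
            "C c": {"BR"},
            "D d": {"TH", "MG"},  # not traded
        }
        frame = national_summary(profiles, occurrence).set_index("country")
        th = frame.loc["TH"]
        assert (th["n_species"], th["n_traded"]) == (3, 2)
        assert th["pct_traded"] == pytest.approx(100 * 2 / 3)
        assert th["n_threatened_or_dd_in_trade"] == 2  # VU + DD
        assert th["n_unlisted_in_trade"] == 1  # A a lacks an appendix
        assert frame.loc["MG", "n_traded"] == 0
        assert frame.loc["BR", "n_traded"] == 1
        assert frame.loc["VN", "n_species"] == 1
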