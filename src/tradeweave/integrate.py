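"""Five-source evidence integration into species trade profiles.

Species lists from online detection, shipment ledgers, CITES gross imports,
IUCN narratives and the literature disagree: each source sees a different
slice of the trade, and the same species appears under different synonyms.
This module merges the per-source evidence into one profile per accepted
species (synonym-aware union of sources, uses and first trade years),
partitions the union by source combination (upset analysis), cross-tabulates
IUCN threat status and CITES coverage, and aggregates to country level from
a species-occurrence table.

First trade years come only from dated sources (online, lemis, cites);
evidence from undated sources (IUCN narratives, literature) never imputes a
year.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_DOWN, ROUND_HALF_EVEN
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .external_sources import EvidenceRecord
from .taxonomy import KeywordIndex, resolve_name

__all__ = [
    "SOURCES",
    "DATED_SOURCES",
    "THREATENED_CATEGORIES",
    "SpeciesTradeProfile",
    "merge_sources",
    "intersect_sources",
    "status_crosstab",
    "percent_of_described",
    "national_summary",
    "profiles_to_frame",
]

SOURCES = ("online", "lemis", "cites", "iucn", "literature")
#: Sources whose evidence carries calendar years.
DATED_SOURCES = frozenset({"online", "lemis", "cites"})
THREATENED_CATEGORIES = frozenset({"VU", "EN", "CR"})


@dataclass
class SpeciesTradeProfile:
    """Accumulated trade evidence for one accepted species."""

    accepted_name: str
    sources: set[str] = field(default_factory=set)
    uses: set[str] = field(default_factory=set)
    first_trade_year: int | None = None
    detection_years: set[int] = field(default_factory=set)
    iucn_category: str = "NE"
    cites_appendix: str = "none"
    order_name: str = ""

    @property
    def threatened(self) -> bool:
        return self.iucn_category in THREATENED_CATEGORIES

    @property
    def data_deficient_or_unassessed(self) -> bool:
        return self.iucn_category in {"DD", "NE"}


def merge_sources(
    evidence: Mapping[str, Sequence[EvidenceRecord]],
    index: KeywordIndex,
) -> tuple[dict[str, SpeciesTradeProfile], list[tuple[str, str]]]:
    """Synonym-aware union of per-source evidence into profiles.

    ``evidence`` maps source name -> evidence records.  Listed names are
    resolved against the backbone; a synonym in one source and the accepted
    name in another land on the same profile.  Uses and sources accumulate;
    ``first_trade_year`` is the minimum year over dated-source detections.
    Returns ``(profiles by accepted name, unmatched (source, name) pairs)``.
    """
    profiles: dict[str, SpeciesTradeProfile] = {}
    unmatched: list[tuple[str, str]] = []
    for source in sorted(evidence):
        for rec in evidence[source]:
            accepted = resolve_name(rec.listed_name, index)
            if accepted is None:
                unmatched.append((source, rec.listed_name))
                continue
            prof = profiles.get(accepted)
            if prof is None:
                concept = index.concepts.get(accepted)
                prof = SpeciesTradeProfile(
                    accepted_name=accepted,
                    iucn_category=concept.iucn_category if concept else "NE",
                    cites_appendix=concept.cites_appendix if concept else "none",
                    order_name=concept.order_name if concept else "",
                )
                profiles[accepted] = prof
            prof.sources.add(source)
            prof.uses.update(rec.uses)
            if rec.year is not None and source in DATED_SOURCES:
                prof.detection_years.add(rec.year)
                if prof.first_trade_year is None or rec.year < prof.first_trade_year:
                    prof.first_trade_year = rec.year
    return profiles, unmatched


def intersect_sources(
    profiles: Iterable[SpeciesTradeProfile],
) -> dict[str, object]:
    """Exact partition of the species union by source combination.

    Returns the upset-analysis tables: ``combinations`` maps each non-empty
    source combination (sorted, "+"-joined) to its species count — these
    cells are disjoint and sum to the union size; ``per_source`` gives each
    source's total species and the count unique to it.
    """
    combos: dict[frozenset[str], int] = {}
    per_source_total: dict[str, int] = {}
    per_source_unique: dict[str, int] = {}
    n = 0
    for prof in profiles:
        n += 1
        key = frozenset(prof.sources)
        combos[key] = combos.get(key, 0) + 1
        for s in prof.sources:
            per_source_total[s] = per_source_total.get(s, 0) + 1
        if len(prof.sources) == 1:
            (only,) = prof.sources
            per_source_unique[only] = per_source_unique.get(only, 0) + 1
    return {
        "n_species": n,
        "combinations": {
            "+".join(sorted(k)): v for k, v in sorted(combos.items(), key=lambda kv: sorted(kv[0]))
        },
        "per_source": {
            s: {
                "n_species": per_source_total.get(s, 0),
                "n_unique": per_source_unique.get(s, 0),
            }
            for s in sorted(per_source_total)
        },
    }


def status_crosstab(
    profiles: Iterable[SpeciesTradeProfile],
) -> pd.DataFrame:
    """IUCN status tabulation per stratum (all species, per source, per use).

    Each row carries species counts by flag — threatened (VU, EN, CR),
    Data Deficient, unassessed (NE), CITES-listed — and the corresponding
    percentages of the stratum.
    """
    profs = list(profiles)
    strata: dict[str, list[SpeciesTradeProfile]] = {"all": profs}
    for p in profs:
        for s in sorted(p.sources):
            strata.setdefault(f"source:{s}", []).append(p)
        for u in sorted(p.uses):
            strata.setdefault(f"use:{u}", []).append(p)
    rows = []
    for name in sorted(strata, key=lambda s: (s != "all", s)):
        members = strata[name]
        n = len(members)
        n_thr = sum(1 for p in members if p.threatened)
        n_dd = sum(1 for p in members if p.iucn_category == "DD")
        n_ne = sum(1 for p in members if p.iucn_category == "NE")
        n_cites = sum(1 for p in members if p.cites_appendix != "none")
        rows.append(
            {
                "stratum": name,
                "n_species": n,
                "n_threatened": n_thr,
                "n_dd": n_dd,
                "n_unassessed": n_ne,
                "n_cites_listed": n_cites,
                "pct_threatened": 100.0 * n_thr / n if n else 0.0,
                "pct_not_threatened": 100.0 * (n - n_thr) / n if n else 0.0,
                "pct_dd_or_unassessed": 100.0 * (n_dd + n_ne) / n if n else 0.0,
                "pct_cites_listed": 100.0 * n_cites / n if n else 0.0,
            }
        )
    return pd.DataFrame(rows)


def percent_of_described(
    n_traded: int,
    n_described: int,
    mode: str = "round",
    decimals: int = 2,
) -> float:
    """Share of described species that are in trade, as a percentage.

    ``mode="truncate"`` cuts (never rounds up) at ``decimals`` places;
    ``mode="round"`` rounds half-to-even.  Decimal arithmetic avoids binary
    float artefacts at the cut.
    """
    if n_described <= 0:
        raise ValueError("n_described must be positive")
    pct = Decimal(100) * Decimal(n_traded) / Decimal(n_described)
    quantum = Decimal(1).scaleb(-decimals)
    if mode == "truncate":
        return float(pct.quantize(quantum, rounding=ROUND_DOWN))
    if mode == "round":
        return float(pct.quantize(quantum, rounding=ROUND_HALF_EVEN))
    raise ValueError(f"unknown mode {mode!r}")


def national_summary(
    profiles: Mapping[str, SpeciesTradeProfile],
    occurrence: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """Country-level species-in-trade summary from an occurrence table.

    ``occurrence`` maps accepted species -> country codes; a species
    contributes to every country in its occurrence set.  Countries with no
    occurring species are excluded.  Per country: total species, species in
    trade, percentage traded, traded species that are threatened or
    DD/unassessed, traded species without a CITES listing.
    """
    by_country: dict[str, set[str]] = {}
    for species, countries in occurrence.items():
        for c in countries:
            by_country.setdefault(c, set()).add(species)
    rows = []
    for country in sorted(by_country):
        species = by_country[country]
        traded = {s for s in species if s in profiles}
        n_species = len(species)
        rows.append(
            {
                "country": country,
                "n_species": n_species,
                "n_traded": len(traded),
                "pct_traded": 100.0 * len(traded) / n_species,
                "n_threatened_or_dd_in_trade": sum(
                    1
                    for s in traded
                    if profiles[s].threatened or profiles[s].data_deficient_or_unassessed
                ),
                "n_unlisted_in_trade": sum(
                    1 for s in traded if profiles[s].cites_appendix == "none"
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "country",
            "n_species",
            "n_traded",
            "pct_traded",
            "n_threatened_or_dd_in_trade",
            "n_unlisted_in_trade",
        ],
    )


def profiles_to_frame(profiles: Mapping[str, SpeciesTradeProfile]) -> pd.DataFrame:
    """Profiles as a tidy frame for CSV export (sources/uses ';'-joined)."""
    rows = [
        {
            "accepted_name": p.accepted_name,
            "sources": ";".join(sorted(p.sources)),
            "uses": ";".join(sorted(p.uses)),
            "first_trade_year": p.first_trade_year,
            "iucn_category": p.iucn_category,
            "cites_appendix": p.cites_appendix,
            "order_name": p.order_name,
        }
        for _, p in sorted(profiles.items())
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "accepted_name",
            "sources",
            "uses",
            "first_trade_year",
            "iucn_category",
            "cites_appendix",
            "order_name",
        ],
    )
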