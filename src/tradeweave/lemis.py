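"""Shipment-ledger filtering and classification (LEMIS-style records).

The US Fish & Wildlife Service's LEMIS ledger records wildlife shipments
with coded item descriptions (what the item physically is), source codes
(wild-taken vs captive provenance) and purpose codes (transaction intent).
This module filters a ledger down to items representing single individual
animals, classifies each record's source and commerciality from the codes,
runs the staged purpose classifier (trader-name keywords, seller
propagation, dead-specimen resolution, individual-importer default), and
summarises wild-sourcing per genus and overall.

All volume summaries weight by the quantity field; species-level counting
happens downstream after backbone resolution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "INDIVIDUAL_UNIT_CODES",
    "DEAD_PATHWAY_CODES",
    "LIVE_PATHWAY_CODES",
    "WILD_SOURCE_CODES",
    "CAPTIVE_SOURCE_CODES",
    "NONCOMMERCIAL_PURPOSE_CODES",
    "GENUS_EXCLUSIONS",
    "USE_CATEGORIES",
    "ShipmentRecord",
    "PurposeKeywordTable",
    "PurposeAssignment",
    "load_shipments",
    "load_keyword_table",
    "filter_individual_units",
    "classify_source",
    "classify_commercial",
    "classify_purpose",
    "genus_wild_summary",
    "source_totals",
    "format_percentage",
]

#: Item description codes that represent exactly one individual animal:
#: whole dead animal, live eggs, dead specimen, live specimen, specimen,
#: whole skin, entire animal trophy.
INDIVIDUAL_UNIT_CODES = frozenset({"BOD", "EGL", "DEA", "LIV", "SPE", "SKI", "TRO"})

#: Live/dead split used by the purpose classifier.  SPE (unspecified
#: specimen) is treated as dead-pathway; declared in config, not hard-wired
#: into callers.
DEAD_PATHWAY_CODES = frozenset({"BOD", "DEA", "SKI", "TRO", "SPE"})
LIVE_PATHWAY_CODES = frozenset({"LIV", "EGL"})

WILD_SOURCE_CODES = frozenset({"W"})
#: Captive provenance: bred in captivity (C, F), commercially bred (D),
#: ranched (R).
CAPTIVE_SOURCE_CODES = frozenset({"C", "F", "D", "R"})

#: Non-commercial purposes: biomedical research (M), scientific (S),
#: reintroduction into the wild (Y).
NONCOMMERCIAL_PURPOSE_CODES = frozenset({"M", "S", "Y"})

#: genus_field values that are not genera and are excluded from per-genus
#: summaries; extensible via config.
GENUS_EXCLUSIONS = frozenset({"Non-CITES entry", "Anura", "Bufonidae", "Tadpole"})

USE_CATEGORIES = ("pet", "meat", "medicinal_pharma", "research_zoo", "other")

#: Deterministic tie-break when one record's trader names hit keywords of
#: different categories.
_CATEGORY_PRIORITY = ("medicinal_pharma", "meat", "pet", "research_zoo", "other")


@dataclass(frozen=True)
class ShipmentRecord:
    """One ledger row.  Codes are upper-cased on load; quantity counts
    individuals."""

    listed_name: str
    genus_field: str
    description_code: str
    source_code: str
    purpose_code: str
    importer_name: str = ""
    exporter_name: str = ""
    importer_is_individual: bool = False
    quantity: int = 0
    year: int = 0
    seized: bool = False

    def __post_init__(self) -> None:
        if self.quantity < 0:
            raise ValueError(f"negative quantity on {self.listed_name!r}")
        for fld in ("description_code", "source_code", "purpose_code"):
            val = getattr(self, fld)
            if val != val.upper():
                object.__setattr__(self, fld, val.upper())


@dataclass(frozen=True)
class PurposeKeywordTable:
    """Trader-name keywords -> use category, plus the zoo handling flags.

    ``zoo_tokens`` are suggestive: a trader whose name carries one but who
    is not in ``zoo_registry`` (genuine zoos/aquaria) is classed as a pet
    trader; registry members are research_zoo.
    """

    keyword_to_category: Mapping[str, str]
    zoo_tokens: frozenset[str] = frozenset({"zoo"})
    zoo_registry: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for kw, cat in self.keyword_to_category.items():
            if kw != kw.lower():
                raise ValueError(f"keyword not lower-cased: {kw!r}")
            if cat not in USE_CATEGORIES:
                raise ValueError(f"unknown category {cat!r} for keyword {kw!r}")


@dataclass(frozen=True)
class PurposeAssignment:
    """Per-record outcome of the staged purpose classifier."""

    category: str | None
    provenance: str  # keyword | seller_propagated | dead_default | individual_default | unresolved


def _norm_entity(name: str) -> str:
    """Seller/buyer identity: case-folded, whitespace-collapsed exact string."""
    return " ".join(name.split()).casefold()


def load_shipments(path: str | Path) -> list[ShipmentRecord]:
    """Read a LEMIS-compatible CSV into ShipmentRecords.

    Expected columns: species, genus, description, source, purpose,
    importer, exporter, importer_is_individual, quantity, year, disposition
    (rows with disposition ``seized`` carry the seized flag).
    """
    frame = pd.read_csv(path, dtype=str).fillna("")
    records = []
    for row in frame.itertuples(index=False):
        d = row._asdict()
        records.append(
            ShipmentRecord(
                listed_name=d.get("species", ""),
                genus_field=d.get("genus", ""),
                description_code=d.get("description", "").upper(),
                source_code=d.get("source", "").upper(),
                purpose_code=d.get("purpose", "").upper(),
                importer_name=d.get("importer", ""),
                exporter_name=d.get("exporter", ""),
                importer_is_individual=str(d.get("importer_is_individual", "")).strip().lower()
                in {"1", "true", "yes", "y"},
                quantity=int(float(d["quantity"])) if d.get("quantity", "") != "" else 0,
                year=int(float(d["year"])) if d.get("year", "") != "" else 0,
                seized=str(d.get("disposition", "")).strip().lower() == "seized",
            )
        )
    return records


def load_keyword_table(path: str | Path) -> PurposeKeywordTable:
    """Read a two-column (keyword, category) CSV keyword table."""
    frame = pd.read_csv(path, dtype=str)
    mapping = {
        str(k).strip().lower(): str(c).strip()
        for k, c in zip(frame["keyword"], frame["category"])
    }
    return PurposeKeywordTable(keyword_to_category=mapping)


def filter_individual_units(
    records: Iterable[ShipmentRecord],
    unit_codes: frozenset[str] = INDIVIDUAL_UNIT_CODES,
) -> list[ShipmentRecord]:
    """Keep exactly the records whose description code is a single-individual
    unit (BOD, EGL, DEA, LIV, SPE, SKI, TRO by default)."""
    return [r for r in records if r.description_code in unit_codes]


def classify_source(record: ShipmentRecord) -> str:
    """W -> wild; C/F/D/R -> captive; anything else (incl. blank) ->
    other_ambiguous."""
    if record.source_code in WILD_SOURCE_CODES:
        return "wild"
    if record.source_code in CAPTIVE_SOURCE_CODES:
        return "captive"
    return "other_ambiguous"


def classify_commercial(record: ShipmentRecord) -> str:
    """Purpose codes M/S/Y -> non_commercial; everything else commercial."""
    if record.purpose_code in NONCOMMERCIAL_PURPOSE_CODES:
        return "non_commercial"
    return "commercial"


def _keyword_hit(record: ShipmentRecord, table: PurposeKeywordTable) -> str | None:
    """Stage 1: category from trader-name keywords, with the zoo rule."""
    hits: set[str] = set()
    for name in (record.exporter_name, record.importer_name):
        lowered = _norm_entity(name)
        if not lowered:
            continue
        for kw, cat in table.keyword_to_category.items():
            if kw in lowered:
                hits.add(cat)
        tokens = set(lowered.split())
        if tokens & {t.lower() for t in table.zoo_tokens}:
            if lowered in {_norm_entity(z) for z in table.zoo_registry}:
                hits.add("research_zoo")
            else:
                hits.add("pet")
    if not hits:
        return None
    if len(hits) == 1:
        return next(iter(hits))
    for cat in _CATEGORY_PRIORITY:
        if cat in hits:
            return cat
    return None


def classify_purpose(
    records: Sequence[ShipmentRecord],
    keyword_table: PurposeKeywordTable,
    dead_codes: frozenset[str] = DEAD_PATHWAY_CODES,
) -> list[PurposeAssignment]:
    """Staged purpose classification of unit-filtered records.

    Stages, applied in order per record:

    1. *keyword* — trader-name keyword hits assign a category directly;
       a "zoo" token on an entity absent from the zoo registry assigns pet.
    2. *seller_propagated* — an unassigned record inherits its seller's
       (exporter's) category when that seller's keyword-assigned records are
       unanimous.  Sellers specialise, so unanimity is evidence.
    3. *dead_default* — remaining unassigned records of sellers who ship any
       dead-pathway items resolve to meat, or to medicinal_pharma when a
       medicinal keyword appears anywhere in that seller's records.  Dead
       specimens indicate consumption or medicine.
    4. *individual_default* — remaining records imported by individuals are
       pets, unless the purpose code is research (M or S) -> research_zoo.
    5. *unresolved* — everything else, counted separately.

    Order-independent: seller groups are processed on sorted keys, so a
    permutation of the input yields identical per-record categories.
    """
    records = list(records)
    if not keyword_table.keyword_to_category:
        warnings.warn("empty purpose keyword table: stage 1 skipped", stacklevel=2)

    assignments: list[PurposeAssignment | None] = [None] * len(records)

    # stage 1: direct keyword hits
    stage1: list[str | None] = []
    for i, rec in enumerate(records):
        cat = _keyword_hit(rec, keyword_table) if keyword_table.keyword_to_category else None
        stage1.append(cat)
        if cat is not None:
            assignments[i] = PurposeAssignment(cat, "keyword")

    # group records by normalised seller identity
    by_seller: dict[str, list[int]] = {}
    for i, rec in enumerate(records):
        by_seller.setdefault(_norm_entity(rec.exporter_name), []).append(i)

    medicinal_kws = [
        kw for kw, cat in keyword_table.keyword_to_category.items()
        if cat == "medicinal_pharma"
    ]

    for seller in sorted(by_seller):
        idxs = by_seller[seller]
        seller_cats = {stage1[i] for i in idxs if stage1[i] is not None}
        unassigned = [i for i in idxs if assignments[i] is None]
        if not unassigned:
            continue
        # stage 2: unanimous seller propagation
        if len(seller_cats) == 1 and seller:
            cat = next(iter(seller_cats))
            for i in unassigned:
                assignments[i] = PurposeAssignment(cat, "seller_propagated")
            continue
        # stage 3: sellers shipping dead specimens -> meat or medicinal
        ships_dead = any(records[i].description_code in dead_codes for i in idxs)
        if ships_dead and seller:
            seller_text = " ".join(
                _norm_entity(records[i].exporter_name) + " " + _norm_entity(records[i].importer_name)
                for i in idxs
            )
            cat = (
                "medicinal_pharma"
                if any(kw in seller_text for kw in medicinal_kws)
                else "meat"
            )
            for i in unassigned:
                assignments[i] = PurposeAssignment(cat, "dead_default")

    # stage 4: individual importers default to pets (research codes aside)
    for i, rec in enumerate(records):
        if assignments[i] is None and rec.importer_is_individual:
            if rec.purpose_code in {"M", "S"}:
                assignments[i] = PurposeAssignment("research_zoo", "individual_default")
            else:
                assignments[i] = PurposeAssignment("pet", "individual_default")

    # stage 5: remainder is unresolved, never guessed
    return [
        a if a is not None else PurposeAssignment(None, "unresolved")
        for a in assignments
    ]


def genus_wild_summary(
    records: Iterable[ShipmentRecord],
    exclusions: frozenset[str] = GENUS_EXCLUSIONS,
) -> tuple[pd.DataFrame, float, float]:
    """Per-genus wild-sourcing, plus across-genus mean and median pct_wild.

    Quantity-weighted: ``pct_wild = 100 * n_wild / n_individuals``.  Genera
    whose total quantity is zero, and genus_field values on the exclusion
    list (placeholders like higher taxa), are excluded.  Returns
    ``(frame, mean_pct_wild, median_pct_wild)``.
    """
    totals: dict[str, int] = {}
    wild: dict[str, int] = {}
    for rec in records:
        genus = rec.genus_field.strip()
        if not genus or genus in exclusions:
            continue
        totals[genus] = totals.get(genus, 0) + rec.quantity
        if classify_source(rec) == "wild":
            wild[genus] = wild.get(genus, 0) + rec.quantity
    rows = [
        {
            "genus": g,
            "n_individuals": totals[g],
            "n_wild": wild.get(g, 0),
            "pct_wild": 100.0 * wild.get(g, 0) / totals[g],
        }
        for g in sorted(totals)
        if totals[g] > 0
    ]
    frame = pd.DataFrame(rows, columns=["genus", "n_individuals", "n_wild", "pct_wild"])
    if frame.empty:
        return frame, float("nan"), float("nan")
    return frame, float(frame["pct_wild"].mean()), float(frame["pct_wild"].median())


def format_percentage(proportion: float) -> float:
    """Report-layer rounding: half-to-even to 1 decimal, 2 decimals below 1%.

    Proportions are kept at full precision internally; this mixed precision
    (e.g. 42.3 vs 0.47) only applies at the reporting surface.
    """
    pct = 100.0 * proportion
    decimals = 2 if pct < 1.0 else 1
    return float(np.round(pct, decimals))


def source_totals(records: Iterable[ShipmentRecord]) -> dict[str, float | int]:
    """Quantity-weighted source/commerciality/seizure totals.

    Returns raw counts (which sum exactly: wild + captive + other == total)
    and formatted percentages per :func:`format_percentage`.
    """
    n_total = n_wild = n_captive = n_other = n_commercial = n_nonseized = 0
    for rec in records:
        q = rec.quantity
        n_total += q
        src = classify_source(rec)
        if src == "wild":
            n_wild += q
        elif src == "captive":
            n_captive += q
        else:
            n_other += q
        if classify_commercial(rec) == "commercial":
            n_commercial += q
        if not rec.seized:
            n_nonseized += q
    out: dict[str, float | int] = {
        "n_total": n_total,
        "n_wild": n_wild,
        "n_captive": n_captive,
        "n_other": n_other,
        "n_commercial": n_commercial,
        "n_nonseized": n_nonseized,
    }
    if n_total:
        out.update(
            pct_wild=format_percentage(n_wild / n_total),
            pct_captive=format_percentage(n_captive / n_total),
            pct_other=format_percentage(n_other / n_total),
            pct_commercial=format_percentage(n_commercial / n_total),
            pct_nonseized=format_percentage(n_nonseized / n_total),
        )
    else:
        out.update(
            pct_wild=float("nan"),
            pct_captive=float("nan"),
            pct_other=float("nan"),
            pct_commercial=float("nan"),
            pct_nonseized=float("nan"),
        )
    return out
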