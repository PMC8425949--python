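"""Seeded synthetic worlds with ground truth for every pipeline input.

Real inputs to the surveillance pipeline (a taxonomic backbone, seller web
pages in six languages, a shipment ledger, CITES tables, use-and-trade
narratives, a literature list) are either live web resources or large
downloads.  This module generates all of them from one seed, together with a
ground-truth record of every planted fact — which species sits on which
page and year, each shipment's true source and purpose, each narrative's
true uses, each species' true first trade year — so the full pipeline can
be exercised and scored without any download.

Determinism: one pseudo-random stream per generator component, all spawned
from the master seed in a fixed order, so adding records to one component
never perturbs another.  Page noise vocabulary is built from a syllable
pool disjoint from the pools used for genera and epithets, so no noise
bigram can collide with a species keyword and detection ground truth is
unambiguous.  Fixtures exercise logic; they make no claim of statistical
realism about market dynamics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import external_sources, integrate, lemis, taxonomy, temporal, webscan
from .external_sources import EvidenceRecord, UseNarrative
from .lemis import PurposeKeywordTable, ShipmentRecord
from .taxonomy import TaxonConcept, build_keyword_index
from .webscan import LANGUAGES, PageDocument, SiteConfig

__all__ = ["GeneratorSpec", "World", "GroundTruth", "generate_world", "end_to_end_check"]

# Disjoint syllable pools: genera (A), epithets (B), page noise (C).
_GENUS_SYLLABLES = ("ba", "do", "fe", "gi", "ku", "la", "mi", "no")
_EPITHET_SYLLABLES = ("pa", "re", "si", "tu", "ve", "ca", "lo", "den")
_NOISE_SYLLABLES = ("zwo", "wix", "qua", "zyx", "wuz", "zev")

_SELLER_CATEGORY_CYCLE = ("pet", "meat", "medicinal_pharma", "research_zoo", "other")

#: Synthetic trader-name keyword table (the real supplementary keyword list
#: is not public; this stand-in is data, not code, and user-replaceable).
DEFAULT_KEYWORD_ROWS = (
    ("petshop", "pet"),
    ("terrarium", "pet"),
    ("frogmeat", "meat"),
    ("gourmet", "meat"),
    ("pharma", "medicinal_pharma"),
    ("medicinal", "medicinal_pharma"),
    ("university", "research_zoo"),
    ("institute", "research_zoo"),
    ("baitco", "other"),
)


@dataclass(frozen=True)
class GeneratorSpec:
    """All dials of the synthetic world; identical seed + spec gives
    byte-identical output files."""

    seed: int = 0
    n_species: int = 30
    synonym_rate: float = 0.3
    n_sites_per_language: int = 1
    pages_per_site: int = 4
    species_per_page: int = 3
    n_shipments: int = 200
    wild_fraction: float = 0.4
    n_sellers: int = 10
    keyword_coverage: float = 1.0
    n_narratives: int = 10
    negation_rate: float = 0.0
    no_trade_rate: float = 0.2
    n_literature: int = 8
    description_year_range: tuple[int, int] = (1980, 2012)
    trade_year_range: tuple[int, int] = (2004, 2019)
    snapshot_year: int = 2020
    n_recent_species: int = 6
    n_snapshot_only_recent: int = 2
    max_lag: int = 5
    cites_listed_fraction: float = 0.2
    cutoff_year: int = 1999
    plant_synonym_collision: bool = False

    def validate(self) -> None:
        for name in ("synonym_rate", "wild_fraction", "keyword_coverage",
                     "negation_rate", "no_trade_rate", "cites_listed_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_species < self.n_recent_species + self.n_snapshot_only_recent:
            raise ValueError("n_species too small for the requested recent species")
        if self.trade_year_range[0] > self.trade_year_range[1]:
            raise ValueError("empty trade year range")


@dataclass
class GroundTruth:
    """Every planted fact, keyed for direct comparison with pipeline output."""

    page_species: dict[tuple[str, str], set[str]] = field(default_factory=dict)
    page_year: dict[tuple[str, str], int] = field(default_factory=dict)
    shipment_source: list[str] = field(default_factory=list)
    shipment_purpose: list[str] = field(default_factory=list)
    n_wild_shipments: int = 0
    narrative_uses: dict[str, frozenset[str] | None] = field(default_factory=dict)
    literature_species: set[str] = field(default_factory=set)
    source_species: dict[str, set[str]] = field(default_factory=dict)
    first_trade_year: dict[str, int] = field(default_factory=dict)
    planted_lags: dict[str, int] = field(default_factory=dict)
    snapshot_only_species: set[str] = field(default_factory=set)


@dataclass
class World:
    """One synthetic world: in-memory inputs plus their ground truth."""

    spec: GeneratorSpec
    concepts: list[TaxonConcept]
    site_configs: list[SiteConfig]
    pages: list[PageDocument]
    shipments: list[ShipmentRecord]
    keyword_table: PurposeKeywordTable
    cites_checklist: dict[str, str]
    gross_imports_frame: pd.DataFrame
    narratives: list[UseNarrative]
    literature_names: list[str]
    ground_truth: GroundTruth

    @property
    def index(self) -> taxonomy.KeywordIndex:
        return build_keyword_index(self.concepts)


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    """One named child stream per component, spawned in fixed order."""
    root = np.random.SeedSequence(seed)
    names = ("backbone", "plan", "pages", "shipments", "narratives",
             "literature", "cites")
    children = root.spawn(len(names))
    return {name: np.random.default_rng(ss) for name, ss in zip(names, children)}


def _make_word(rng: np.random.Generator, syllables: tuple[str, ...], n: int) -> str:
    return "".join(rng.choice(syllables) for _ in range(n))


def _unique_words(rng, syllables, count, n_syll, taken: set[str]) -> list[str]:
    if count + len(taken) > len(syllables) ** n_syll:
        raise ValueError("syllable pool too small for the requested vocabulary")
    out: list[str] = []
    while len(out) < count:
        w = _make_word(rng, syllables, n_syll)
        if w not in taken:
            taken.add(w)
            out.append(w)
    return out


def _make_backbone(spec: GeneratorSpec, rng: np.random.Generator) -> list[TaxonConcept]:
    taken_g: set[str] = set()
    taken_e: set[str] = set()
    n = spec.n_species
    n_syn = int(round(spec.synonym_rate * n))
    genera = _unique_words(rng, _GENUS_SYLLABLES, max(3, n // 4), 3, taken_g)
    epithets = _unique_words(rng, _EPITHET_SYLLABLES, n + n_syn, 3, taken_e)
    syn_genera = _unique_words(rng, _GENUS_SYLLABLES, max(1, n_syn), 3, taken_g)

    orders = ("Anura", "Caudata", "Gymnophiona")
    iucn_pool = ("LC", "LC", "LC", "NT", "VU", "EN", "CR", "DD", "NE")

    # description years: recent species (post-cutoff) get years that leave
    # room for a planted lag inside the temporal window
    trade_min, trade_max = spec.trade_year_range
    recent_total = spec.n_recent_species + spec.n_snapshot_only_recent
    concepts: list[TaxonConcept] = []
    for i in range(n):
        genus = genera[i % len(genera)].capitalize()
        accepted = f"{genus} {epithets[i]}"
        if i < recent_total:
            lo = max(spec.cutoff_year + 1, trade_min)
            hi = trade_max - spec.max_lag
            year = int(rng.integers(lo, hi + 1))
        else:
            year = int(rng.integers(spec.description_year_range[0],
                                    min(spec.description_year_range[1], spec.cutoff_year) + 1))
        synonyms: frozenset[str] = frozenset()
        if i < n_syn:
            syn = f"{syn_genera[i % len(syn_genera)].capitalize()} {epithets[n + i]}"
            synonyms = frozenset({syn})
        concepts.append(
            TaxonConcept(
                accepted_name=accepted,
                synonyms=synonyms,
                order_name=orders[i % 3],
                family_name=f"{genus}idae",
                year_described=year,
                iucn_category=str(rng.choice(iucn_pool)),
            )
        )
    if spec.plant_synonym_collision and len(concepts) >= 2 and concepts[0].synonyms:
        shared = next(iter(concepts[0].synonyms))
        c1 = concepts[1]
        concepts[1] = TaxonConcept(
            accepted_name=c1.accepted_name,
            synonyms=c1.synonyms | {shared},
            order_name=c1.order_name,
            family_name=c1.family_name,
            year_described=c1.year_described,
            iucn_category=c1.iucn_category,
        )
    return concepts


def _listed_name(rng, concept: TaxonConcept) -> str:
    """Accepted name, or one of its synonyms half the time."""
    if concept.synonyms and rng.random() < 0.5:
        return sorted(concept.synonyms)[0]
    return concept.accepted_name


def generate_world(spec: GeneratorSpec, out_dir: str | Path | None = None) -> World:
    """Generate a full synthetic world; optionally write all input files.

    When ``out_dir`` is given, every input is written in exactly the format
    the ingest functions read (backbone CSV, site-config YAML, page text
    files, shipment CSV, keyword-table CSV, CITES checklist and wide-by-year
    gross-imports CSVs, narrative CSV, literature CSV) plus
    ``ground_truth.json``.
    """
    spec.validate()
    rngs = _rngs(spec.seed)
    truth = GroundTruth()

    concepts = _make_backbone(spec, rngs["backbone"])
    by_name = {c.accepted_name: c for c in concepts}
    species = [c.accepted_name for c in concepts]
    recent = species[: spec.n_recent_species]
    snapshot_only = species[
        spec.n_recent_species: spec.n_recent_species + spec.n_snapshot_only_recent
    ]
    truth.snapshot_only_species = set(snapshot_only)

    # --- plan first trade years -------------------------------------------
    plan_rng = rngs["plan"]
    trade_min, trade_max = spec.trade_year_range
    first_year: dict[str, int] = {}
    for sp in recent:
        lag = int(plan_rng.integers(1, spec.max_lag + 1))
        yd = by_name[sp].year_described
        first_year[sp] = yd + lag
        truth.planted_lags[sp] = lag
    for sp in snapshot_only:
        first_year[sp] = spec.snapshot_year
    for sp in species[spec.n_recent_species + spec.n_snapshot_only_recent:]:
        first_year[sp] = int(plan_rng.integers(trade_min, trade_max + 1))
    truth.first_trade_year = dict(first_year)

    # --- sites and pages ---------------------------------------------------
    pages_rng = rngs["pages"]
    site_configs: list[SiteConfig] = []
    pages: list[PageDocument] = []
    online_species: set[str] = set()
    noise_pool = _unique_words(pages_rng, _NOISE_SYLLABLES, 40, 3, set())

    temporal_species = [sp for sp in species if sp not in snapshot_only]
    # anchor each non-snapshot-only species at exactly its first trade year
    anchors: dict[int, list[str]] = {}
    for sp in temporal_species:
        anchors.setdefault(first_year[sp], []).append(sp)

    site_no = 0
    temporal_sites: list[str] = []
    snapshot_sites: list[str] = []
    for lang in LANGUAGES:
        for _ in range(spec.n_sites_per_language):
            site_id = f"{lang}{site_no:02d}"
            snapshot_site = site_no % 2 == 0
            site_configs.append(
                SiteConfig(
                    site_id=site_id,
                    language=lang,
                    site_type=("commercial" if snapshot_site else "classifieds"),
                    collection_method="single_page" if snapshot_site else "page_cycle",
                    listing_order="unclear",
                    request_delay_s=10.0,
                    max_pages=spec.pages_per_site,
                )
            )
            (snapshot_sites if snapshot_site else temporal_sites).append(site_id)
            site_no += 1

    # temporal pages cover every year of the window at least once, so every
    # anchor year has a page; extra slots recycle the window
    n_years = trade_max - trade_min + 1
    n_temporal_pages = max(len(temporal_sites) * spec.pages_per_site, n_years)
    page_assignments: list[tuple[str, int, list[str]]] = [
        (temporal_sites[j % len(temporal_sites)], trade_min + (j % n_years), [])
        for j in range(n_temporal_pages)
    ]
    snapshot_start = len(page_assignments)
    for site_id in snapshot_sites:
        for _ in range(spec.pages_per_site):
            page_assignments.append((site_id, spec.snapshot_year, []))
    snapshot_idx = list(range(snapshot_start, len(page_assignments)))

    year_to_pages: dict[int, list[int]] = {}
    for i, (_, year, _) in enumerate(page_assignments[:snapshot_start]):
        year_to_pages.setdefault(year, []).append(i)
    for year in sorted(anchors):
        targets = year_to_pages[year]
        for k, sp in enumerate(anchors[year]):
            page_assignments[targets[k % len(targets)]][2].append(sp)
    for k, sp in enumerate(sorted(snapshot_only)):
        page_assignments[snapshot_idx[k % len(snapshot_idx)]][2].append(sp)

    page_counter = 0
    for sid, year, anchor_species in page_assignments:
        eligible = [
            sp
            for sp in species
            if first_year[sp] <= year and not (sp in truth.snapshot_only_species and year != spec.snapshot_year)
        ]
        extra_n = max(0, spec.species_per_page - len(anchor_species))
        extras = (
            [str(s) for s in pages_rng.choice(eligible, size=min(extra_n, len(eligible)), replace=False)]
            if eligible and extra_n
            else []
        )
        chosen = list(dict.fromkeys(anchor_species + extras))
        page_id = f"p{page_counter:04d}"
        page_counter += 1
        fragments = []
        for sp in chosen:
            listed = _listed_name(pages_rng, by_name[sp])
            price = int(pages_rng.integers(5, 250))
            noise = str(pages_rng.choice(noise_pool))
            fragments.append(f"<li><b>{listed}</b> {price}&euro; {noise}</li>")
        filler = " ".join(str(w) for w in pages_rng.choice(noise_pool, size=6))
        raw = f"<html><body><p>{filler}</p><ul>{''.join(fragments)}</ul></body></html>"
        pages.append(PageDocument(site_id=sid, page_id=page_id, year=year, raw_text=raw))
        key = (sid, page_id)
        truth.page_species[key] = set(chosen)
        truth.page_year[key] = year
        online_species.update(chosen)
    truth.source_species["online"] = set(online_species)

    # --- shipments ----------------------------------------------------------
    ship_rng = rngs["shipments"]
    keyword_table = PurposeKeywordTable(
        keyword_to_category=dict(DEFAULT_KEYWORD_ROWS),
        zoo_tokens=frozenset({"zoo"}),
        zoo_registry=frozenset({"municipal zoo garden"}),
    )
    cat_keyword = {
        "pet": "petshop",
        "meat": "frogmeat",
        "medicinal_pharma": "pharma",
        "research_zoo": "university",
        "other": "baitco",
    }
    cat_codes = {
        "pet": "LIV",
        "meat": "BOD",
        "medicinal_pharma": "SPE",
        "research_zoo": "LIV",
        "other": "LIV",
    }
    sellers = [
        (f"seller{j:02d} exports", _SELLER_CATEGORY_CYCLE[j % len(_SELLER_CATEGORY_CYCLE)])
        for j in range(spec.n_sellers)
    ]
    n_wild = int(round(spec.wild_fraction * spec.n_shipments))
    wild_idx = set(
        int(i) for i in ship_rng.choice(spec.n_shipments, size=n_wild, replace=False)
    )
    truth.n_wild_shipments = n_wild
    captive_pool = ("C", "F", "D", "R")

    shipments: list[ShipmentRecord] = []
    lemis_species: set[str] = set()
    seller_record_counter: dict[str, int] = {}
    for i in range(spec.n_shipments):
        seller_name, cat = sellers[i % len(sellers)]
        k = seller_record_counter.get(seller_name, 0)
        seller_record_counter[seller_name] = k + 1
        # snapshot-only species never enter the ledger, and no shipment may
        # precede its species' planted first trade year
        concept = by_name[temporal_species[int(ship_rng.integers(0, len(temporal_species)))]]
        sp = concept.accepted_name
        year = int(ship_rng.integers(max(first_year[sp], trade_min), trade_max + 1))
        lemis_species.add(sp)
        keyworded = k == 0 and spec.keyword_coverage > 0 or ship_rng.random() < spec.keyword_coverage
        if cat == "pet":
            importer = f"{cat_keyword[cat]} retail" if keyworded else "j smith"
            is_individual = not keyworded
            purpose = "T"
        elif cat == "research_zoo":
            importer = f"state {cat_keyword[cat]}" if keyworded else "collection dept"
            is_individual = False
            purpose = "S"
        else:
            importer = f"{cat_keyword[cat]} corp" if keyworded else "import co"
            is_individual = False
            purpose = "T"
        shipments.append(
            ShipmentRecord(
                listed_name=_listed_name(ship_rng, concept),
                genus_field=sp.split(" ")[0],
                description_code=cat_codes[cat],
                source_code="W" if i in wild_idx else str(ship_rng.choice(captive_pool)),
                purpose_code=purpose,
                importer_name=importer,
                exporter_name=seller_name,
                importer_is_individual=is_individual,
                quantity=1,
                year=year,
                seized=False,
            )
        )
        truth.shipment_source.append("wild" if i in wild_idx else "captive")
        truth.shipment_purpose.append(cat)
    truth.source_species["lemis"] = lemis_species

    # --- CITES tables -------------------------------------------------------
    cites_rng = rngs["cites"]
    n_listed = int(round(spec.cites_listed_fraction * spec.n_species))
    listed = sorted(
        str(s) for s in cites_rng.choice(temporal_species, size=min(n_listed, len(temporal_species)), replace=False)
    )
    checklist = {sp.lower(): ("I" if j % 5 == 0 else "II") for j, sp in enumerate(listed)}
    gi_years = list(range(trade_min, trade_max + 1))
    gi_rows = []
    cites_species: set[str] = set()
    for sp in listed:
        cites_species.add(sp)
        row: dict[str, object] = {"App.": checklist[sp.lower()], "Taxon": sp, "Term": "live", "Country": "US"}
        start = max(first_year[sp], trade_min)
        for y in gi_years:
            row[str(y)] = int(cites_rng.integers(1, 50)) if y >= start else ""
        gi_rows.append(row)
    gross_imports_frame = pd.DataFrame(
        gi_rows, columns=["App.", "Taxon", "Term", "Country", *map(str, gi_years)]
    )
    truth.source_species["cites"] = cites_species

    # --- narratives ---------------------------------------------------------
    narr_rng = rngs["narratives"]
    templates: list[tuple[str, frozenset[str] | None]] = [
        ("this species is collected for food in local markets", frozenset({"meat"})),
        ("commonly traded as pets in the terrarium hobby", frozenset({"pet"})),
        ("used in traditional medicine across its range", frozenset({"medicinal_pharma"})),
        ("harvested and traded locally for unknown purposes", frozenset({"other"})),
    ]
    negated_templates: list[tuple[str, frozenset[str] | None]] = [
        ("traded as pets but not for food", frozenset({"pet"})),
        ("used for medicine although not collected for food", frozenset({"medicinal_pharma"})),
    ]
    no_trade_template = ("there is no evidence of trade for this species", None)

    narratives: list[UseNarrative] = []
    iucn_species: set[str] = set()
    narrative_candidates = temporal_species[: spec.n_narratives]
    for sp in narrative_candidates:
        r = narr_rng.random()
        if r < spec.no_trade_rate:
            text, uses = no_trade_template
        elif r < spec.no_trade_rate + spec.negation_rate:
            text, uses = negated_templates[int(narr_rng.integers(0, len(negated_templates)))]
        else:
            text, uses = templates[int(narr_rng.integers(0, len(templates)))]
        narratives.append(UseNarrative(listed_name=sp, narrative_text=text))
        truth.narrative_uses[sp] = uses
        if uses is not None:
            iucn_species.add(sp)
    truth.source_species["iucn"] = iucn_species

    # --- literature list ----------------------------------------------------
    lit_rng = rngs["literature"]
    lit_pool = temporal_species
    lit_species = sorted(
        str(s) for s in lit_rng.choice(lit_pool, size=min(spec.n_literature, len(lit_pool)), replace=False)
    )
    literature_names = [_listed_name(lit_rng, by_name[sp]) for sp in lit_species]
    truth.literature_species = set(lit_species)
    truth.source_species["literature"] = set(lit_species)

    world = World(
        spec=spec,
        concepts=concepts,
        site_configs=site_configs,
        pages=pages,
        shipments=shipments,
        keyword_table=keyword_table,
        cites_checklist=checklist,
        gross_imports_frame=gross_imports_frame,
        narratives=narratives,
        literature_names=literature_names,
        ground_truth=truth,
    )
    if out_dir is not None:
        write_world(world, Path(out_dir))
    return world


def write_world(world: World, out_dir: Path) -> dict[str, Path]:
    """Write every input file in the exact formats the ingest modules read."""
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    backbone_rows = [
        {
            "species": c.accepted_name,
            "synonymies": ";".join(sorted(c.synonyms)),
            "order": c.order_name,
            "family": c.family_name,
            "year_described": c.year_described,
            "iucn": c.iucn_category,
        }
        for c in world.concepts
    ]
    paths["backbone"] = out_dir / "backbone.csv"
    pd.DataFrame(backbone_rows).to_csv(paths["backbone"], index=False)

    paths["sites"] = out_dir / "sites.yaml"
    paths["sites"].write_text(
        yaml.safe_dump(
            [
                {
                    "site_id": s.site_id,
                    "language": s.language,
                    "site_type": s.site_type,
                    "collection_method": s.collection_method,
                    "url_keyword_filter": s.url_keyword_filter,
                    "listing_order": s.listing_order,
                    "request_delay_s": s.request_delay_s,
                    "max_pages": s.max_pages,
                }
                for s in world.site_configs
            ],
            sort_keys=False,
        )
    )

    pages_dir = out_dir / "pages"
    for page in world.pages:
        site_dir = pages_dir / page.site_id
        site_dir.mkdir(parents=True, exist_ok=True)
        (site_dir / f"{page.page_id}_{page.year}.html").write_text(
            page.raw_text, encoding="utf-8"
        )
    paths["pages"] = pages_dir

    paths["shipments"] = out_dir / "shipments.csv"
    pd.DataFrame(
        [
            {
                "species": r.listed_name,
                "genus": r.genus_field,
                "description": r.description_code,
                "source": r.source_code,
                "purpose": r.purpose_code,
                "importer": r.importer_name,
                "exporter": r.exporter_name,
                "importer_is_individual": int(r.importer_is_individual),
                "quantity": r.quantity,
                "year": r.year,
                "disposition": "seized" if r.seized else "cleared",
            }
            for r in world.shipments
        ]
    ).to_csv(paths["shipments"], index=False)

    paths["keyword_table"] = out_dir / "keyword_table.csv"
    pd.DataFrame(
        sorted(world.keyword_table.keyword_to_category.items()),
        columns=["keyword", "category"],
    ).to_csv(paths["keyword_table"], index=False)

    paths["cites_checklist"] = out_dir / "cites_checklist.csv"
    pd.DataFrame(
        [{"FullName": k, "CurrentListing": v} for k, v in sorted(world.cites_checklist.items())]
    ).to_csv(paths["cites_checklist"], index=False)

    paths["gross_imports"] = out_dir / "gross_imports.csv"
    world.gross_imports_frame.to_csv(paths["gross_imports"], index=False)

    paths["narratives"] = out_dir / "narratives.csv"
    pd.DataFrame(
        [{"species": n.listed_name, "narrative": n.narrative_text} for n in world.narratives]
    ).to_csv(paths["narratives"], index=False)

    paths["literature"] = out_dir / "literature.csv"
    pd.DataFrame({"species": world.literature_names}).to_csv(paths["literature"], index=False)

    truth = world.ground_truth
    paths["ground_truth"] = out_dir / "ground_truth.json"
    paths["ground_truth"].write_text(
        json.dumps(
            {
                "page_species": {
                    f"{sid}/{pid}": sorted(v) for (sid, pid), v in sorted(truth.page_species.items())
                },
                "shipment_source": truth.shipment_source,
                "shipment_purpose": truth.shipment_purpose,
                "n_wild_shipments": truth.n_wild_shipments,
                "narrative_uses": {
                    k: (sorted(v) if v is not None else None)
                    for k, v in sorted(truth.narrative_uses.items())
                },
                "source_species": {k: sorted(v) for k, v in sorted(truth.source_species.items())},
                "first_trade_year": dict(sorted(truth.first_trade_year.items())),
                "planted_lags": dict(sorted(truth.planted_lags.items())),
                "snapshot_only_species": sorted(truth.snapshot_only_species),
            },
            indent=1,
            sort_keys=True,
        )
    )
    return paths


def end_to_end_check(world: World) -> dict[str, float]:
    """Run the full pipeline on a synthetic world and score it against the
    planted ground truth.

    Reports page-level species detection recall and precision, the error of
    the recovered wild percentage against the planted wild fraction,
    purpose-classification and narrative-classification accuracy, the
    species-union error against the planted union, and the error of the
    recovered mean description-to-trade lag.  On a noiseless world (full
    keyword coverage, no negations, no conflicts) every rate is 100% and
    every error is zero.
    """
    truth = world.ground_truth
    index = world.index
    lang_of = {s.site_id: s.language for s in world.site_configs}

    # detection on pages
    detections = webscan.scan_pages(world.pages, index, lang_of)
    found: dict[tuple[str, str], set[str]] = {}
    for det in detections:
        found.setdefault((det.site_id, det.page_id), set()).add(det.accepted_name)
    tp = fp = fn = 0
    for key, planted in truth.page_species.items():
        got = found.get(key, set())
        tp += len(got & planted)
        fp += len(got - planted)
        fn += len(planted - got)
    for key, got in found.items():
        if key not in truth.page_species:
            fp += len(got)
    recall = 100.0 * tp / (tp + fn) if tp + fn else 100.0
    precision = 100.0 * tp / (tp + fp) if tp + fp else 100.0

    # shipment source recovery
    units = lemis.filter_individual_units(world.shipments)
    totals = lemis.source_totals(units)
    planted_wild_pct = 100.0 * truth.n_wild_shipments / len(world.shipments)
    recovered_wild_pct = 100.0 * totals["n_wild"] / totals["n_total"]
    wild_pct_error = abs(recovered_wild_pct - planted_wild_pct)

    # purpose classification accuracy
    assignments = lemis.classify_purpose(units, world.keyword_table)
    correct = sum(
        1 for a, t in zip(assignments, truth.shipment_purpose) if a.category == t
    )
    purpose_accuracy = 100.0 * correct / len(assignments) if assignments else 100.0

    # narrative classification accuracy
    narr_correct = 0
    for narrative in world.narratives:
        got = external_sources.classify_use_narrative(narrative)
        if got == truth.narrative_uses[narrative.listed_name]:
            narr_correct += 1
    narrative_accuracy = (
        100.0 * narr_correct / len(world.narratives) if world.narratives else 100.0
    )

    # species union via merge
    evidence = assemble_evidence(world, detections, assignments)
    profiles, unmatched = integrate.merge_sources(evidence, index)
    planted_union = set().union(*truth.source_species.values())
    union_error = abs(len(profiles) - len(planted_union))

    # lag recovery
    trade_years = {name: p.detection_years for name, p in profiles.items()}
    year_described = {
        c.accepted_name: c.year_described for c in world.concepts if c.year_described
    }
    lag = temporal.description_trade_lag(
        trade_years,
        year_described,
        cutoff_year=world.spec.cutoff_year,
        snapshot_year=world.spec.snapshot_year,
    )
    planted_mean = (
        float(np.mean(list(truth.planted_lags.values()))) if truth.planted_lags else float("nan")
    )
    lag_mean_error = abs(lag.mean_lag - planted_mean) if truth.planted_lags else 0.0

    return {
        "detection_recall": recall,
        "detection_precision": precision,
        "wild_pct_error": wild_pct_error,
        "purpose_accuracy": purpose_accuracy,
        "narrative_accuracy": narrative_accuracy,
        "union_species_error": float(union_error),
        "n_unmatched_names": float(len(unmatched)),
        "lag_mean_error": float(lag_mean_error),
        "lag_n_included": float(lag.n_included),
        "lag_n_excluded": float(lag.n_excluded_snapshot_only),
    }


def assemble_evidence(
    world: World,
    detections: list[webscan.DetectionRecord] | None = None,
    assignments: list[lemis.PurposeAssignment] | None = None,
) -> dict[str, list[EvidenceRecord]]:
    """Turn one world's raw inputs into the per-source evidence mapping that
    :func:`tradeweave.integrate.merge_sources` consumes.

    Online detections count as pet-trade evidence; shipment uses come from
    the purpose classifier; narrative species matching a no-trade phrase are
    dropped entirely.
    """
    index = world.index
    lang_of = {s.site_id: s.language for s in world.site_configs}
    if detections is None:
        detections = webscan.scan_pages(world.pages, index, lang_of)
    units = lemis.filter_individual_units(world.shipments)
    if assignments is None:
        assignments = lemis.classify_purpose(units, world.keyword_table)

    evidence: dict[str, list[EvidenceRecord]] = {s: [] for s in integrate.SOURCES}
    for det in detections:
        evidence["online"].append(
            EvidenceRecord(
                listed_name=det.accepted_name,
                source="online",
                uses=frozenset({"pet"}),
                year=det.year,
            )
        )
    for rec, asg in zip(units, assignments):
        evidence["lemis"].append(
            EvidenceRecord(
                listed_name=rec.listed_name,
                source="lemis",
                uses=frozenset({asg.category}) if asg.category else frozenset(),
                year=rec.year or None,
            )
        )
    gross = external_sources.load_gross_imports_frame(
        world.gross_imports_frame, checklist=world.cites_checklist
    )
    for gi in gross:
        evidence["cites"].append(
            EvidenceRecord(
                listed_name=gi.listed_name,
                source="cites",
                uses=frozenset(),
                year=gi.year,
            )
        )
    for narrative in world.narratives:
        uses = external_sources.classify_use_narrative(narrative)
        if uses is None:
            continue  # no-trade species are removed from the listings
        evidence["iucn"].append(
            EvidenceRecord(
                listed_name=narrative.listed_name,
                source="iucn",
                uses=uses,
                year=None,
            )
        )
    lit_records = [
        EvidenceRecord(listed_name=n, source="literature", uses=frozenset({"other"}))
        for n in world.literature_names
    ]
    evidence["literature"] = lit_records
    return evidence
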