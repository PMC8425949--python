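"""CITES tables, IUCN use-and-trade narratives, and literature species lists.

Three further evidence sources feed the species-trade integration:

* the CITES checklist (which taxa carry an Appendix listing) and the CITES
  gross-imports table (reported import quantities per taxon-year, wide by
  year);
* IUCN Red List "Use and Trade" narrative text per species, classified into
  use categories by keyword with a negation window (narratives frequently
  say what a species is *not* traded for);
* a published literature species list, ingested as evidence of trade with
  use category "other".

CITES gross-import rows do not identify the importer entity, so only the
coarse purpose codes are mapped to use categories here.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .taxonomy import KeywordIndex, normalize_binomial, resolve_name

__all__ = [
    "CitesGrossImport",
    "UseNarrative",
    "EvidenceRecord",
    "NO_TRADE_PHRASES",
    "NEGATION_TOKENS",
    "USE_KEYWORDS",
    "classify_use_narrative",
    "join_cites_appendix",
    "load_cites_checklist",
    "load_gross_imports",
    "load_gross_imports_frame",
    "load_narratives",
    "load_literature_list",
    "cites_purpose_to_use",
]


@dataclass(frozen=True)
class CitesGrossImport:
    """One taxon-year-importer gross-import quantity."""

    listed_name: str
    year: int
    term: str
    importer_country: str
    quantity: float
    appendix: str = "none"


@dataclass(frozen=True)
class UseNarrative:
    """Free-text use-and-trade narrative for one listed species."""

    listed_name: str
    narrative_text: str


@dataclass(frozen=True)
class EvidenceRecord:
    """One species-in-trade evidence item from any source."""

    listed_name: str
    source: str
    uses: frozenset[str] = frozenset()
    year: int | None = None


#: Phrases whose presence marks a narrative as reporting no trade at all.
NO_TRADE_PHRASES = (
    "no evidence of trade",
    "not known to be in trade",
    "not in trade",
    "no trade",
    "not utilized",
    "not utilised",
)

#: Negation tokens searched in the window preceding a use keyword.  The
#: window is configurable; per-language equivalents can be appended.
NEGATION_TOKENS = frozenset({"not", "no", "never", "non", "nicht", "kein", "pas", "sin"})

#: Narrative keyword -> use category.
USE_KEYWORDS: Mapping[str, str] = {
    "food": "meat",
    "meat": "meat",
    "consumption": "meat",
    "eaten": "meat",
    "pet": "pet",
    "pets": "pet",
    "terrarium": "pet",
    "medicine": "medicinal_pharma",
    "medicinal": "medicinal_pharma",
    "pharmaceutical": "medicinal_pharma",
    "pharmacological": "medicinal_pharma",
}

#: Words that signal the narrative discusses trade even without a category
#: keyword.
_TRADE_TOKENS = frozenset({"trade", "traded", "trading", "sold", "sale", "harvested", "collected", "exported", "export", "use", "used", "utilized", "utilised"})

_TOKEN = re.compile(r"[^\W\d_]+")


def classify_use_narrative(
    narrative: UseNarrative,
    negation_window: int = 3,
    negation_tokens: frozenset[str] = NEGATION_TOKENS,
    use_keywords: Mapping[str, str] | None = None,
) -> frozenset[str] | None:
    """Classify a use-and-trade narrative into use categories.

    Returns a frozenset of use categories, or ``None`` when the narrative
    matches a no-trade phrase (never both).  A use keyword is suppressed
    when a negation token occurs within ``negation_window`` tokens before
    it ("traded as pets but not for food" keeps pet, drops meat).  Trade
    stated without any category keyword classifies as {"other"}.
    """
    text = narrative.narrative_text.lower()
    kws = dict(USE_KEYWORDS if use_keywords is None else use_keywords)

    tokens = _TOKEN.findall(text)
    uses: set[str] = set()
    for i, tok in enumerate(tokens):
        cat = kws.get(tok)
        if cat is None:
            continue
        window = tokens[max(0, i - negation_window): i]
        if any(w in negation_tokens for w in window):
            continue
        uses.add(cat)

    if not uses and any(phrase in text for phrase in NO_TRADE_PHRASES):
        return None
    if uses:
        return frozenset(uses)
    if set(tokens) & _TRADE_TOKENS:
        return frozenset({"other"})
    return None


def load_narratives(path: str | Path) -> list[UseNarrative]:
    """Two-column CSV (species, narrative) -> UseNarratives."""
    frame = pd.read_csv(path, dtype=str).fillna("")
    name_col, text_col = frame.columns[:2]
    return [
        UseNarrative(listed_name=row[name_col], narrative_text=row[text_col])
        for _, row in frame.iterrows()
    ]


def load_cites_checklist(path: str | Path) -> dict[str, str]:
    """CITES checklist CSV -> {normalised listed name: appendix}.

    Expects the Index_of_CITES_Species column style: a full-name column
    (binomial or trinomial) and a current-listing/appendix column.
    """
    frame = pd.read_csv(path, dtype=str).fillna("")
    cols = {c.lower().strip(): c for c in frame.columns}
    name_col = next(
        (cols[k] for k in ("fullname", "full name", "scientific name", "species", "taxon") if k in cols),
        frame.columns[0],
    )
    app_col = next(
        (cols[k] for k in ("currentlisting", "current listing", "appendix", "listing") if k in cols),
        frame.columns[-1],
    )
    out: dict[str, str] = {}
    for _, row in frame.iterrows():
        name = normalize_binomial(str(row[name_col]))
        app = str(row[app_col]).strip().upper().replace("APPENDIX", "").strip()
        # a taxon listed on several appendices keeps the strictest one
        app = app.split("/")[0].strip()
        if app in {"I", "II", "III"} and name:
            prev = out.get(name)
            if prev is None or ("I", "II", "III").index(app) < ("I", "II", "III").index(prev):
                out[name] = app
    return out


def _leading_binomial(name: str) -> str:
    parts = normalize_binomial(name).split(" ")
    return " ".join(parts[:2])


def join_cites_appendix(
    species: Iterable[str],
    checklist: Mapping[str, str],
) -> tuple[dict[str, str], dict[str, float | int]]:
    """Join a species set against the CITES checklist.

    Checklist entries listed as trinomials match queries on their leading
    binomial.  Returns ``(per-species appendix, coverage stats)`` where
    unlisted species get appendix "none"; coverage = listed / total
    (reported as 0 over 0 for an empty set, never a division error).
    """
    binomial_checklist: dict[str, str] = {}
    for name, app in sorted(checklist.items()):
        key = _leading_binomial(name)
        prev = binomial_checklist.get(key)
        if prev is None or ("I", "II", "III").index(app) < ("I", "II", "III").index(prev):
            binomial_checklist[key] = app

    appendix: dict[str, str] = {}
    for sp in species:
        appendix[sp] = binomial_checklist.get(_leading_binomial(sp), "none")
    n_total = len(appendix)
    n_listed = sum(1 for a in appendix.values() if a != "none")
    stats = {
        "n_listed": n_listed,
        "n_total": n_total,
        "pct_listed": 100.0 * n_listed / n_total if n_total else 0.0,
    }
    return appendix, stats


def load_gross_imports(
    path: str | Path,
    checklist: Mapping[str, str] | None = None,
) -> list[CitesGrossImport]:
    """CITES gross-imports CSV (wide by year) -> long records.

    Expects columns App./Taxon/Term/Unit/Country followed by year columns;
    appendix comes from the checklist join when provided, else from the
    table's own App. column, else "none".
    """
    frame = pd.read_csv(path, dtype=str).fillna("")
    return load_gross_imports_frame(frame, checklist=checklist)


def load_gross_imports_frame(
    frame: pd.DataFrame,
    checklist: Mapping[str, str] | None = None,
) -> list[CitesGrossImport]:
    """Melt an already-loaded wide-by-year gross-imports table to records."""
    frame = frame.astype(str).replace("nan", "").fillna("")
    year_cols = [c for c in frame.columns if re.fullmatch(r"\d{4}", str(c).strip())]
    cols = {c.lower().strip(): c for c in frame.columns}
    taxon_col = next((cols[k] for k in ("taxon", "species", "fullname") if k in cols), frame.columns[0])
    term_col = cols.get("term", None)
    country_col = next((cols[k] for k in ("country", "importer") if k in cols), None)
    app_col = next((cols[k] for k in ("app.", "app", "appendix") if k in cols), None)

    records: list[CitesGrossImport] = []
    for _, row in frame.iterrows():
        name = str(row[taxon_col]).strip()
        if not name:
            continue
        if checklist is not None:
            appendix = join_cites_appendix([name], checklist)[0][name]
        elif app_col:
            raw = str(row[app_col]).strip().upper()
            appendix = raw if raw in {"I", "II", "III"} else "none"
        else:
            appendix = "none"
        for yc in year_cols:
            cell = str(row[yc]).strip().replace(",", "")
            if not cell:
                continue
            records.append(
                CitesGrossImport(
                    listed_name=name,
                    year=int(yc),
                    term=str(row[term_col]).strip() if term_col else "",
                    importer_country=str(row[country_col]).strip() if country_col else "",
                    quantity=float(cell),
                    appendix=appendix,
                )
            )
    return records


#: Coarse CITES purpose code -> use category (gross imports carry no
#: importer identity, so this is the whole mapping).
_CITES_PURPOSE_TO_USE: Mapping[str, str] = {
    "T": "pet",
    "P": "pet",
    "M": "medicinal_pharma",
    "S": "research_zoo",
    "Z": "research_zoo",
    "B": "research_zoo",
    "E": "research_zoo",
}


def cites_purpose_to_use(purpose_code: str) -> str:
    """Map a coarse CITES purpose code to a use category ("other" when
    unmapped)."""
    return _CITES_PURPOSE_TO_USE.get(purpose_code.strip().upper(), "other")


def load_literature_list(
    path: str | Path,
    index: KeywordIndex,
) -> tuple[list[EvidenceRecord], list[str]]:
    """One-column CSV of species names from the literature.

    Every record is tagged source="literature", use="other" (literature
    collations enter the total analysis only).  Returns
    ``(resolved evidence records, unmatched names)``.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8").strip()
    if not text:
        return [], []
    frame = pd.read_csv(path, dtype=str).fillna("")
    names = [str(v).strip() for v in frame.iloc[:, 0] if str(v).strip()]
    records: list[EvidenceRecord] = []
    unmatched: list[str] = []
    seen: set[str] = set()
    for name in names:
        accepted = resolve_name(name, index)
        if accepted is None:
            unmatched.append(name)
        elif accepted not in seen:
            seen.add(accepted)
            records.append(
                EvidenceRecord(
                    listed_name=accepted,
                    source="literature",
                    uses=frozenset({"other"}),
                    year=None,
                )
            )
    return records, unmatched
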