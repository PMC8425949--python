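"""Taxonomic backbone: accepted names, synonyms, and keyword resolution.

The species lists produced by every other stage of the pipeline are only
comparable after synonym resolution against a single taxonomic backbone
(an AmphibiaWeb-style table of accepted binomials, their synonyms, higher
taxonomy, description year and IUCN category).  This module loads such a
backbone, builds a case-insensitive keyword index over accepted names and
synonyms, and resolves arbitrary listed names to accepted species.

Matching is exact-binomial only: names are normalised (lower-cased,
whitespace collapsed), trinomials fall back to their leading binomial, and
abbreviations such as ``D. melanostictus`` never match.  Fuzzy matching and
common names are deliberately out of scope.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "IUCN_CATEGORIES",
    "CITES_APPENDICES",
    "TaxonConcept",
    "KeywordIndex",
    "BackboneError",
    "normalize_binomial",
    "load_backbone",
    "build_keyword_index",
    "resolve_name",
    "dedupe_species",
]

IUCN_CATEGORIES = frozenset({"LC", "NT", "VU", "EN", "CR", "EW", "EX", "DD", "NE"})
CITES_APPENDICES = frozenset({"I", "II", "III", "none"})

#: Default column mapping for AmphibiaWeb-style backbone files; override via
#: the ``columns`` argument of :func:`load_backbone` (the pipeline exposes it
#: in the run config).
DEFAULT_COLUMNS: Mapping[str, str] = {
    "accepted_name": "species",
    "synonyms": "synonymies",
    "order_name": "order",
    "family_name": "family",
    "year_described": "year_described",
    "iucn_category": "iucn",
}

_WS = re.compile(r"\s+")


class BackboneError(ValueError):
    """Raised when a backbone file violates a structural invariant."""


@dataclass(frozen=True)
class TaxonConcept:
    """One accepted species with its synonymy and status metadata."""

    accepted_name: str
    synonyms: frozenset[str] = frozenset()
    order_name: str = ""
    family_name: str = ""
    year_described: int | None = None
    iucn_category: str = "NE"
    cites_appendix: str = "none"

    def __post_init__(self) -> None:
        if len(self.accepted_name.split()) != 2:
            raise BackboneError(
                f"accepted name must be a binomial: {self.accepted_name!r}"
            )
        if self.accepted_name in self.synonyms:
            raise BackboneError(
                f"accepted name listed among its own synonyms: {self.accepted_name!r}"
            )
        if self.iucn_category not in IUCN_CATEGORIES:
            raise BackboneError(
                f"unknown IUCN category {self.iucn_category!r} for {self.accepted_name}"
            )
        if self.cites_appendix not in CITES_APPENDICES:
            raise BackboneError(
                f"unknown CITES appendix {self.cites_appendix!r} for {self.accepted_name}"
            )


@dataclass(frozen=True)
class KeywordIndex:
    """Case-insensitive map from binomial keyword to accepted name.

    Keys are normalised binomials (accepted names and synonyms alike); every
    accepted name maps to itself.  A keyword claimed by two accepted species
    is a load error, never an arbitrary assignment.
    """

    keyword_to_accepted: Mapping[str, str]
    concepts: Mapping[str, TaxonConcept] = field(default_factory=dict)

    @property
    def n_keywords(self) -> int:
        return len(self.keyword_to_accepted)

    def keywords(self) -> Iterable[str]:
        return self.keyword_to_accepted.keys()


def normalize_binomial(name: str) -> str:
    """Lower-case, trim, and collapse internal whitespace to single spaces.

    No diacritic folding: scientific names are ASCII by convention.
    """
    return _WS.sub(" ", name.strip()).lower()


def _leading_binomial(normalized: str) -> str:
    """Reduce a trinomial (or longer) to its leading two tokens."""
    parts = normalized.split(" ")
    return " ".join(parts[:2]) if len(parts) > 2 else normalized


def _parse_synonyms(cell: object) -> frozenset[str]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return frozenset()
    text = str(cell).strip()
    if not text or text.lower() in {"nan", "none"}:
        return frozenset()
    parts = re.split(r"[;,|]", text)
    return frozenset(p.strip() for p in parts if p.strip())


def load_backbone(
    path: str | Path,
    columns: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> list[TaxonConcept]:
    """Load an AmphibiaWeb-style delimited backbone file.

    Parameters
    ----------
    path:
        Tab- or comma-delimited text file, one row per accepted species.
    columns:
        Mapping from TaxonConcept field to file column name; defaults to
        :data:`DEFAULT_COLUMNS`.
    sep:
        Field delimiter; sniffed from the extension when omitted
        (``.tsv``/``.txt`` -> tab, else comma).

    Raises
    ------
    BackboneError
        On a missing required column or a duplicate accepted name (the
        duplicate is named); malformed rows are reported with line numbers.
    """
    path = Path(path)
    cols = dict(DEFAULT_COLUMNS)
    if columns:
        cols.update(columns)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    frame = pd.read_csv(path, sep=sep, dtype=str)

    required = {"accepted_name", "order_name", "family_name"}
    missing = [cols[k] for k in sorted(required) if cols[k] not in frame.columns]
    if missing:
        raise BackboneError(f"missing required column(s) in {path.name}: {missing}")

    concepts: list[TaxonConcept] = []
    seen: dict[str, int] = {}
    errors: list[str] = []
    for pos, row in frame.iterrows():
        line_no = int(pos) + 2  # header is line 1
        raw_name = row.get(cols["accepted_name"])
        if raw_name is None or pd.isna(raw_name) or not str(raw_name).strip():
            errors.append(f"line {line_no}: empty accepted name")
            continue
        name = _WS.sub(" ", str(raw_name).strip())
        if len(name.split(" ")) != 2:
            errors.append(f"line {line_no}: accepted name {name!r} is not a binomial")
            continue
        key = name.lower()
        if key in seen:
            raise BackboneError(
                f"duplicate accepted name {name!r} (lines {seen[key]} and {line_no})"
            )
        seen[key] = line_no

        year_raw = row.get(cols["year_described"])
        year: int | None = None
        if year_raw is not None and not pd.isna(year_raw) and str(year_raw).strip():
            try:
                year = int(float(str(year_raw)))
            except ValueError:
                errors.append(f"line {line_no}: bad year {year_raw!r}")
                continue

        iucn_raw = row.get(cols["iucn_category"])
        iucn = str(iucn_raw).strip().upper() if iucn_raw is not None and not pd.isna(iucn_raw) else ""
        synonyms = _parse_synonyms(row.get(cols["synonyms"])) - {name}
        try:
            concepts.append(
                TaxonConcept(
                    accepted_name=name,
                    synonyms=synonyms,
                    order_name=str(row.get(cols["order_name"], "")).strip(),
                    family_name=str(row.get(cols["family_name"], "")).strip(),
                    year_described=year,
                    iucn_category=iucn or "NE",
                    cites_appendix="none",
                )
            )
        except BackboneError as exc:
            errors.append(f"line {line_no}: {exc}")
    if errors:
        raise BackboneError(
            f"{len(errors)} malformed row(s) in {path.name}: " + "; ".join(errors)
        )
    return concepts


def build_keyword_index(concepts: Iterable[TaxonConcept]) -> KeywordIndex:
    """Index accepted names and synonyms as lower-cased binomial keywords.

    Raises
    ------
    BackboneError
        If one keyword is claimed by two accepted species (both claimants
        are named).
    """
    mapping: dict[str, str] = {}
    claimants: dict[str, str] = {}
    collisions: list[str] = []
    by_name: dict[str, TaxonConcept] = {}
    for concept in concepts:
        by_name[concept.accepted_name] = concept
        for keyword in (concept.accepted_name, *sorted(concept.synonyms)):
            norm = normalize_binomial(keyword)
            owner = claimants.get(norm)
            if owner is not None and owner != concept.accepted_name:
                collisions.append(
                    f"{norm!r} claimed by both {owner!r} and {concept.accepted_name!r}"
                )
                continue
            claimants[norm] = concept.accepted_name
            mapping[norm] = concept.accepted_name
    if collisions:
        raise BackboneError("keyword collision(s): " + "; ".join(sorted(collisions)))
    return KeywordIndex(keyword_to_accepted=mapping, concepts=by_name)


def resolve_name(name: str, index: KeywordIndex) -> str | None:
    """Resolve one listed name to its accepted species, or None for no match.

    Exact binomial lookup after normalisation; trinomials resolve via their
    leading binomial; abbreviations (``D. melanostictus``) never match.
    """
    norm = _leading_binomial(normalize_binomial(name))
    return index.keyword_to_accepted.get(norm)


def dedupe_species(
    names: Sequence[str], index: KeywordIndex
) -> tuple[set[str], list[str]]:
    """Resolve a list of names to a deduplicated accepted-species set.

    Returns ``(accepted_set, unmatched)``; unresolved names are returned in
    input order, never silently dropped.
    """
    accepted: set[str] = set()
    unmatched: list[str] = []
    for name in names:
        hit = resolve_name(name, index)
        if hit is None:
            unmatched.append(name)
        else:
            accepted.add(hit)
    return accepted, unmatched
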