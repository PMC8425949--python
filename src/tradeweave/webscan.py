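"""Species-keyword detection on seller pages and declarative site collection.

Online trade evidence comes from seller web pages: contemporary snapshot
pages and archive-stamped historical pages.  Pages are cleaned with a fixed
character-replacement rule (markup, digits and special characters become
single spaces, so a genus and epithet separated only by a tag or a price tag
end up adjacent), then searched by case-insensitive fixed-string matching
against the binomial keyword index.  No partial or abbreviated matching.

Site traversal is declarative: each site carries one of five collection
methods (single page, sequential page cycling, cycling plus depth-1 link
retrieval, depth-1 crawl, depth-2 crawl) evaluated against a fixture page
graph, with an optional URL keyword filter restricting which links are
followed.  The fetch layer is an interface: tests and examples feed it
in-memory graphs or on-disk page files, never the live web.  Politeness
metadata (request delay, default 10 s) travels with the site config and is
the contract for any real fetcher.
"""

from __future__ import annotations

import html
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .taxonomy import KeywordIndex

__all__ = [
    "LANGUAGES",
    "SITE_TYPES",
    "COLLECTION_METHODS",
    "LISTING_ORDERS",
    "SiteConfig",
    "PageDocument",
    "DetectionRecord",
    "PageNode",
    "SiteGraph",
    "SiteConfigError",
    "clean_page_text",
    "scan_page",
    "scan_pages",
    "collect_site",
    "language_summary",
    "load_site_configs",
    "load_pages",
    "detections_to_frame",
]

LANGUAGES = ("en", "fr", "de", "ja", "pt", "es")
SITE_TYPES = ("classifieds", "commercial", "other")
COLLECTION_METHODS = (
    "single_page",
    "page_cycle",
    "page_cycle_then_crawl1",
    "crawl1",
    "crawl2",
)
LISTING_ORDERS = ("alphabetical", "featured", "date", "price", "popularity", "unclear")

#: Safety bound for page cycling when a site declares no maximum and the
#: graph never yields an error page.
DEFAULT_HARD_CAP = 500


class SiteConfigError(ValueError):
    """Raised for unknown collection methods or malformed site configs."""


@dataclass(frozen=True)
class SiteConfig:
    """Per-website sampling metadata."""

    site_id: str
    language: str = "en"
    site_type: str = "commercial"
    collection_method: str = "single_page"
    url_keyword_filter: str | None = None
    listing_order: str = "unclear"
    request_delay_s: float = 10.0
    max_pages: int | None = None

    def __post_init__(self) -> None:
        if self.language not in LANGUAGES:
            raise SiteConfigError(f"{self.site_id}: unknown language {self.language!r}")
        if self.site_type not in SITE_TYPES:
            raise SiteConfigError(f"{self.site_id}: unknown site type {self.site_type!r}")
        if self.collection_method not in COLLECTION_METHODS:
            raise SiteConfigError(
                f"{self.site_id}: unknown collection method {self.collection_method!r}"
            )
        if self.request_delay_s < 0:
            raise SiteConfigError(f"{self.site_id}: negative request delay")


@dataclass(frozen=True)
class PageDocument:
    """One retrieved page: archive year for temporal pages, sampling year
    for snapshot pages."""

    site_id: str
    page_id: str
    year: int
    raw_text: str = ""


@dataclass(frozen=True)
class DetectionRecord:
    """One species keyword found on one page."""

    keyword: str
    accepted_name: str
    page_id: str
    site_id: str
    language: str
    year: int


@dataclass(frozen=True)
class PageNode:
    """One page in a fixture site graph."""

    page_id: str
    url: str = ""
    next_id: str | None = None  # sequential successor for page cycling
    links: tuple[str, ...] = ()
    is_error: bool = False


@dataclass
class SiteGraph:
    """Link structure of one site: start page, successors, outgoing links."""

    start_id: str
    nodes: Mapping[str, PageNode] = field(default_factory=dict)

    def node(self, page_id: str) -> PageNode | None:
        return self.nodes.get(page_id)


_TAG = re.compile(r"<[^>]*>")


def clean_page_text(raw_text: str) -> str:
    """Apply the page-cleaning rule and lower-case the result.

    HTML elements, digits and every non-letter character are replaced by
    single spaces; runs of whitespace collapse to one space.  Letters —
    including accented letters and CJK — survive.  A tag or digit between a
    genus and its epithet therefore leaves them adjacent (one space apart),
    while letters are never merged across a removed separator.
    """
    if not raw_text:
        return ""
    text = html.unescape(raw_text)
    text = _TAG.sub(" ", text)
    text = "".join(ch if ch.isalpha() else " " for ch in text)
    return " ".join(text.split()).lower()


def scan_page(page: PageDocument, index: KeywordIndex, language: str = "en") -> list[DetectionRecord]:
    """Fixed-string search of one page for every indexed binomial keyword.

    The page is cleaned internally; a keyword matches when its normalised
    form occurs as a substring of the cleaned text (genus and epithet
    adjacent).  One DetectionRecord per distinct keyword present — a page
    listing both an accepted name and one of its synonyms yields two
    records that resolve to one species downstream.
    """
    cleaned = clean_page_text(page.raw_text)
    if not cleaned:
        return []
    haystack = cleaned
    out: list[DetectionRecord] = []
    for keyword in sorted(index.keywords()):
        if keyword in haystack:
            out.append(
                DetectionRecord(
                    keyword=keyword,
                    accepted_name=index.keyword_to_accepted[keyword],
                    page_id=page.page_id,
                    site_id=page.site_id,
                    language=language,
                    year=page.year,
                )
            )
    return out


def scan_pages(
    pages: Iterable[PageDocument],
    index: KeywordIndex,
    site_language: Mapping[str, str] | None = None,
) -> list[DetectionRecord]:
    """Scan many pages, attaching each site's configured language."""
    site_language = site_language or {}
    detections: list[DetectionRecord] = []
    for page in pages:
        lang = site_language.get(page.site_id, "en")
        detections.extend(scan_page(page, index, language=lang))
    return detections


def _cycle(graph: SiteGraph, site: SiteConfig) -> tuple[list[str], bool]:
    """Sequential page cycling; returns (visited ids, hit_hard_cap)."""
    cap = site.max_pages if site.max_pages is not None else DEFAULT_HARD_CAP
    visited: list[str] = []
    seen: set[str] = set()
    current: str | None = graph.start_id
    while current is not None and current in graph.nodes and current not in seen:
        node = graph.nodes[current]
        if node.is_error:
            return visited, False
        visited.append(current)
        seen.add(current)
        if len(visited) >= cap:
            return visited, site.max_pages is None
        current = node.next_id
    return visited, False


def _passes_filter(node: PageNode, keyword: str | None) -> bool:
    return keyword is None or keyword in node.url


def _expand_links(
    graph: SiteGraph,
    frontier: Sequence[str],
    seen: set[str],
    keyword: str | None,
) -> list[str]:
    """One level of link retrieval; unknown targets and error pages skipped."""
    added: list[str] = []
    for page_id in frontier:
        node = graph.nodes.get(page_id)
        if node is None:
            continue
        for target in node.links:
            child = graph.nodes.get(target)
            if child is None or target in seen or child.is_error:
                continue
            if not _passes_filter(child, keyword):
                continue
            seen.add(target)
            added.append(target)
    return added


def collect_site(
    site: SiteConfig,
    graph: SiteGraph,
    page_text: Mapping[str, str] | None = None,
    year: int = 2020,
) -> list[PageDocument]:
    """Visit a site's pages per its configured collection method.

    Methods: ``single_page`` retrieves the start page only; ``page_cycle``
    follows sequential successors until the declared maximum, an error page,
    or the hard cap; ``page_cycle_then_crawl1`` additionally retrieves pages
    linked from each cycled page; ``crawl1``/``crawl2`` follow links from
    the start page to depth 1 or 2.  The URL keyword filter gates which
    links are followed (the start page is always retrieved).  Every page is
    visited at most once and only pages present in the graph are requested.
    """
    method = site.collection_method
    if method not in COLLECTION_METHODS:
        raise SiteConfigError(f"unknown collection method {method!r}")
    keyword = site.url_keyword_filter

    if graph.start_id not in graph.nodes:
        return []
    visited: list[str]
    if method == "single_page":
        visited = [graph.start_id]
    elif method in {"page_cycle", "page_cycle_then_crawl1"}:
        visited, capped = _cycle(graph, site)
        if capped:
            # no declared maximum and no error page: bounded by the hard cap
            import warnings

            warnings.warn(
                f"site {site.site_id}: page cycle hit hard cap {DEFAULT_HARD_CAP}",
                stacklevel=2,
            )
        if method == "page_cycle_then_crawl1":
            seen = set(visited)
            visited = visited + _expand_links(graph, visited, seen, keyword)
    elif method == "crawl1":
        seen = {graph.start_id}
        visited = [graph.start_id] + _expand_links(graph, [graph.start_id], seen, keyword)
    else:  # crawl2
        seen = {graph.start_id}
        level1 = _expand_links(graph, [graph.start_id], seen, keyword)
        level2 = _expand_links(graph, level1, seen, keyword)
        visited = [graph.start_id] + level1 + level2

    texts = page_text or {}
    return [
        PageDocument(
            site_id=site.site_id,
            page_id=pid,
            year=year,
            raw_text=texts.get(pid, ""),
        )
        for pid in visited
    ]


def language_summary(detections: Iterable[DetectionRecord]) -> pd.DataFrame:
    """Per-language species totals, unique-to-language counts, site counts.

    ``n_species`` counts distinct accepted species detected in that
    language; ``n_unique`` counts species detected in that language and in
    no other; ``n_sites`` counts distinct sites with any detection.
    """
    records = list(detections)
    by_lang: dict[str, set[str]] = {}
    sites: dict[str, set[str]] = {}
    for rec in records:
        by_lang.setdefault(rec.language, set()).add(rec.accepted_name)
        sites.setdefault(rec.language, set()).add(rec.site_id)
    rows = []
    for lang in sorted(by_lang):
        species = by_lang[lang]
        others = set().union(*(s for l, s in by_lang.items() if l != lang)) if len(by_lang) > 1 else set()
        rows.append(
            {
                "language": lang,
                "n_species": len(species),
                "n_unique": len(species - others),
                "n_sites": len(sites[lang]),
            }
        )
    return pd.DataFrame(rows, columns=["language", "n_species", "n_unique", "n_sites"])


def load_site_configs(path: str | Path) -> list[SiteConfig]:
    """Read site configs from YAML (list of mappings) or CSV."""
    path = Path(path)
    if path.suffix.lower() in {".yaml", ".yml"}:
        raw = yaml.safe_load(path.read_text())
        rows = raw if isinstance(raw, list) else raw.get("sites", [])
    else:
        rows = pd.read_csv(path, dtype=str).to_dict("records")
    configs = []
    for row in rows:
        kwargs = {k: v for k, v in row.items() if v is not None and v == v}
        if "request_delay_s" in kwargs:
            kwargs["request_delay_s"] = float(kwargs["request_delay_s"])
        if "max_pages" in kwargs:
            kwargs["max_pages"] = int(float(kwargs["max_pages"]))
        filt = kwargs.get("url_keyword_filter")
        if isinstance(filt, str) and not filt.strip():
            kwargs["url_keyword_filter"] = None
        configs.append(SiteConfig(**kwargs))
    return configs


_PAGE_NAME = re.compile(r"^(?P<page_id>.+)_(?P<year>\d{4})\.(html|txt)$")


def load_pages(root: str | Path) -> list[PageDocument]:
    """Load pages from ``<root>/<site_id>/<page_id>_<year>.html|txt``."""
    root = Path(root)
    pages: list[PageDocument] = []
    for site_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        for f in sorted(site_dir.iterdir()):
            m = _PAGE_NAME.match(f.name)
            if not m:
                continue
            pages.append(
                PageDocument(
                    site_id=site_dir.name,
                    page_id=m.group("page_id"),
                    year=int(m.group("year")),
                    raw_text=f.read_text(encoding="utf-8"),
                )
            )
    return pages


def detections_to_frame(detections: Iterable[DetectionRecord]) -> pd.DataFrame:
    """Detections as a tidy frame (site_id, page_id, year, language,
    keyword, accepted_name) ready for CSV export."""
    cols = ["site_id", "page_id", "year", "language", "keyword", "accepted_name"]
    rows = [
        {
            "site_id": d.site_id,
            "page_id": d.page_id,
            "year": d.year,
            "language": d.language,
            "keyword": d.keyword,
            "accepted_name": d.accepted_name,
        }
        for d in detections
    ]
    return pd.DataFrame(rows, columns=cols)
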