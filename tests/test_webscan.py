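"""Page cleaning, keyword scanning, site collection, language summaries."""

from __future__ import annotations

import pytest

from tradeweave.webscan import (
    DetectionRecord,
    PageDocument,
    PageNode,
    SiteConfig,
    SiteConfigError,
    SiteGraph,
    clean_page_text,
    collect_site,
    language_summary,
    scan_page,
)


class TestCleanPageText:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ("", ""),
            ("<b>Bombina</b>orientalis 25€", "bombina orientalis"),
            ("Hyla3arborea", "hyla arborea"),
            ("  double  spaces\tand\nnewlines ", "double spaces and newlines"),
            ("<div class='x'>Rana&nbsp;alpha</div>", "rana alpha"),
        ],
    )
    def test_replacement_rules(self, raw, expected):
        assert clean_page_text(raw) == expected

    def test_accented_and_cjk_letters_preserved(self):
        assert clean_page_text("café カエル 42") == "café カエル"

    def test_cleaning_is_idempotent_for_scanning(self, index):
        raw = "<p>AMBYSTOMA <i>MEXICANUM</i> 12 for sale</p>"
        page_raw = PageDocument("s", "p", 2020, raw)
        page_clean = PageDocument("s", "p", 2020, clean_page_text(raw))
        assert [d.keyword for d in scan_page(page_raw, index)] == [
            d.keyword for d in scan_page(page_clean, index)
        ]


class TestScanPage:
    def test_case_insensitive_match(self, index):
        page = PageDocument("s1", "p1", 2020, "AMBYSTOMA MEXICANUM for sale")
        hits = scan_page(page, index)
        assert [d.accepted_name for d in hits] == ["Ambystoma mexicanum"]

    def test_no_binomials_no_detections(self, index):
        page = PageDocument("s1", "p1", 2020, "nothing to see here 123 <b>!</b>")
        assert scan_page(page, index) == []

    def test_accepted_name_and_synonym_are_two_keywords_one_species(self, index):
        page = PageDocument(
            "s1", "p1", 2020, "We sell Hyla alpha, also known as Rana alpha."
        )
        hits = scan_page(page, index)
        assert len(hits) == 2
        assert {d.accepted_name for d in hits} == {"Hyla alpha"}

    def test_digit_or_markup_between_tokens_still_matches(self, index):
        page = PageDocument("s1", "p1", 2020, "Hyla<br>3alpha in stock")
        assert [d.accepted_name for d in scan_page(page, index)] == ["Hyla alpha"]

    def test_intervening_word_breaks_the_match(self, index):
        page = PageDocument("s1", "p1", 2020, "Hyla great alpha")
        assert scan_page(page, index) == []

    def test_abbreviation_not_matched(self, index):
        page = PageDocument("s1", "p1", 2020, "D. melanostictus wholesale")
        assert scan_page(page, index) == []


def _chain_graph(n: int, error_at: int | None = None) -> SiteGraph:
    nodes = {}
    for i in range(1, n + 1):
        nodes[f"p{i}"] = PageNode(
            page_id=f"p{i}",
            url=f"https://x.example/list?page={i}",
            next_id=f"p{i + 1}" if i < n else None,
            is_error=(error_at == i),
        )
    return SiteGraph(start_id="p1", nodes=nodes)


class TestCollectSite:
    def test_single_page_returns_exactly_start(self):
        site = SiteConfig(site_id="s", collection_method="single_page")
        pages = collect_site(site, _chain_graph(4))
        assert [p.page_id for p in pages] == ["p1"]

    def test_page_cycle_stops_at_declared_maximum(self):
        site = SiteConfig(site_id="s", collection_method="page_cycle", max_pages=5)
        pages = collect_site(site, _chain_graph(10))
        assert [p.page_id for p in pages] == ["p1", "p2", "p3", "p4", "p5"]

    def test_page_cycle_stops_at_error_page(self):
        site = SiteConfig(site_id="s", collection_method="page_cycle", max_pages=10)
        pages = collect_site(site, _chain_graph(10, error_at=4))
        assert [p.page_id for p in pages] == ["p1", "p2", "p3"]

    def test_unbounded_cycle_hits_hard_cap_with_warning(self):
        site = SiteConfig(site_id="s", collection_method="page_cycle")
        with pytest.warns(UserWarning, match="hard cap"):
            pages = collect_site(site, _chain_graph(600))
        assert len(pages) == 500

    def test_unknown_method_is_config_error(self):
        with pytest.raises(SiteConfigError, match="unknown collection method"):
            SiteConfig(site_id="s", collection_method="teleport")

    def _tree(self) -> SiteGraph:
        # depth-3 tree; only some URLs carry the 'products' keyword
        nodes = {
            "root": PageNode("root", "https://x.example/products/home",
                             links=("a", "b")),
            "a": PageNode("a", "https://x.example/products/frogs", links=("a1", "a2")),
            "b": PageNode("b", "https://x.example/blog", links=("b1",)),
            "a1": PageNode("a1", "https://x.example/products/frogs/tree",
                           links=("deep",)),
            "a2": PageNode("a2", "https://x.example/about"),
            "b1": PageNode("b1", "https://x.example/products/salamanders"),
            "deep": PageNode("deep", "https://x.example/products/frogs/tree/x"),
        }
        return SiteGraph(start_id="root", nodes=nodes)

    def test_crawl2_with_url_filter_matches_hand_enumeration(self):
        site = SiteConfig(
            site_id="s", collection_method="crawl2", url_keyword_filter="products"
        )
        pages = collect_site(site, self._tree())
        # depth<=2 pages whose URL contains 'products': root, a, a1
        # (b is filtered so b1 is unreachable; 'deep' is depth 3)
        assert [p.page_id for p in pages] == ["root", "a", "a1"]

    def test_crawl1_collects_start_plus_direct_links(self):
        site = SiteConfig(site_id="s", collection_method="crawl1")
        pages = collect_site(site, self._tree())
        assert [p.page_id for p in pages] == ["root", "a", "b"]

    def test_cycle_then_crawl1(self):
        nodes = {
            "p1": PageNode("p1", "u1", next_id="p2", links=("d1",)),
            "p2": PageNode("p2", "u2", links=("d2",)),
            "d1": PageNode("d1", "detail1"),
            "d2": PageNode("d2", "detail2"),
        }
        graph = SiteGraph(start_id="p1", nodes=nodes)
        site = SiteConfig(
            site_id="s", collection_method="page_cycle_then_crawl1", max_pages=5
        )
        pages = collect_site(site, graph)
        assert [p.page_id for p in pages] == ["p1", "p2", "d1", "d2"]

    def test_never_revisits_and_never_leaves_graph(self):
        nodes = {
            "p1": PageNode("p1", "u1", links=("p2", "ghost", "p1")),
            "p2": PageNode("p2", "u2", links=("p1", "p2")),
        }
        graph = SiteGraph(start_id="p1", nodes=nodes)
        site = SiteConfig(site_id="s", collection_method="crawl2")
        visited = [p.page_id for p in collect_site(site, graph)]
        assert visited == ["p1", "p2"]
        assert len(visited) == len(set(visited))
        assert set(visited) <= set(nodes)


def _det(sp, lang, site="s1"):
    return DetectionRecord(sp.lower(), sp, "p1", site, lang, 2020)


class TestLanguageSummary:
    def test_single_language_unique_equals_total(self):
        frame = language_summary([_det("Hyla alpha", "en"), _det("Hyla beta", "en")])
        row = frame.iloc[0]
        assert row["n_species"] == row["n_unique"] == 2

    def test_fully_shared_species_have_zero_unique(self):
        dets = [
            _det("Hyla alpha", "en"), _det("Hyla beta", "en"),
            _det("Hyla alpha", "de", site="s2"), _det("Hyla beta", "de", site="s2"),
        ]
        frame = language_summary(dets).set_index("language")
        assert frame.loc["en", "n_unique"] == 0
        assert frame.loc["de", "n_unique"] == 0

    def test_three_language_fixture_matches_hand_enumeration(self):
        dets = [
            _det("A a", "en"), _det("B b", "en"), _det("C c", "en"),
            _det("B b", "de", "s2"), _det("D d", "de", "s2"),
            _det("C c", "fr", "s3"),
        ]
        frame = language_summary(dets).set_index("language")
        assert frame.loc["en"].to_dict() == {"n_species": 3, "n_unique": 1, "n_sites": 1}
        assert frame.loc["de"].to_dict() == {"n_species": 2, "n_unique": 1, "n_sites": 1}
        assert frame.loc["fr"].to_dict() == {"n_species": 1, "n_unique": 0, "n_sites": 1}
        # sum of unique counts never exceeds the union
        union = {"A a", "B b", "C c", "D d"}
        assert frame["n_unique"].sum() <= len(union)
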