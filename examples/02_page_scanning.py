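"""Detect species keywords on a messy seller page.

Page text is cleaned with a fixed replacement rule (markup, digits and
special characters become single spaces) and then searched with
case-insensitive fixed-string matching against every indexed binomial.
"""

from tradeweave.taxonomy import TaxonConcept, build_keyword_index
from tradeweave.webscan import PageDocument, clean_page_text, scan_page

index = build_keyword_index(
    [
        TaxonConcept("Bombina orientalis", frozenset(), "Anura", "Bombinatoridae"),
        TaxonConcept("Hyla alpha", frozenset({"Rana alpha"}), "Anura", "Hylidae"),
    ]
)

raw = "<ul><li><b>BOMBINA</b>orientalis 25€</li><li>Rana alpha — 12,50</li></ul>"
print("raw page   :", raw)
print("cleaned    :", clean_page_text(raw))

page = PageDocument(site_id="shop1", page_id="p1", year=2020, raw_text=raw)
for det in scan_page(page, index):
    print(f"detected keyword '{det.keyword}' -> accepted species {det.accepted_name}")
# the markup and the price digits act as separators, so both binomials are
# found even though the HTML glues the first one to its tag
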