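"""Merge species evidence from several sources and partition the union.

Different sources see different species; the upset-style partition shows
how much each source contributes uniquely, which is why no single
inventory suffices.
"""

import json

from tradeweave.external_sources import EvidenceRecord
from tradeweave.integrate import intersect_sources, merge_sources
from tradeweave.taxonomy import TaxonConcept, build_keyword_index

index = build_keyword_index(
    [
        TaxonConcept("Hyla alpha", frozenset({"Rana alpha"}), "Anura", "Hylidae", 1905, "LC"),
        TaxonConcept("Hyla beta", frozenset(), "Anura", "Hylidae", 2005, "VU"),
        TaxonConcept("Salamandra delta", frozenset(), "Caudata", "Salamandridae", 1995, "EN"),
    ]
)

evidence = {
    "online": [EvidenceRecord("Rana alpha", "online", frozenset({"pet"}), 2012)],
    "lemis": [
        EvidenceRecord("Hyla alpha", "lemis", frozenset({"meat"}), 2008),
        EvidenceRecord("Hyla beta", "lemis", frozenset({"pet"}), 2014),
    ],
    "literature": [EvidenceRecord("Salamandra delta", "literature", frozenset({"other"}))],
}

profiles, unmatched = merge_sources(evidence, index)
print(f"union: {len(profiles)} species (unmatched names: {len(unmatched)})")
for name, p in sorted(profiles.items()):
    print(f"  {name}: sources={sorted(p.sources)} uses={sorted(p.uses)} "
          f"first_trade_year={p.first_trade_year}")
# Hyla alpha was listed online under a synonym but still lands on one
# profile, with its first trade year taken from the earliest dated source

print(json.dumps(intersect_sources(profiles.values()), indent=1))
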