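"""Resolve listed species names against a taxonomic backbone.

Species counts across trade data sources are only comparable after synonyms
are collapsed onto accepted names; this shows the keyword index and dedup.
"""

from tradeweave.taxonomy import TaxonConcept, build_keyword_index, dedupe_species, resolve_name

concepts = [
    TaxonConcept("Hyla alpha", frozenset({"Rana alpha"}), "Anura", "Hylidae", 1905, "LC"),
    TaxonConcept("Ambystoma mexicanum", frozenset({"Siredon mexicanus"}),
                 "Caudata", "Ambystomatidae", 1789, "CR"),
]
index = build_keyword_index(concepts)
print(f"keywords indexed: {index.n_keywords}  (accepted names + synonyms)")

print("'RANA ALPHA'      ->", resolve_name("RANA ALPHA", index))
print("'D. melanostictus' ->", resolve_name("D. melanostictus", index),
      " (abbreviations never match)")

names = ["Rana alpha", "Hyla alpha", "Siredon mexicanus", "Unknown frog"]
accepted, unmatched = dedupe_species(names, index)
print(f"{len(names)} listed names -> {len(accepted)} accepted species, "
      f"{len(unmatched)} unmatched: {unmatched}")
# two of the four names are synonyms/duplicates of the same species, so the
# deduplicated species count is what a cross-source union should use
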