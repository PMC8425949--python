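"""Shared fixtures: a small hand-built backbone and its keyword index."""

from __future__ import annotations

import pytest

from tradeweave.taxonomy import TaxonConcept, build_keyword_index


@pytest.fixture(scope="session")
def concepts() -> list[TaxonConcept]:
    """Ten species, four synonyms in total -> 14 keywords."""
    base = [
        TaxonConcept("Hyla alpha", frozenset({"Rana alpha", "Litoria alpha"}),
                     "Anura", "Hylidae", 1905, "LC"),
        TaxonConcept("Bombina orientalis", frozenset({"Bombinator orientalis"}),
                     "Anura", "Bombinatoridae", 1890, "LC"),
        TaxonConcept("Ambystoma mexicanum", frozenset({"Siredon mexicanus"}),
                     "Caudata", "Ambystomatidae", 1789, "CR"),
        TaxonConcept("Duttaphrynus melanostictus", frozenset(),
                     "Anura", "Bufonidae", 1799, "LC"),
        TaxonConcept("Hyla beta", frozenset(), "Anura", "Hylidae", 2005, "NE"),
        TaxonConcept("Hyla gamma", frozenset(), "Anura", "Hylidae", 2008, "VU"),
        TaxonConcept("Salamandra delta", frozenset(), "Caudata", "Salamandridae", 1995, "EN"),
        TaxonConcept("Salamandra epsilon", frozenset(), "Caudata", "Salamandridae", 1820, "DD"),
        TaxonConcept("Ichthyophis zeta", frozenset(), "Gymnophiona", "Ichthyophiidae", 1960, "LC"),
        TaxonConcept("Hyla eta", frozenset(), "Anura", "Hylidae", 2010, "NT"),
    ]
    return base


@pytest.fixture(scope="session")
def index(concepts):
    return build_keyword_index(concepts)
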