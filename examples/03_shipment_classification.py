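"""Classify a small shipment ledger by source and purpose.

Only description codes that represent single individual animals are kept;
source codes map to wild/captive; the staged purpose classifier combines
trader-name keywords, seller specialisation, the dead-specimen default and
the individual-importer default.
"""

from tradeweave.lemis import (
    PurposeKeywordTable,
    ShipmentRecord,
    classify_purpose,
    filter_individual_units,
    source_totals,
)

table = PurposeKeywordTable(keyword_to_category={"gourmet": "meat", "petshop": "pet"})
ledger = [
    ShipmentRecord("Hyla alpha", "Hyla", "LIV", "W", "T",
                   importer_name="petshop one", exporter_name="frogs ltd", quantity=40),
    ShipmentRecord("Hyla alpha", "Hyla", "LIV", "C", "T",
                   importer_name="no hints", exporter_name="frogs ltd", quantity=10),
    ShipmentRecord("Hyla beta", "Hyla", "BOD", "W", "T",
                   importer_name="gourmet kitchens", exporter_name="meat co", quantity=50),
    ShipmentRecord("Hyla beta", "Hyla", "SHO", "W", "T", quantity=999),  # shoes: not an individual
]

units = filter_individual_units(ledger)
print(f"{len(ledger)} records -> {len(units)} single-individual records")

totals = source_totals(units)
print(f"individuals: {totals['n_total']}, wild {totals['pct_wild']}%, "
      f"captive {totals['pct_captive']}%")

for rec, asg in zip(units, classify_purpose(units, table)):
    print(f"{rec.listed_name:12s} {rec.description_code} -> {asg.category:5s} via {asg.provenance}")
# the second record has no keyword but inherits 'pet' because its seller's
# keyword-classified shipments are unanimous
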