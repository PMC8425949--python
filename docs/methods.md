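# Methods

## Problem and scope

Wildlife-trade monitoring for species-rich, lightly regulated taxa such as
amphibians cannot rely on any single inventory. `tradeweave` integrates five
evidence streams — online seller pages (snapshot and archived), a
LEMIS-style shipment ledger, CITES checklist/gross-import tables, IUCN
use-and-trade narratives, and literature species lists — into per-species
trade profiles, then summarises scale (species counts, individual volumes),
sourcing (wild vs captive), uses, geography, and temporal dynamics.

The package operates entirely on files and in-memory structures. Live web
discovery, search-engine harvesting, Wayback API calls, and range-polygon
rasterisation are deliberately outside scope: the fetch layer is an
interface fed by page fixtures or pre-downloaded files, and geographic
summaries work from a plain species → country occurrence table.

## Taxonomic resolution

All species counting passes through a backbone of accepted binomials with
synonyms, higher taxonomy, description year and IUCN category. Keywords
(accepted names + synonyms) are normalised by lower-casing and whitespace
collapsing; no diacritic folding (scientific names are ASCII by
convention). Resolution is exact-binomial: trinomials resolve via their
leading binomial, and abbreviations (`D. melanostictus`) never match —
approximate matching trades false positives for recall and is excluded.
Two structural choices are stricter than strictly necessary, both to
protect union counts:

* a duplicate accepted name in the backbone is a load error, and
* a synonym claimed by two accepted species is a hard load error naming
  both claimants, never an arbitrary assignment.

## Page cleaning and detection

Cleaning replaces HTML elements, digits and all non-letter characters with
single spaces, collapses whitespace and lower-cases; letters including
accented and CJK characters survive. Consequences that matter: a tag or a
price wedged between genus and epithet leaves them adjacent (so
`<b>Bombina</b>orientalis 25€` still matches), while an intervening word
breaks the match. Detection is case-insensitive fixed-string search of each
keyword in the cleaned text — substring semantics, so a keyword that is a
prefix of a longer string can fire; species-level dedup happens downstream.
Cleaning is idempotent with respect to scanning: scanning cleaned text
equals scanning the raw page.

Site collection is declarative. Each site carries one of five methods
(single page; sequential page cycling; cycling + depth-1 link retrieval;
depth-1 crawl; depth-2 crawl), an optional URL keyword filter, and
politeness metadata (request delay, default 10 s — a contract for any real
fetcher; fixtures run with the graph directly). Cycling stops at the
declared maximum or an error page; with neither, a hard cap of 500 pages
applies and is reported. The URL filter gates which links are followed;
the start page itself is always retrieved (the operator chose it). Pages
are visited at most once and only pages present in the supplied graph are
requested.

Each page carries a calendar year: the archive timestamp's year for
temporal samples, the sampling year for snapshot pages.

## Shipment classification

Unit filter: only description codes that denote one individual animal are
kept — BOD, EGL, DEA, LIV, SPE, SKI, TRO. EGL (live eggs) is counted as one
individual per unit, as it sits in the same unit list; users who disagree
can drop it via the configurable code set. Source: W → wild; C, F, D, R →
captive; anything else (including blank) → other/ambiguous. Commerciality:
purpose codes M, S, Y → non-commercial; everything else commercial. All
volume summaries weight by the quantity field.

The purpose classifier is staged, and each record's provenance is recorded:

1. **keyword** — lower-cased trader-name keywords (importer and exporter)
   assign categories directly; a `zoo` token on an entity not in the
   genuine-zoo registry assigns pet (hobbyist shops advertise as "zoo").
   If one record's names hit keywords of different categories, a fixed
   priority (medicinal > meat > pet > research/zoo > other) breaks the tie
   deterministically.
2. **seller_propagated** — sellers specialise; an unassigned record
   inherits its exporter's category when that seller's keyword-assigned
   records are unanimous. Unanimity rather than majority: deterministic and
   conservative, with conflicts deferred to stage 3.
3. **dead_default** — remaining unassigned records of sellers who ship any
   dead-pathway item (BOD, DEA, SKI, TRO, SPE; SPE counts as dead-pathway)
   resolve to meat, or to medicinal/pharmaceutical when a medicinal keyword
   appears anywhere in that seller's records. Dead specimens indicate
   consumption or medicine.
4. **individual_default** — remaining records imported by private
   individuals are pets, unless the purpose code is research (M, S), which
   maps to research/zoo.
5. **unresolved** — everything else is counted separately, never guessed.

Seller identity is the case-folded, whitespace-collapsed exporter string;
no entity linkage beyond exact match. The classifier is order-independent
(seller groups are processed on sorted keys): permuting the input permutes
the output identically. The trader-keyword table is data, not code: the
package ships a small documented synthetic default for tests and the
generator, and real analyses supply their own CSV.

Genus summaries use the ledger's genus field, excluding placeholder values
(`Non-CITES entry`, `Anura`, `Bufonidae`, `Tadpole`; extensible), weight by
quantity, and report per-genus wild percentage plus across-genus mean and
median. Percentages are kept at full precision internally; the report layer
rounds half-to-even to one decimal, two decimals below 1%.

## External sources

IUCN use-and-trade narratives are classified by keyword (food/meat terms →
meat, pet terms → pet, medicine/pharma terms → medicinal) with a negation
window: a negation token within the three tokens preceding a keyword
suppresses that hit ("traded as pets but not for food" → pet only). Texts
matching no-trade phrases classify as no-trade and drop out of the species
listings; trade stated without a category keyword classifies as "other".
The window size and token lists are configurable; rule-based classification
of free text will miss constructions a human reader catches — that is the
documented cost of automating what was originally a manual review, and the
rules are validated only on synthetic narratives with known labels.

CITES checklists join by leading binomial (trinomial listings match their
binomial); a taxon on several appendices keeps the strictest. Gross-import
tables are wide-by-year and carry no importer identity, so only coarse
purpose codes can be mapped to use categories. Literature lists enter as
evidence with use "other" and no dated detection.

## Integration and reporting

Merging is a synonym-aware union: sources and uses accumulate per accepted
species; `first_trade_year` is the minimum year over dated sources (online,
shipment ledger, CITES) and is never imputed from undated evidence (IUCN,
literature). Unresolvable names are returned, contribute to volume totals
upstream, and never enter species counts. The source-combination partition
(upset analysis) is exact: cells are disjoint and sum to the union size.
Threatened means VU, EN or CR; a near-threatened-inclusive flag is
reported separately. Percent-of-described supports both truncation and
half-even rounding because published coverage figures mix the two
conventions; Decimal arithmetic avoids binary-float artefacts at the cut.

National summaries attribute each traded species to every country in its
occurrence set and report totals, traded counts and shares, traded species
that are threatened or data-deficient/unassessed, and traded species with
no CITES listing.

## Temporal analyses

Yearly series count a species once per source-year; unique-to-year counts
species seen in no other year of the same source. The effort-adjusted trend
is ordinary least squares of yearly species count on yearly pages searched
(statsmodels OLS; tests check it against a normal-equations oracle), with
df = years − 2 and residuals returned per year as the trend signal.

The lag analysis takes species described after the cutoff year (default
1999, i.e. described ≥ 2000; configurable) that appear in trade. Species
whose only detection year is the snapshot year have no usable onset date
and are excluded but counted. Lag = first trade year − description year;
the summary reports mean ± sample sd/√n (the ± is a standard error).
Negative lags are flagged as data errors rather than silently dropped.

## Synthetic worlds

The generator emulates all six input classes from one seed, with one
spawned random stream per component (backbone, plan, pages, shipments,
narratives, literature, CITES) so enlarging one component never perturbs
another; identical seed + spec gives byte-identical files. Key defaults:
30 species with synonym rate 0.3; one site per language (six languages),
four pages each, three species per page; 200 shipments of quantity 1 with
wild fraction 0.4 (the planted wild count is exact by construction, not in
expectation); ten sellers cycling through the five use categories with
keyword coverage 1.0 (at least one keyworded record per seller whenever
coverage is positive); narratives with a 0.2 no-trade rate and 0 negation
rate; description years 1980–2012 with six post-cutoff species given
planted lags of 1–5 years and two snapshot-only species; trade window
2004–2019 with snapshot year 2020. Species names are built from disjoint
syllable pools for genera, epithets and page noise, so no noise bigram can
collide with a keyword and detection ground truth is unambiguous.

What the worlds do *not* emulate: realistic trade volumes, skewed
seller-size distributions, misspellings, multilingual free text beyond
noise tokens, or genuinely adversarial pages. Passing the recovery checks
therefore demonstrates the logic is correct under the stated rules, not
that real-world recall would be 100%; on real pages the fixed-string
constraint (no abbreviations, no fuzzy matching) is a known source of
misses.

`end_to_end_check` runs the real pipeline on a world and reports detection
recall/precision, wild-percentage error, purpose and narrative
classification accuracy, species-union error, and lag-mean error. A
noiseless world scores 100% / zero on all of them; reducing keyword
coverage degrades purpose accuracy in a way that is computable from the
planted seller mix, which the tests exploit.

## Numerical and degenerate-input conventions

Empty inputs return empty outputs, never errors (empty dedup list, empty
detection set, empty species set → coverage reported as 0/0). Zero-quantity
genera are excluded from genus summaries. The trend fit requires at least
three years. All classifier behaviour is deterministic; the only
randomness in the package lives in the generator and is seed-controlled.
Problem sizes in the test suite and acceptance script (worlds of ~30
species, 200–1000 shipments, ≤ 200-species intersection fixtures) were
chosen as the smallest sizes at which every mechanism — propagation,
conflicts, exclusions, anchoring — is actually exercised.

## Known limitations

* Seller identity is exact-string; entity resolution across spelling
  variants is out of scope.
* Narrative classification approximates a manual review; its negation
  window is a blunt instrument.
* The CITES purpose mapping is coarse by necessity (no importer identity in
  gross imports).
* Occurrence-based national summaries inherit whatever bias the occurrence
  table carries; no range-map processing is attempted.
* Fixed-string matching cannot find abbreviated or misspelt names; that is
  a stated design boundary, not an oversight.
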