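# Methods

This note documents the procedures implemented in `nppairs`, the parameters
that matter, the design choices made where the design was genuinely open, and
what the synthetic test corpus does and does not establish about real data.

## Harmonization

Raw per-source tables are mapped to a common schema by declarative per-source
configs (`SourceMapping`): each raw column is declared as a structure
descriptor (optionally with a subcategory hint), the organism field, or one of
the ten reference subcategories. Subcategory assignment is deterministic and
total on non-empty input:

* **structure** — `inchi` iff the value starts with `InChI=`; `smiles` iff
  RDKit parses the value as a line notation (values with whitespace are never
  SMILES); otherwise `name`.
* **organism** — `dirty` when a packaged trigger lexicon (organ words,
  isolation phrases, locality words, `spp.`, `cf.`, `ex`, …) matches
  word-bounded and case-insensitively, or when the value is not a plausible
  bare Latin name; `clean` otherwise. The classifier deliberately defaults to
  `dirty` when uncertain, since dirty fields get the full
  recognition/translation treatment and clean ones are a subset of it.
* **reference** — subcategory comes from the mapping, not from content.

All available structure descriptors of a record are retained; the preference
order (structural identifiers over names, SMILES over InChI) is applied
downstream when one descriptor must be chosen. A SQLite-backed store keyed by
(object kind, raw value) serves as the single source of truth: a value seen
before is served from the store and never re-curated.

## Structure curation

Names are normalized before resolution: Greek characters are replaced by
ASCII words via a packaged table (α→alpha, β/ß→beta, …), optical-rotation
prefixes ((+)-, (−)-, (±)-) are stripped, whitespace is collapsed, case is
preserved. Resolution walks an ordered resolver chain whose first member is a
local name→SMILES dictionary; remote resolvers (systematic-name parser,
compound-name service, identifier resolver) plug in behind the same
one-callable interface but are off by default, keeping the pipeline
deterministic and offline. IUPAC/traditional name *generation* is not
implemented — no open engine provides it; the absence is recorded in the
audit trail, never fatal.

Sanitization uses RDKit's `rdMolStandardize` (the MolVS standardizer bundled
with RDKit), in this order:

1. `Cleanup` — valence check, explicit-H removal, metal disconnection,
   normalization, acid reionization, stereochemistry recalculation;
2. fragment removal driven by a packaged counterion/solvent SMARTS list
   (adapted from the open MolVS/ChEMBL salt lists; the list is a data file
   and editable);
3. neutralization (`Uncharger`);
4. the dimer rule: any structure whose canonical SMILES still contains `.`
   is discarded.

Sanitization is idempotent (tested on a 120+-molecule battery of vocabulary
structures with salt/charge decorations), and the SMILES- and InChI-derived
InChIKeys agree for every accepted record. The *planar key* is the first 14
characters of the InChIKey; structures whose potential stereocentres and
stereogenic bonds are all specified are classed `chemical_compound`, the rest
`stereoisomer_group` (achiral molecules are vacuously fully defined).

## Organism curation

Translation dictionaries are built from aggregated (common name, canonical
name) pairs under these rules, applied per common name:

* names of ≤ 3 characters and stop-listed unspecific names are dropped;
* a translation that *adds* a specific epithet to a common name which is
  itself the bare genus is discarded ("Aloe" → "Aloe vera");
* common names whose candidate translation is genus-level ("Kiwi" →
  *Apteryx* spp.) are discarded outright;
* with several candidates, genus and epithet frequencies decide: both
  consistent at **strictly** more than 50% keeps the consistent binomial(s),
  including infraspecific variants; genus-only consistency keeps the bare
  genus; neither drops the name. ">50%" is read strictly — exactly half
  fails — because a half-supported epithet is not a majority. A single
  candidate is trivially 100% consistent and kept verbatim.

TCM dictionaries additionally strip organ/drug-part words (Radix, Rhizoma,
Folium, …) and apply packaged Latin-genitive mappings. All dictionaries are
ordered by decreasing common-name length (lexicographic tie-break) so longer
names are translated before their substrings.

Raw organism text is processed as: recognition → subtraction → translation →
re-recognition → taxonomy unification. Recognition is a gazetteer
longest-match scanner (case-insensitive, word-bounded) behind the same
interface a names-finder/verifier service would implement; all accepted
synonyms of a matched name are kept, each with its source database and
identifier, and only databases on the packaged accepted list are admitted.
Subtraction removes the matched spans before vernacular translation so
epithets are never re-translated. Unified-taxonomy mapping is a pluggable
service (fixture table offline); unmapped names are flagged, not dropped.
Genus-rank records are kept and flagged rather than discarded. Nomenclatural
homonyms are surfaced as multiple gazetteer entries for one matched name;
resolving them is out of scope.

The four-reservoir grouping combines the two highest lineage levels:
Eukaryota_Archaeplastida → Plantae, Eukaryota_Fungi → Fungi,
Eukaryota_Metazoa → Animalia, Bacteria_NA → Bacteria; Eukaryota_NA (mostly
algae) and every unknown combination are excluded.

## Reference curation

Candidates come from a provider interface: `query(text, limit)` for free
text (≤ 20 kept, provider score order), exact lookup for DOI and PMID (≤ 1
candidate, round-trip verified — a dead identifier resolves to nothing). The
offline fixture provider ranks stored references by a deterministic
token-overlap score where each shared token contributes its inverse document
frequency (a tf-idf-style score); ties keep store order.

Because retrieval relevance alone is not informative enough, candidates are
re-ranked lexicographically: relevance (desc), then for the free-text
subcategories (`original`, `publishingDetails`, `split`) a complement score
(desc) counting which of {journal, first author's family name, 4-digit
publication year} appear in the original string, then genus-in-title (desc),
then for the identifier/title subcategories the OSA distance (asc) between
input and candidate compared like-with-like (doi↔doi, pmid↔pmid,
title↔title, casefolded). The complement is taken as three components —
journal, first author, year — consistent with the validation filter that
searches exactly those three in the original entry. Containment checks are
case-insensitive with punctuation stripped; the year must match as a 4-digit
token. The first candidate after the stable sort is selected; a
DOI↔PMID↔PMCID map (PMC-ids style CSV) completes missing identifiers.

The OSA (optimal string alignment, restricted Damerau–Levenshtein) distance
is the standard DP with unit-cost insert/delete/substitute and adjacent
transposition, no substring edited twice; it is verified against an
independent brute-force recursion on 10,000+ random pairs, including the
restricted-variant witness osa("CA","ABC") = 3.

## Validation filter

A curated pair is auto-validated iff one clause holds —

* **[A]** reference subcategory `doi` or `pubmed`;
* **[B]** subcategory `title` with OSA(original, resolved title) **< 10**
  (strictly);
* **[C]** resolved journal is one of *Journal of Natural Products*,
  *Phytochemistry*, *Journal of Agricultural and Food Chemistry* (exact full
  names, case-insensitive);
* **[D]** subcategory `original`/`publishingDetails`/`split` with complement
  ≥ 2 of 3 —

and the resolved title contains the genus (first token) of the canonical
name; this title check is waived for DOI-based references except those
sourced from COCONUT. The decision is a pure function of the pair and
carries the deciding clause (or rejection reason) as an audit code. Clauses
are tried in A–D order, so a pair satisfying several reports the first.

Filter quality is measured with F<sub>β</sub> at β = 0.5 (precision weighted
twice recall); the degenerate 0/0 case is defined as 0. Stratified sampling
for manual validation is deterministic given a seed, guarantees a minimum
per present reference subcategory, and allocates the remainder by largest
remainder. Manual-validation criteria (descriptor linkable to the final
InChIKey, organism descriptor linkable to the canonical name, reference
describing the occurrence) are an annotation schema, not automated.

## Realignment, deduplication, export

Realignment joins each original entry to its curated objects, one output
pair per (structure, organism, reference) combination; incomplete entries
are dropped with per-object counts. Deduplication is unique on (full
stereo-aware InChIKey, canonical name + taxonomy database, reference
identity at DOI > PMID > title precedence), provenance merged. The planar
key is an analytics-level aggregation, not the dedup key: two
stereo-distinct keys sharing a planar key stay separate rows.

The frozen export is a TSV with fixed column order, rows sorted by (planar
key, canonical name, DOI), reload-roundtrip-identical. The KB-ready export
applies the upload constraints: names > 250 characters dropped from the name
field only, InChI > 1500 characters omitted, molecular-formula digits
converted to Unicode subscripts, taxa restricted to ranks {family,
subfamily, tribe, subtribe, genus, species, variety} and the restricted
database list, previously exported rows skipped via the store; every skip
carries a reason code. Live knowledge-base upserts are out of scope — the
exporter produces the upsert-ready table.

## Analytics

All statistics count distinct (planar key, taxon) pairs, never raw rows, so
multiply-referenced occurrences do not inflate anything. "Specific" in the
four-reservoir table means present in exactly one group. Source
intersections use UpSet semantics (exclusive combinations). The family
filter keeps families with ≥ 50 distinct planar keys by default.

The JSD specificity of a chemical class at a taxonomic level is the base-2
Jensen–Shannon divergence between P, the class's distribution of distinct
(planar key, taxon) pairs over taxa at that level, and Q, the same
distribution over *all* pairs (the background includes the class itself).
Base-2 bounds the score to [0, 1]; zero-probability taxa need no smoothing.
With the class included in the background, a class confined to a single
taxon scores slightly below 1 in small tables — exact 1 requires disjoint
supports. The Jaccard specificity of (class, family) is intersection over
union of their planar-key sets. Class labels come from the chemical
classification interface; offline, a fixture classifier supplies one class
per planar key.

## Synthetic corpus

The generator emulates the heterogeneity the pipeline must survive: mixed
structure descriptors (default 40% SMILES / 30% InChI / 30% names; 15% of
SMILES carry salt/solvent adducts, 30% of names carry Greek letters), 70%
clean / 30% dirty organism strings (30% of them vernacular), and reference
values across the subcategories, weighted on the six with a translation
route (doi 25%, title 25%, original 20%, pubmed 12%, split 10%,
publishingDetails 8%) — `authors`, `journal`, `external`, `isbn` are
classified at harmonization but have no resolution path, matching the
pipeline's scope, so their default weight is zero. 20% of titles are
corrupted by ≤ 4 character edits; 10% of entries are emitted by a second
source to exercise provenance merging; `wrong_pair_rate` swaps in a
reference documenting a different organism and labels the entry invalid.

Entries are distinct structure–organism combinations, each with its own
synthesized reference, and author tags are retrieval-unique; this engineered
unambiguity is what makes 100% recovery of uncorrupted entries a meaningful
closure property rather than a probabilistic one. Statistical realism beyond
exercising every code path is explicitly a non-goal: passing tests show the
machinery is correct and deterministic, not that real-world recovery rates
reach any particular value. Real corpora bring ambiguous citations, homonyms
and resolver misses that the fixture services are too clean to contain —
with default corruption the corpus already shows the realistic failure mode
(a corrupted title retrieved as the wrong, near-tied candidate). The fixture
vocabularies (≈ 120 structures with names and class labels, ≈ 50 organisms
with lineage) are packaged synthetic stand-ins; real dictionaries are
drop-in replacements of the same file shapes.

## Numerical and procedural choices

* Default problem sizes: the end-to-end closure check runs a 1000-entry
  corpus (all 1000 ground-truth triples recovered); filter evaluation uses a
  600-entry corpus with 20% wrong pairs. These sizes exercise every
  subcategory and noise path while keeping a full run in seconds.
* Determinism: every stochastic step (corpus generation, sampling) takes an
  explicit seed; the curation itself is seed-free and pure.
* Tie-breaks are always explicit: dictionary order (length desc,
  lexicographic), candidate ranking (stable sort, store order on full ties),
  dedup (insertion order).
* Degenerate inputs: empty tables raise; unresolved objects are flagged and
  dropped only at realignment, with counts; malformed id-map rows are
  skipped with warnings.

## Known limitations

* Name resolution offline is only as good as the local dictionary; remote
  resolvers are interface stubs by design.
* The trigger lexicon, counterion list, stop-lists and Greek table are
  deliberately small packaged approximations; each is a plain data file
  meant to be replaced wholesale.
* Homonymy ("Lotus" the legume genus vs. the vernacular lotus) is flagged,
  not resolved.
* The filter's clause [A] waiver means a wrong pair arriving with a valid
  DOI from a non-COCONUT source is accepted — visible as the residual
  false-positive rate (~4–5%) in the acceptance run, and the price of not
  rejecting correct DOI-referenced pairs whose titles omit the genus.
* Whether genus-only organism records should survive validation is left
  permissive (kept, flagged); stricter policies can filter on the flag.
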