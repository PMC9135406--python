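# nppairs

Curation of referenced natural-product **structure–organism pairs**: an
offline-capable toolkit that turns heterogeneous raw records of natural-product
occurrences (free-form structure, organism and reference fields, as exported by
the many electronic NP resources) into validated triples of

* a **chemical structure** (canonical SMILES, InChI, InChIKey, the 14-character
  *planar key*, and a stereo entity class),
* a **biological organism** (canonical scientific name with per-database taxon
  identifiers and a unified-taxonomy id),
* a **bibliographic reference** (DOI / PMID / PMCID plus title) documenting the
  occurrence,

and then computes chemotaxonomic distribution and specificity statistics on the
curated result. It is written for natural-product chemists, chemical ecologists
and knowledge-base maintainers who need reproducible, referenced occurrence
data rather than a heap of inconsistent source dumps.

## The method

Curation runs in four stages:

1. **Harmonization** — per-source declarative column mappings classify every
   raw field into subcategories: structures into `inchi` / `smiles` / `name`,
   organisms into `clean` / `dirty`, references into ten subcategories
   (`authors, doi, external, isbn, journal, original, publishingDetails,
   pubmed, title, split`). A local store guarantees each raw value is curated
   once.
2. **Object curation**
   * *Structures*: descriptor preference (SMILES > InChI > name), Greek-letter
     normalization of names (α → alpha), resolution through an ordered resolver
     chain (local dictionary first; remote services optional and off by
     default), then sanitization: standardization, SMARTS-driven
     counterion/solvent removal, neutralization, and discard of anything still
     multi-fragment ("dimer rule"). Structures with every stereocentre
     specified are *chemical compounds*; the rest are *groups of stereoisomers*.
   * *Organisms*: scientific-name recognition against a gazetteer, subtraction
     of recognized names (so the epithet of *Bromus mango* is never
     re-translated as the fruit), longest-first vernacular/TCM translation with
     dictionaries built under a strict >50% genus/epithet consistency rule, a
     second recognition pass, and unified-taxonomy mapping.
   * *References*: candidate retrieval (≤ 20 candidates for free text, a single
     round-trip-verified candidate for DOI/PMID), scoring, and lexicographic
     re-ranking by relevance, complement score (journal / first author / year
     found in the original string), genus-in-title, and optimal string
     alignment (OSA, restricted Damerau–Levenshtein) distance.
3. **Validation** — an automatic filter accepts a pair when its reference came
   from [A] an identifier, [B] a title at OSA distance < 10, [C] one of three
   whitelisted NP journals, or [D] free text containing ≥ 2 of {year, journal,
   first author}; plus a genus-in-title check, waived for DOI-based references
   (except those sourced from COCONUT). Filter quality is scored against
   manual labels with the precision-weighted F-score

   F<sub>β</sub> = (1 + β²)·P·R / (β²·P + R),  β = 0.5.

4. **Realignment & export** — curated objects are joined back to the original
   entries, deduplicated stereo-aware (full InChIKey; reference identity at
   DOI > PMID > title precedence) with provenance merged, and emitted as a
   frozen TSV and a knowledge-base-ready table (field-length limits, formula
   subscripting C15H10O5 → C₁₅H₁₀O₅, allowed taxon ranks and databases).

On the curated table, the analytics module computes organism/structure
marginal distributions, the four-reservoir (Plantae/Fungi/Animalia/Bacteria)
specificity table, exclusive source intersections (UpSet semantics), and two
chemotaxonomic specificity scores: a base-2 **Jensen–Shannon divergence**
between a chemical class's distribution over taxa and the background (1 =
highly specific, 0 = ubiquitous), and a **Jaccard index** between a chemical
class's and a biological family's planar-key sets.

Every external service (name resolver, scientific-name verifier, bibliographic
search, chemical classifier) sits behind a pluggable interface with an offline
fixture implementation, so the whole pipeline is deterministic without a
network. A synthetic-corpus generator produces messy corpora *with ground
truth*, which is how the pipeline is tested end to end.

## Worked example

```python
from nppairs import (CorpusSpec, generate_corpus, build_fixture_services,
                     curate_corpus)

corpus = generate_corpus(CorpusSpec(seed=1, n_entries=200, wrong_pair_rate=0.1))
services = build_fixture_services(corpus)
result = curate_corpus(corpus, services)
print("harmonized entries :", len(result.entries))
print("realigned pairs    :", len(result.pairs))
print("unique pairs       :", len(result.unique_pairs))
```

prints

```
harmonized entries : 218
realigned pairs    : 218
unique pairs       : 200
```

218 raw rows (200 distinct entries, some emitted by two sources) harmonize,
realign into 218 pairs and deduplicate to 200 unique triples with merged
provenance. One auto-validated pair looks like

```
WWNNZCOKKKDOPX-UHFFFAOYSA-N | Papaver somniferum | 10.5281/SYNTH.00002 | clause D
```

i.e. an InChIKey, a canonical organism and a DOI, accepted by the free-text
clause [D] (journal and year found in the original citation). The same run is
available from the shell:

```bash
nppairs run --seed 1 --n 200 --wrong-pair-rate 0.1
```

which additionally reports filter precision/recall/F0.5 against the corpus
ground truth (0.989 / 1.0 / 0.992 here). `nppairs harmonize --source
examples/source_demo.yaml --in examples/source_demo.tsv --out out.tsv` shows
the harmonization stage alone on a three-row demo source.

## Layout

```
src/nppairs/
  ingest.py       harmonization, subcategory assignment, source mappings
  structures.py   structure translation + sanitization (RDKit)
  organisms.py    dictionaries, recognition, translation, taxonomy
  references.py   OSA distance, candidate retrieval, scoring, re-ranking
  validation.py   filter rules, F-beta, stratified sampling, evaluation
  assemble.py     realignment, deduplication, frozen / KB exports
  analytics.py    distributions, specificity tables, JSD / Jaccard, UpSet
  corpus.py       synthetic corpora + offline fixture services
  pipeline.py     end-to-end orchestration
  cli.py          `nppairs` command-line interface
  data/           packaged tables (Greek letters, triggers, counterion
                  SMARTS, stop-lists, accepted DBs, synthetic vocabularies)
```

See `docs/methods.md` for the modelling choices, parameter defaults and known
limitations.
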