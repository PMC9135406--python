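"""End-to-end orchestration: raw tables -> curated, validated, deduplicated
structure-organism-reference pairs.

This is the glue the command-line interface and the test harness share.  Each
object family is curated once per distinct raw value (memoized, mirroring the
single-source-of-truth store), then realigned to the original entries,
deduplicated, stamped by the automatic validation filter, and laid out as the
frozen tabular export.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections import Counter
from typing import Mapping, Sequence

import pandas as pd

from .assemble import deduplicate, pairs_to_frame, realign
from .cache import CurationCache
from .corpus import FixtureServices, SyntheticCorpus
from .ingest import HarmonizedEntry, SourceMapping, harmonize, records_from_frame
from .organisms import OrganismRecord, curate_organism
from .references import RESOLVABLE_SUBCATEGORIES, ReferenceRecord, curate_reference
from .structures import StructureRecord, curate_structure, select_descriptor
from .validation import CuratedPair, apply_filter

#: Priority when an entry carries several reference subcategories.
REFERENCE_PRIORITY = (
    "doi",
    "pubmed",
    "title",
    "original",
    "split",
    "publishingDetails",
    "authors",
    "journal",
    "external",
    "isbn",
)


@dataclass
class PipelineResult:
    entries: list[HarmonizedEntry]
    pairs: list[CuratedPair]
    unique_pairs: list[CuratedPair]
    frozen: pd.DataFrame
    dropped_harmonization: int = 0
    dropped_realignment: Counter = field(default_factory=Counter)


def curate_tables(
    tables: Mapping[str, pd.DataFrame],
    mappings: Mapping[str, SourceMapping],
    services: FixtureServices,
    cache: CurationCache | None = None,
) -> PipelineResult:
    """Run the whole curation pipeline on raw per-source tables."""
    entries: list[HarmonizedEntry] = []
    dropped_harmonization = 0
    for source_id in sorted(tables):
        records = records_from_frame(tables[source_id], mappings[source_id])
        source_entries, dropped = harmonize(records, mappings[source_id], cache)
        entries.extend(source_entries)
        dropped_harmonization += dropped

    structure_memo: dict[tuple[str, str], StructureRecord] = {}
    organism_memo: dict[str, list[OrganismRecord]] = {}
    reference_memo: dict[tuple[str, str, str], ReferenceRecord] = {}

    structure_map: dict[tuple[str, int], StructureRecord] = {}
    organism_map: dict[tuple[str, int], Sequence[OrganismRecord]] = {}
    reference_map: dict[tuple[str, int], ReferenceRecord] = {}

    for entry in entries:
        key = (entry.source_id, entry.row_id)

        try:
            value, sub = select_descriptor(entry)
        except Exception:
            value = sub = None
        if value is not None:
            memo_key = (sub, value)
            if memo_key not in structure_memo:
                structure_memo[memo_key] = curate_structure(
                    value, sub, services.resolver_chain
                )
            structure_map[key] = structure_memo[memo_key]

        if entry.organism_value:
            if entry.organism_value not in organism_memo:
                organism_memo[entry.organism_value] = curate_organism(
                    entry.organism_value,
                    services.gazetteer,
                    services.dictionaries,
                )
            organism_map[key] = organism_memo[entry.organism_value]

        ref_sub = next(
            (s for s in REFERENCE_PRIORITY if entry.reference_values.get(s)),
            None,
        )
        if ref_sub is not None and ref_sub in RESOLVABLE_SUBCATEGORIES:
            organisms = organism_map.get(key, ())
            genus = (
                organisms[0].canonical.split()[0]
                if organisms and organisms[0].canonical
                else ""
            )
            ref_value = entry.reference_values[ref_sub]
            memo_key = (ref_sub, ref_value, genus)
            if memo_key not in reference_memo:
                reference_memo[memo_key] = curate_reference(
                    ref_value,
                    ref_sub,
                    genus,
                    services.provider,
                    services.id_map,
                )
            reference_map[key] = reference_memo[memo_key]

    pairs, dropped_realignment = realign(
        entries, structure_map, organism_map, reference_map
    )
    unique_pairs = deduplicate(pairs)
    apply_filter(unique_pairs)
    frozen = pairs_to_frame(unique_pairs)
    return PipelineResult(
        entries=entries,
        pairs=pairs,
        unique_pairs=unique_pairs,
        frozen=frozen,
        dropped_harmonization=dropped_harmonization,
        dropped_realignment=dropped_realignment,
    )


def curate_corpus(
    corpus: SyntheticCorpus,
    services: FixtureServices,
    cache: CurationCache | None = None,
) -> PipelineResult:
    return curate_tables(corpus.tables, corpus.mappings, services, cache)


def recovered_triples(result: PipelineResult) -> set[tuple[str, str, str]]:
    """(InChIKey, canonical organism, DOI) triples in the deduplicated
    output."""
    return {
        (p.structure.inchikey, p.organism.canonical, p.reference.doi)
        for p in result.unique_pairs
    }


def truth_triples(truth: pd.DataFrame) -> set[tuple[str, str, str]]:
    return {
        (r["inchikey"], r["organism_canonical"], r["reference_doi"])
        for _, r in truth.iterrows()
    }
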