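"""Realignment, deduplication and export of curated structure-organism-reference
triples.

After the three objects are curated independently, every original entry is
joined back to its curated structure(s), organism(s) and reference; only
entries complete on all three objects survive.  Deduplication is stereo-aware
(full InChIKey) with reference identity taken at DOI > PMID > title
precedence, and provenance lists are merged.  Two exporters emit (i) the
frozen tabular dataset with a fixed column order and row sort for
reproducible diffs, and (ii) a knowledge-base-ready minimal-field table with
the upload constraints applied (field-length drops, molecular-formula
subscripting, allowed taxon ranks and databases, skip of already-exported
rows).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from rdkit.Chem import rdMolDescriptors

from .cache import CurationCache
from .ingest import HarmonizedEntry
from .organisms import OrganismRecord
from .references import ReferenceRecord
from .structures import StructureRecord
from .validation import AUTO_VALIDATED, MANUALLY_VALIDATED, CuratedPair

#: Databases whose identifiers are admitted in the knowledge-base export.
KB_DATABASES = frozenset(
    {
        "ITIS",
        "GBIF Backbone Taxonomy",
        "NCBI",
        "Index Fungorum",
        "The Interim Register of Marine and Nonmarine Genera",
        "World Register of Marine Species",
        "WoRMS",
        "Database of Vascular Plants of Canada (VASCAN)",
        "iNaturalist",
        "Open Tree of Life",
    }
)

#: Taxon ranks admitted in the knowledge-base export.
KB_RANKS = frozenset(
    {"family", "subfamily", "tribe", "subtribe", "genus", "species", "variety"}
)

MAX_NAME_LENGTH = 250
MAX_INCHI_LENGTH = 1500

FROZEN_COLUMNS = [
    "structure_inchi",
    "structure_smiles",
    "structure_inchikey",
    "structure_planar_key",
    "structure_entity_class",
    "organism_canonical",
    "organism_db",
    "organism_taxon_id",
    "organism_unified_id",
    "organism_rank",
    "organism_family",
    "organism_domain",
    "organism_kingdom",
    "reference_title",
    "reference_doi",
    "reference_pmcid",
    "reference_pmid",
    "sources",
    "validation_status",
]


def realign(
    entries: Sequence[HarmonizedEntry],
    structure_map: Mapping[tuple[str, int], StructureRecord],
    organism_map: Mapping[tuple[str, int], Sequence[OrganismRecord]],
    reference_map: Mapping[tuple[str, int], ReferenceRecord],
) -> tuple[list[CuratedPair], Counter]:
    """Join original entries to their curated objects.

    One pair is emitted per (structure, organism, reference) combination of
    an entry; entries missing any curated object are dropped and counted by
    reason.
    """
    pairs: list[CuratedPair] = []
    dropped: Counter = Counter()
    for entry in entries:
        key = (entry.source_id, entry.row_id)
        structure = structure_map.get(key)
        organisms = organism_map.get(key, ())
        reference = reference_map.get(key)
        if structure is None or not structure.ok:
            dropped["structure"] += 1
            continue
        if not organisms:
            dropped["organism"] += 1
            continue
        if reference is None or not reference.ok:
            dropped["reference"] += 1
            continue
        for organism in organisms:
            pairs.append(
                CuratedPair(
                    structure=structure,
                    organism=organism,
                    reference=reference,
                    sources=[entry.source_id],
                )
            )
    return pairs, dropped


def _reference_identity(reference: ReferenceRecord) -> tuple[str, str]:
    """Reference identity at DOI > PMID > title precedence."""
    if reference.doi:
        return ("doi", reference.doi.casefold())
    if reference.pmid:
        return ("pmid", str(reference.pmid))
    return ("title", reference.title.casefold())


def pair_key(pair: CuratedPair) -> tuple:
    organism = pair.organism
    db = organism.taxon_refs[0][0] if organism.taxon_refs else ""
    return (
        pair.structure.inchikey,
        organism.canonical,
        db,
        _reference_identity(pair.reference),
    )


def deduplicate(pairs: Iterable[CuratedPair]) -> list[CuratedPair]:
    """Unique pairs on (full InChIKey, canonical name + taxonomy DB,
    reference identity), with provenance lists merged; insertion-ordered."""
    merged: dict[tuple, CuratedPair] = {}
    for pair in pairs:
        key = pair_key(pair)
        existing = merged.get(key)
        if existing is None:
            merged[key] = CuratedPair(
                structure=pair.structure,
                organism=pair.organism,
                reference=pair.reference,
                sources=list(pair.sources),
                validation_status=pair.validation_status,
                filter_reason=pair.filter_reason,
            )
        else:
            for source in pair.sources:
                if source not in existing.sources:
                    existing.sources.append(source)
    return list(merged.values())


def pairs_to_frame(pairs: Sequence[CuratedPair]) -> pd.DataFrame:
    rows = []
    for pair in pairs:
        organism = pair.organism
        db, taxon_id = organism.taxon_refs[0] if organism.taxon_refs else ("", "")
        rows.append(
            {
                "structure_inchi": pair.structure.resolved_inchi,
                "structure_smiles": pair.structure.resolved_smiles,
                "structure_inchikey": pair.structure.inchikey,
                "structure_planar_key": pair.structure.planar_key,
                "structure_entity_class": pair.structure.entity_class,
                "organism_canonical": organism.canonical,
                "organism_db": db,
                "organism_taxon_id": taxon_id,
                "organism_unified_id": organism.unified_id or "",
                "organism_rank": organism.rank,
                "organism_family": organism.family,
                "organism_domain": organism.domain,
                "organism_kingdom": organism.kingdom,
                "reference_title": pair.reference.title,
                "reference_doi": pair.reference.doi,
                "reference_pmcid": pair.reference.pmcid,
                "reference_pmid": pair.reference.pmid,
                "sources": "|".join(pair.sources),
                "validation_status": pair.validation_status,
            }
        )
    frame = pd.DataFrame(rows, columns=FROZEN_COLUMNS)
    return frame.sort_values(
        ["structure_planar_key", "organism_canonical", "reference_doi"],
        kind="mergesort",
    ).reset_index(drop=True)


def export_frozen(pairs: Sequence[CuratedPair] | pd.DataFrame, path: str | Path) -> pd.DataFrame:
    """Write the frozen tabular export (TSV, UTF-8, deterministic column
    order and row sort); returns the written frame."""
    frame = pairs if isinstance(pairs, pd.DataFrame) else pairs_to_frame(pairs)
    frame.to_csv(path, sep="\t", index=False, encoding="utf-8")
    return frame


def load_frozen(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


_SUBSCRIPT = str.maketrans("0123456789", "₀₁₂₃₄₅₆₇₈₉")


def subscript_formula(formula: str) -> str:
    """Molecular formula with digits as Unicode subscripts
    (C15H10O5 -> C₁₅H₁₀O₅)."""
    return formula.translate(_SUBSCRIPT)


@dataclass
class KbExportResult:
    table: pd.DataFrame
    skipped: list[dict] = field(default_factory=list)


def export_kb_ready(
    pairs: Sequence[CuratedPair],
    structure_names: Mapping[str, str] | None = None,
    cache: CurationCache | None = None,
) -> KbExportResult:
    """Minimal-field, knowledge-base-ready table from validated pairs.

    Constraints applied: molecule names longer than 250 characters are
    dropped from the name field (the structure row is kept); rows whose InChI
    exceeds 1500 characters omit the InChI; molecular formulas get Unicode
    subscript digits; taxa are restricted to the allowed rank and database
    lists; rows already exported (tracked in the cache) are filtered out.
    Every skip carries a reason code.
    """
    names = structure_names or {}
    rows = []
    skipped: list[dict] = []
    for pair in pairs:
        if pair.validation_status not in (AUTO_VALIDATED, MANUALLY_VALIDATED):
            skipped.append({"key": str(pair_key(pair)), "reason": "not_validated"})
            continue
        organism = pair.organism
        db = organism.taxon_refs[0][0] if organism.taxon_refs else ""
        if organism.rank not in KB_RANKS:
            skipped.append({"key": str(pair_key(pair)), "reason": "rank_not_allowed"})
            continue
        if db not in KB_DATABASES:
            skipped.append({"key": str(pair_key(pair)), "reason": "db_not_allowed"})
            continue
        key = str(pair_key(pair))
        if cache is not None and cache.contains("exported", key):
            skipped.append({"key": key, "reason": "already_exported"})
            continue
        name = names.get(pair.structure.planar_key, "")
        if len(name) > MAX_NAME_LENGTH:
            name = ""
        inchi_str = pair.structure.resolved_inchi
        if len(inchi_str) > MAX_INCHI_LENGTH:
            inchi_str = ""
        formula = ""
        if pair.structure.mol is not None:
            formula = subscript_formula(
                rdMolDescriptors.CalcMolFormula(pair.structure.mol)
            )
        rows.append(
            {
                "inchikey": pair.structure.inchikey,
                "inchi": inchi_str,
                "smiles": pair.structure.resolved_smiles,
                "name": name,
                "molecular_formula": formula,
                "entity_class": pair.structure.entity_class,
                "organism_canonical": organism.canonical,
                "organism_db": db,
                "organism_taxon_id": organism.taxon_refs[0][1]
                if organism.taxon_refs
                else "",
                "reference_doi": pair.reference.doi,
                "reference_pmid": pair.reference.pmid,
                "reference_pmcid": pair.reference.pmcid,
                "reference_title": pair.reference.title,
            }
        )
        if cache is not None:
            cache.put("exported", key, True)
    return KbExportResult(table=pd.DataFrame(rows), skipped=skipped)
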