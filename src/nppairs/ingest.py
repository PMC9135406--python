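"""Harmonization of raw per-source tables into the common sixteen-column-style
schema with subcategory labels.

Raw occurrence records arrive as heterogeneous tabular files, one layout per
source.  A declarative :class:`SourceMapping` (one config per source, the
stand-in for per-source tailored scripts) names which raw columns hold
structure, organism and reference information and with which subcategory.
Harmonization classifies each object field:

* structure values into ``inchi`` / ``smiles`` / ``name``,
* organism values into ``clean`` (a bare scientific name) / ``dirty``
  (anything else: organ words, isolation phrases, "spp.", ...),
* reference values into the ten reference subcategories
  (``authors, doi, external, isbn, journal, original, publishingDetails,
  pubmed, title, split``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml
from rdkit import Chem, RDLogger

from ._data import trigger_lexicon
from .cache import CurationCache

RDLogger.DisableLog("rdApp.*")

REFERENCE_SUBCATEGORIES = frozenset(
    {
        "authors",
        "doi",
        "external",
        "isbn",
        "journal",
        "original",
        "publishingDetails",
        "pubmed",
        "title",
        "split",
    }
)

STRUCTURE_SUBCATEGORIES = ("smiles", "inchi", "name")


class ConfigurationError(ValueError):
    """A source mapping references a column absent from the input table."""


class ClassificationError(ValueError):
    """A value violates the preconditions of a subcategory classifier."""


@dataclass(frozen=True)
class SourceMapping:
    """Declarative per-source column mapping.

    ``structure_columns`` maps raw column name -> subcategory hint
    (``"smiles"``, ``"inchi"``, ``"name"`` or ``None`` for auto-detection);
    ``reference_columns`` maps raw column name -> one of the ten reference
    subcategories.
    """

    source_id: str
    structure_columns: Mapping[str, str | None] = field(default_factory=dict)
    organism_column: str | None = None
    reference_columns: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = set(self.reference_columns.values()) - REFERENCE_SUBCATEGORIES
        if bad:
            raise ConfigurationError(
                f"unknown reference subcategories: {sorted(bad)}"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SourceMapping":
        with open(path, encoding="utf-8") as fh:
            cfg = yaml.safe_load(fh)
        return cls(
            source_id=cfg["source_id"],
            structure_columns=cfg.get("structure_columns", {}) or {},
            organism_column=cfg.get("organism_column"),
            reference_columns=cfg.get("reference_columns", {}) or {},
        )

    @property
    def columns(self) -> list[str]:
        cols = list(self.structure_columns) + list(self.reference_columns)
        if self.organism_column:
            cols.append(self.organism_column)
        return cols


@dataclass(frozen=True)
class RawSourceRecord:
    source_id: str
    row_id: int
    fields: Mapping[str, str]


@dataclass
class HarmonizedEntry:
    """One raw record in the harmonized schema.

    All available structure descriptors are retained (``structure_values``,
    one per subcategory); the downstream structure pipeline applies the
    descriptor preference order.  ``structure_value``/``structure_subcategory``
    expose the preferred descriptor.
    """

    source_id: str
    row_id: int
    structure_values: dict[str, str] = field(default_factory=dict)
    organism_value: str = ""
    organism_subcategory: str = ""
    reference_values: dict[str, str] = field(default_factory=dict)
    recomputed: bool = True

    @property
    def structure_subcategory(self) -> str:
        for sub in STRUCTURE_SUBCATEGORIES:
            if self.structure_values.get(sub):
                return sub
        return ""

    @property
    def structure_value(self) -> str:
        sub = self.structure_subcategory
        return self.structure_values.get(sub, "")

    def is_empty(self) -> bool:
        return not (
            any(self.structure_values.values())
            or self.organism_value
            or any(self.reference_values.values())
        )


def load_source(
    table_path: str | Path, mapping: SourceMapping
) -> list[RawSourceRecord]:
    """Read one raw source table (TSV or CSV, UTF-8, header row) into records.

    Row order is preserved; ``row_id`` is the 0-based data-row index.
    """
    path = Path(table_path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    return records_from_frame(frame, mapping)


def records_from_frame(
    frame: pd.DataFrame, mapping: SourceMapping
) -> list[RawSourceRecord]:
    """In-memory counterpart of :func:`load_source`."""
    missing = [c for c in mapping.columns if c not in frame.columns]
    if missing:
        raise ConfigurationError(
            f"mapping for source '{mapping.source_id}' references absent "
            f"column(s): {missing}"
        )
    return [
        RawSourceRecord(mapping.source_id, i, row)
        for i, row in enumerate(frame.to_dict(orient="records"))
    ]


def assign_structure_subcategory(value: str) -> str:
    """Classify a structure descriptor as ``inchi``, ``smiles`` or ``name``.

    InChI is recognized by its mandatory prefix; a value is a SMILES if RDKit
    parses it as a structure line notation; everything else is a chemical
    name.
    """
    if not value or not value.strip():
        raise ClassificationError("empty structure value")
    value = value.strip()
    if value.startswith("InChI="):
        return "inchi"
    if " " not in value and Chem.MolFromSmiles(value) is not None:
        return "smiles"
    return "name"


_WORDLIKE = re.compile(r"[^\W\d_]+(?:[.'-][^\W\d_]+)*\.?", re.UNICODE)
_BARE_NAME = re.compile(
    r"^[A-Z][a-zA-Z-]+(?: ×)?(?: [a-z][a-z-]+){0,3}$"
)


def _trigger_patterns() -> list[re.Pattern]:
    pats = []
    for token in trigger_lexicon():
        pats.append(re.compile(rf"(?<![\w.]){re.escape(token)}(?![\w])", re.IGNORECASE))
    return pats


_TRIGGERS: list[re.Pattern] | None = None


def assign_organism_subcategory(value: str) -> str:
    """Classify an organism field as ``clean`` (bare scientific name) or
    ``dirty`` (free text around / instead of the name).

    A packaged trigger lexicon (organ words, isolation phrases, "spp.",
    "cf.", locality words) marks a field dirty; fields that are not a
    plausible bare Latin name default to dirty as well.
    """
    global _TRIGGERS
    if not value or not value.strip():
        raise ClassificationError("empty organism value")
    value = value.strip()
    if _TRIGGERS is None:
        _TRIGGERS = _trigger_patterns()
    for pat in _TRIGGERS:
        if pat.search(value):
            return "dirty"
    return "clean" if _BARE_NAME.match(value) else "dirty"


def harmonize(
    records: Iterable[RawSourceRecord],
    mapping: SourceMapping,
    cache: CurationCache | None = None,
) -> tuple[list[HarmonizedEntry], int]:
    """Normalize raw records of one source into harmonized entries.

    Returns ``(entries, dropped)`` where *dropped* counts records with no
    usable field; rows in = entries out + dropped.  When a cache is given,
    previously harmonized identical rows are served from the store with
    ``recomputed=False`` so the same data is only curated once.
    """
    entries: list[HarmonizedEntry] = []
    dropped = 0
    for rec in records:
        key = f"{rec.source_id}\x1f" + "\x1f".join(
            f"{c}={rec.fields.get(c, '')}" for c in sorted(mapping.columns)
        )
        if cache is not None:
            hit = cache.get("harmonized", key)
            if hit is not None:
                if hit == "dropped":
                    dropped += 1
                    continue
                entry = HarmonizedEntry(**hit)
                entry.row_id = rec.row_id
                entry.recomputed = False
                entries.append(entry)
                continue
        entry = _harmonize_one(rec, mapping)
        if entry is None:
            dropped += 1
            if cache is not None:
                cache.put("harmonized", key, "dropped")
            continue
        entries.append(entry)
        if cache is not None:
            payload = {
                "source_id": entry.source_id,
                "row_id": entry.row_id,
                "structure_values": entry.structure_values,
                "organism_value": entry.organism_value,
                "organism_subcategory": entry.organism_subcategory,
                "reference_values": entry.reference_values,
            }
            cache.put("harmonized", key, payload)
    return entries, dropped


def _harmonize_one(
    rec: RawSourceRecord, mapping: SourceMapping
) -> HarmonizedEntry | None:
    structure_values: dict[str, str] = {}
    for col, hint in mapping.structure_columns.items():
        value = (rec.fields.get(col) or "").strip()
        if not value:
            continue
        sub = hint or assign_structure_subcategory(value)
        if sub == "name" and value.startswith("InChI="):
            sub = "inchi"
        structure_values.setdefault(sub, value)

    organism_value = ""
    organism_sub = ""
    if mapping.organism_column:
        organism_value = (rec.fields.get(mapping.organism_column) or "").strip()
        if organism_value:
            organism_sub = assign_organism_subcategory(organism_value)

    reference_values: dict[str, str] = {}
    for col, sub in mapping.reference_columns.items():
        value = (rec.fields.get(col) or "").strip()
        if value:
            reference_values[sub] = value

    entry = HarmonizedEntry(
        source_id=rec.source_id,
        row_id=rec.row_id,
        structure_values=structure_values,
        organism_value=organism_value,
        organism_subcategory=organism_sub,
        reference_values=reference_values,
    )
    return None if entry.is_empty() else entry


def entries_to_frame(entries: Sequence[HarmonizedEntry]) -> pd.DataFrame:
    """Tabular view of harmonized entries (one row per entry)."""
    rows = []
    for e in entries:
        row = {
            "source_id": e.source_id,
            "row_id": e.row_id,
            "structure_smiles": e.structure_values.get("smiles", ""),
            "structure_inchi": e.structure_values.get("inchi", ""),
            "structure_name": e.structure_values.get("name", ""),
            "organism_value": e.organism_value,
            "organism_subcategory": e.organism_subcategory,
        }
        for sub in sorted(REFERENCE_SUBCATEGORIES):
            row[f"reference_{sub}"] = e.reference_values.get(sub, "")
        rows.append(row)
    return pd.DataFrame(rows)
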