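"""Biological organism curation: dictionaries, name recognition, vernacular
translation and taxonomy unification.

The original organism field may hold a bare scientific name, free text around
one or more names, vernacular (common) names, or traditional-Chinese-medicine
drug names.  Curation proceeds as in the field's name-resolution toolchains:

1. scientific-name recognition against a gazetteer (the pluggable stand-in
   for a names-finder/verifier service),
2. subtraction of the recognized names from the text, so that epithets such
   as the "mango" of *Bromus mango* are not re-translated as common names,
3. longest-first vernacular/TCM translation using dictionaries built under
   the >50% genus/epithet consistency rule,
4. a second recognition pass on the translated text,
5. mapping of every canonical name to a unified-taxonomy identifier.

All accepted synonyms of a name are kept, each with its source database and
identifier; only databases on the packaged accepted list are admitted.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._data import (
    accepted_taxonomic_databases,
    latin_genitive_table,
    vernacular_stoplist,
)

PLANTAE, FUNGI, ANIMALIA, BACTERIA, EXCLUDED = (
    "Plantae",
    "Fungi",
    "Animalia",
    "Bacteria",
    "excluded",
)

#: Organ / drug-part words stripped from TCM names before translation.
TCM_ORGAN_WORDS = frozenset(
    {
        "radix",
        "rhizoma",
        "folium",
        "cortex",
        "semen",
        "fructus",
        "flos",
        "herba",
        "ramulus",
        "caulis",
        "pericarpium",
        "bulbus",
        "tuber",
        "root",
        "rhizome",
        "leaf",
        "bark",
        "seed",
        "fruit",
        "flower",
    }
)


@dataclass(frozen=True)
class TranslationPair:
    common_name: str
    canonical: str


@dataclass
class OrganismRecord:
    """One canonical organism resolved from a raw field."""

    original_value: str
    recognized_names: list[str] = field(default_factory=list)
    taxon_refs: list[tuple[str, str]] = field(default_factory=list)
    unified_id: str | None = None
    rank: str = ""
    family: str = ""
    domain: str = ""
    kingdom: str = ""
    flags: list[str] = field(default_factory=list)

    @property
    def canonical(self) -> str:
        return self.recognized_names[0] if self.recognized_names else ""


# ---------------------------------------------------------------------------
# dictionary construction


def _split_canonical(canonical: str) -> tuple[str, str | None, tuple[str, ...]]:
    tokens = canonical.split()
    genus = tokens[0]
    epithet = tokens[1] if len(tokens) > 1 else None
    return genus, epithet, tuple(tokens[2:])


def _sort_dictionary(pairs: Iterable[TranslationPair]) -> list[TranslationPair]:
    # longest common names first so they are translated before their parts;
    # lexicographic tie-break for reproducibility
    return sorted(
        set(pairs), key=lambda p: (-len(p.common_name), p.common_name, p.canonical)
    )


def build_common_dictionary(
    raw_pairs: Iterable[tuple[str, str]],
    stoplist: frozenset[str] | None = None,
) -> list[TranslationPair]:
    """Aggregate raw (common name, canonical name) pairs into a translation
    dictionary.

    Rules applied per common name:

    * names of three characters or fewer, and stop-listed unspecific names,
      are dropped;
    * a translation whose canonical adds a specific epithet to a common name
      that is itself the bare genus is discarded ("Aloe" -> "Aloe vera");
    * common names corresponding to a generic (genus-level) name are
      discarded ("Kiwi" -> *Apteryx* spp.);
    * with several candidate translations, genus and epithet counts decide:
      both consistent at strictly more than 50% keeps the consistent
      binomial(s) (including infraspecific variants), genus-only consistency
      keeps the bare genus, neither drops the name.

    The output is ordered by decreasing common-name length.
    """
    stop = vernacular_stoplist() if stoplist is None else stoplist
    grouped: dict[str, list[str]] = {}
    display: dict[str, str] = {}
    for common, canonical in raw_pairs:
        common = common.strip()
        canonical = re.sub(r"\s+", " ", canonical.strip())
        if not common or not canonical:
            continue
        key = common.casefold()
        grouped.setdefault(key, []).append(canonical)
        display.setdefault(key, common)

    out: list[TranslationPair] = []
    for key, canonicals in grouped.items():
        common = display[key]
        if len(common) <= 3 or key in stop:
            continue
        # generic-name vernaculars: any candidate that is itself genus-level
        if any(
            len(c.split()) == 1 or c.split()[1].rstrip(".") in ("sp", "spp")
            for c in canonicals
        ):
            continue
        # the bare-genus common name must not gain an epithet
        kept = [
            c
            for c in canonicals
            if not (
                _split_canonical(c)[1] is not None
                and key == _split_canonical(c)[0].casefold()
            )
        ]
        if not kept:
            continue
        n = len(kept)
        genus_counts = Counter(_split_canonical(c)[0] for c in kept)
        epithet_counts = Counter(_split_canonical(c)[1] for c in kept)
        top_genus, n_genus = genus_counts.most_common(1)[0]
        top_epithet, n_epithet = epithet_counts.most_common(1)[0]
        if n_genus / n > 0.5 and top_epithet is not None and n_epithet / n > 0.5:
            for c in sorted(set(kept)):
                genus, epithet, _ = _split_canonical(c)
                if genus == top_genus and epithet == top_epithet:
                    out.append(TranslationPair(common, c))
        elif n_genus / n > 0.5:
            out.append(TranslationPair(common, top_genus))
    return _sort_dictionary(out)


def build_tcm_dictionary(
    raw_pairs: Iterable[tuple[str, str]],
    stoplist: frozenset[str] | None = None,
    genitive_table: Mapping[str, str] | None = None,
) -> list[TranslationPair]:
    """Build the TCM-name dictionary.

    Organ/drug-part words (Radix, Rhizoma, Folium, ...) are stripped from the
    name before matching, Latin-genitive custom mappings are applied,
    stop-listed unspecific names are dropped, and the output is ordered by
    decreasing string length.
    """
    stop = vernacular_stoplist() if stoplist is None else stoplist
    genitives = latin_genitive_table() if genitive_table is None else {
        k.casefold(): v for k, v in genitive_table.items()
    }
    out: list[TranslationPair] = []
    for common, canonical in raw_pairs:
        common = common.strip()
        canonical = re.sub(r"\s+", " ", canonical.strip())
        if not common:
            continue
        words = [
            w for w in common.split() if w.casefold() not in TCM_ORGAN_WORDS
        ]
        stripped = " ".join(words)
        if len(stripped) <= 3 or stripped.casefold() in stop:
            continue
        mapped = genitives.get(stripped.casefold())
        if mapped is not None:
            canonical = mapped
        if not canonical:
            continue
        out.append(TranslationPair(stripped, canonical))
    return _sort_dictionary(out)


# ---------------------------------------------------------------------------
# recognition / translation


@dataclass(frozen=True)
class GazetteerEntry:
    canonical: str
    db: str
    taxon_id: str
    rank: str = "species"
    family: str = ""
    domain: str = ""
    kingdom: str = ""
    unified_id: str | None = None


@dataclass(frozen=True)
class RecognizedName:
    canonical: str
    db: str
    taxon_id: str
    start: int
    end: int
    matched_text: str


class Gazetteer:
    """Scientific-name matcher backed by a table of names.

    The local stand-in for a names-finder/verifier service: it recognizes
    canonical names and their listed synonyms inside free text
    (case-insensitive, word-bounded, longest match first) and returns every
    matching entry — all accepted synonyms are kept.  Only entries whose
    database is on the accepted-database list are admitted.
    """

    def __init__(self, entries: Mapping[str, Sequence[GazetteerEntry]]) -> None:
        accepted = accepted_taxonomic_databases()
        self._names: dict[str, list[GazetteerEntry]] = {}
        for name, entry_list in entries.items():
            kept = [e for e in entry_list if e.db in accepted]
            if kept:
                self._names[name.casefold()] = list(kept)
        self._patterns = [
            (re.compile(rf"(?<!\w){re.escape(name)}(?!\w)", re.IGNORECASE), name)
            for name in sorted(self._names, key=lambda n: (-len(n), n))
        ]

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Gazetteer":
        """Build from a table with columns canonical, synonyms (pipe
        separated, optional), db, taxon_id, rank, family, domain, kingdom,
        ott_id."""
        entries: dict[str, list[GazetteerEntry]] = {}
        for row in frame.to_dict(orient="records"):
            entry = GazetteerEntry(
                canonical=row["canonical"],
                db=row["db"],
                taxon_id=str(row["taxon_id"]),
                rank=row.get("rank", "species"),
                family=row.get("family", ""),
                domain=row.get("domain", ""),
                kingdom=row.get("kingdom", ""),
                unified_id=str(row["ott_id"]) if row.get("ott_id") else None,
            )
            names = [row["canonical"]]
            if row.get("synonyms"):
                names += [s for s in str(row["synonyms"]).split("|") if s]
            for name in names:
                entries.setdefault(name, []).append(entry)
        return cls(entries)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Gazetteer":
        return cls.from_frame(
            pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        )

    def entries_for(self, name: str) -> list[GazetteerEntry]:
        return list(self._names.get(name.casefold(), ()))

    def find(self, text: str) -> list[RecognizedName]:
        """All gazetteer matches in *text*, in input order; overlapping
        shorter matches are suppressed by earlier longer ones."""
        taken: list[tuple[int, int]] = []
        hits: list[RecognizedName] = []
        for pattern, name in self._patterns:
            for m in pattern.finditer(text):
                span = (m.start(), m.end())
                if any(s < span[1] and span[0] < e for s, e in taken):
                    continue
                taken.append(span)
                for entry in self._names[name]:
                    hits.append(
                        RecognizedName(
                            canonical=entry.canonical,
                            db=entry.db,
                            taxon_id=entry.taxon_id,
                            start=span[0],
                            end=span[1],
                            matched_text=m.group(0),
                        )
                    )
        hits.sort(key=lambda h: (h.start, h.canonical, h.db))
        return hits


def recognize_scientific(
    text: str, gazetteer: Gazetteer
) -> list[tuple[str, str, str]]:
    """Every matched canonical name with its source database and identifier,
    in input order; empty list when nothing matches."""
    return [(h.canonical, h.db, h.taxon_id) for h in gazetteer.find(text)]


def subtract_recognized(text: str, recognized: Sequence[RecognizedName]) -> str:
    """Remove the matched spans of recognized scientific names from *text* so
    their epithets cannot be re-translated as common names."""
    if not recognized:
        return text
    spans = sorted({(h.start, h.end) for h in recognized})
    out = []
    pos = 0
    for start, end in spans:
        out.append(text[pos:start])
        pos = max(pos, end)
    out.append(text[pos:])
    return "".join(out)


def translate_vernacular(
    text: str, dictionaries: Sequence[Sequence[TranslationPair]] | Sequence[TranslationPair]
) -> str:
    """Longest-first, non-overlapping replacement of common/TCM names by
    their canonical names (case-insensitive, word-bounded)."""
    if dictionaries and isinstance(dictionaries[0], TranslationPair):
        dictionaries = [dictionaries]  # type: ignore[list-item]
    merged: dict[str, str] = {}
    for dictionary in dictionaries:
        for pair in dictionary:
            merged.setdefault(pair.common_name.casefold(), pair.canonical)
    taken: list[tuple[int, int]] = []
    replacements: list[tuple[int, int, str]] = []
    for key in sorted(merged, key=lambda n: (-len(n), n)):
        pattern = re.compile(rf"(?<!\w){re.escape(key)}(?!\w)", re.IGNORECASE)
        for m in pattern.finditer(text):
            span = (m.start(), m.end())
            if any(s < span[1] and span[0] < e for s, e in taken):
                continue
            taken.append(span)
            replacements.append((span[0], span[1], merged[key]))
    out = text
    for start, end, canonical in sorted(replacements, reverse=True):
        out = out[:start] + canonical + out[end:]
    return out


# ---------------------------------------------------------------------------
# unified taxonomy


def unify_taxonomy(
    records: Sequence[OrganismRecord], gazetteer: Gazetteer
) -> list[OrganismRecord]:
    """Attach a unified-taxonomy identifier (and lineage) to each record via
    the pluggable taxonomy service; unmapped names are flagged, not
    dropped."""
    for rec in records:
        entry = next(
            (
                e
                for e in gazetteer.entries_for(rec.canonical)
                if e.unified_id is not None
            ),
            None,
        )
        if entry is None:
            rec.flags.append("unified_taxonomy_unmapped")
        else:
            rec.unified_id = entry.unified_id
            rec.rank = rec.rank or entry.rank
            rec.family = entry.family
            rec.domain = entry.domain
            rec.kingdom = entry.kingdom
    return records


_KINGDOM_GROUPS = {
    ("Eukaryota", "Archaeplastida"): PLANTAE,
    ("Eukaryota", "Fungi"): FUNGI,
    ("Eukaryota", "Metazoa"): ANIMALIA,
    ("Bacteria", "NA"): BACTERIA,
}


def group_kingdom(domain: str, kingdom: str | None) -> str:
    """Four-reservoir grouping from the two highest taxonomic levels:
    Eukaryota_Archaeplastida -> Plantae, Eukaryota_Fungi -> Fungi,
    Eukaryota_Metazoa -> Animalia, Bacteria_NA -> Bacteria; everything else
    (Eukaryota_NA is mostly algae) is excluded."""
    kingdom = kingdom if kingdom not in (None, "", "none", "None") else "NA"
    return _KINGDOM_GROUPS.get((domain, kingdom), EXCLUDED)


# ---------------------------------------------------------------------------
# full organism curation


def curate_organism(
    text: str,
    gazetteer: Gazetteer,
    dictionaries: Sequence[Sequence[TranslationPair]] = (),
) -> list[OrganismRecord]:
    """Raw organism field -> list of resolved organism records (one per
    distinct canonical name; all accepted synonyms kept inside each).

    Pipeline: recognition, subtraction of recognized names, vernacular/TCM
    translation of the remainder, re-recognition, taxonomy unification.
    """
    hits = gazetteer.find(text)
    remainder = subtract_recognized(text, hits)
    if dictionaries:
        translated = translate_vernacular(remainder, dictionaries)
        if translated != remainder:
            hits.extend(gazetteer.find(translated))
    by_canonical: dict[str, list[RecognizedName]] = {}
    for h in hits:
        by_canonical.setdefault(h.canonical, []).append(h)
    records = []
    for canonical in sorted(by_canonical):
        group = by_canonical[canonical]
        refs = sorted({(h.db, h.taxon_id) for h in group})
        records.append(
            OrganismRecord(
                original_value=text,
                recognized_names=[canonical],
                taxon_refs=refs,
            )
        )
    return unify_taxonomy(records, gazetteer)
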