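"""Loaders for the small data files packaged with nppairs.

Everything here is plain text shipped under ``nppairs/data``: the Greek-letter
replacement table, the clean/dirty trigger lexicon, the counterion SMARTS
list, vernacular stop-list, Latin-genitive mappings, the accepted taxonomic
database list and the synthetic fixture vocabularies (structures, organisms).
The fixture vocabularies are stand-ins labelled ``_synthetic``; drop-in
replacement by real dictionaries is a matter of pointing the loaders at other
files of the same shape.
"""

from __future__ import annotations

import functools
from importlib import resources

import pandas as pd


def _data_path(name: str):
    return resources.files("nppairs").joinpath("data", name)


def _read_lines(name: str) -> list[str]:
    text = _data_path(name).read_text(encoding="utf-8")
    out = []
    for line in text.splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


@functools.lru_cache(maxsize=None)
def greek_table() -> dict[str, str]:
    """Greek character -> ASCII word (empty string means strip)."""
    table = {}
    for line in _data_path("greek_letters.tsv").read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        parts = line.split("\t")
        table[parts[0]] = parts[1] if len(parts) > 1 else ""
    return table


@functools.lru_cache(maxsize=None)
def trigger_lexicon() -> tuple[str, ...]:
    """Tokens marking an organism field as 'dirty' (more than a bare name)."""
    return tuple(_read_lines("organism_triggers.txt"))


@functools.lru_cache(maxsize=None)
def counterion_data() -> str:
    """Counterion/solvent list in the tab-separated form rdMolStandardize
    FragmentRemoverFromData expects."""
    lines = [
        line
        for line in _data_path("counterions.tsv").read_text(encoding="utf-8").splitlines()
        if line.strip() and not line.startswith("#")
    ]
    return "\n".join(lines) + "\n"


@functools.lru_cache(maxsize=None)
def vernacular_stoplist() -> frozenset[str]:
    return frozenset(name.casefold() for name in _read_lines("vernacular_stoplist.txt"))


@functools.lru_cache(maxsize=None)
def latin_genitive_table() -> dict[str, str]:
    table = {}
    for line in _read_lines("latin_genitive.tsv"):
        key, canonical = line.split("\t")
        table[key.casefold()] = canonical
    return table


@functools.lru_cache(maxsize=None)
def accepted_taxonomic_databases() -> frozenset[str]:
    return frozenset(_read_lines("taxonomic_databases.txt"))


def structure_vocabulary() -> pd.DataFrame:
    """Synthetic fixture vocabulary of natural-product names, SMILES and a
    chemical class label (illustrative pairing, not an authoritative
    nomenclature source)."""
    with resources.as_file(_data_path("np_vocabulary_synthetic.tsv")) as path:
        return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def organism_vocabulary() -> pd.DataFrame:
    """Synthetic fixture gazetteer: canonical names with synonyms,
    vernaculars, one (database, id) pair, rank and OTL-style lineage."""
    with resources.as_file(_data_path("organisms_synthetic.tsv")) as path:
        return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
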