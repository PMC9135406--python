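"""Synthetic messy corpora with ground truth, and the offline fixture
services that make the full pipeline testable without any network.

The generator emulates the heterogeneity of real occurrence records: mixed
structure descriptors (InChI / SMILES / chemical names, with Greek letters
and salt adducts), clean and dirty organism strings (free text, vernacular
names), and noisy reference fields across the reference subcategories.
Every entry's intended (structure, organism, reference) triple and a
validity label are recorded in a ground-truth table, so end-to-end recovery
and filter quality can be measured exactly.

The corpus is deliberately engineered for unambiguous offline resolution of
uncorrupted entries (unique structure-organism combinations, one reference
per combination, retrieval-unique author tags): statistical realism beyond
exercising every code path is a non-goal.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import pandas as pd
from rdkit import Chem
from rdkit.Chem import inchi as rdinchi

from ._data import organism_vocabulary, structure_vocabulary
from .ingest import SourceMapping
from .organisms import (
    Gazetteer,
    TranslationPair,
    build_common_dictionary,
)
from .references import FixtureCandidateProvider, IdMap, ReferenceCandidate
from .structures import LocalDictionaryResolver, ResolverChain

SOURCES = ("SRC_A", "SRC_B", "COCONUT")

JOURNALS = (
    "Journal of Natural Products",
    "Phytochemistry",
    "Journal of Agricultural and Food Chemistry",
    "Planta Medica",
    "Fitoterapia",
    "Tetrahedron Letters",
    "Organic Letters",
    "Natural Product Research",
)

SURNAMES = (
    "Wijeratne", "Kingston", "Tanaka", "Müller", "Garcia", "Kim", "Nguyen",
    "Silva", "Okafor", "Petrov", "Rossi", "Dubois", "Hansen", "Yamada",
    "Costa", "Novak", "Schmidt", "Olsen", "Moreau", "Santos",
)

SALT_SUFFIXES = (".Cl", ".O", ".CO", ".CC(=O)O", ".[Na+].[Cl-]")

DIRTY_TEMPLATES = (
    "Compound isolated from the fresh leaves of {name}",
    "Stem bark of {name}",
    "Isolated from the roots of {name}",
    "Obtained from {name} extract",
    "Whole plant of {name}, collected in the field",
)

_GREEK_SWAP = (("alpha", "α"), ("beta", "ß"), ("gamma", "γ"), ("omega", "ω"))


@dataclass
class CorpusSpec:
    """Conditions under which a synthetic corpus is generated.

    Mixture proportions must sum to 1 per object; noise rates lie in [0, 1].
    Reference weight is put on the six subcategories the pipeline translates
    (doi, pubmed, title, original, split, publishingDetails); the remaining
    four (authors, journal, external, isbn) are carried through harmonization
    but have no translation route, so their default weight is zero.
    """

    seed: int = 42
    n_entries: int = 1000
    structure_mix: dict[str, float] = field(
        default_factory=lambda: {"smiles": 0.4, "inchi": 0.3, "name": 0.3}
    )
    organism_mix: dict[str, float] = field(
        default_factory=lambda: {"clean": 0.7, "dirty": 0.3}
    )
    reference_mix: dict[str, float] = field(
        default_factory=lambda: {
            "doi": 0.25,
            "pubmed": 0.12,
            "title": 0.25,
            "original": 0.2,
            "split": 0.1,
            "publishingDetails": 0.08,
            "authors": 0.0,
            "journal": 0.0,
            "external": 0.0,
            "isbn": 0.0,
        }
    )
    greek_rate: float = 0.3
    salt_rate: float = 0.15
    vernacular_rate: float = 0.3
    citation_corruption_rate: float = 0.2
    wrong_pair_rate: float = 0.0
    duplicate_rate: float = 0.1

    def validate(self) -> None:
        for label, mix in (
            ("structure_mix", self.structure_mix),
            ("organism_mix", self.organism_mix),
            ("reference_mix", self.reference_mix),
        ):
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError(f"{label} proportions must sum to 1")
            if any(v < 0 for v in mix.values()):
                raise ValueError(f"{label} proportions must be non-negative")
        for label in (
            "greek_rate",
            "salt_rate",
            "vernacular_rate",
            "citation_corruption_rate",
            "wrong_pair_rate",
            "duplicate_rate",
        ):
            rate = getattr(self, label)
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{label} must lie in [0, 1]")


@dataclass
class SyntheticCorpus:
    spec: CorpusSpec
    tables: dict[str, pd.DataFrame]
    mappings: dict[str, SourceMapping]
    truth: pd.DataFrame
    references: list[ReferenceCandidate]
    structure_names: dict[str, str]  # planar key -> vocabulary name
    chemical_classes: dict[str, str]  # planar key -> class label


@dataclass
class FixtureServices:
    """Offline fixture implementations of every external service interface."""

    resolver_chain: ResolverChain
    gazetteer: Gazetteer
    dictionaries: list[list[TranslationPair]]
    provider: FixtureCandidateProvider
    id_map: IdMap
    chemical_classes: dict[str, str]


def _choose(rng: random.Random, mix: dict[str, float]) -> str:
    labels = sorted(mix)
    return rng.choices(labels, weights=[mix[l] for l in labels], k=1)[0]


def _corrupt(rng: random.Random, text: str, max_edits: int = 4) -> str:
    """A few character-level edits (sub/del/insert/swap), keeping the string
    within OSA distance max_edits of the original."""
    chars = list(text)
    for _ in range(rng.randint(1, max_edits)):
        if len(chars) < 4:
            break
        op = rng.choice("sdis")
        pos = rng.randrange(1, len(chars) - 1)
        if op == "s":
            chars[pos] = rng.choice("abcdefghijklmnopqrstuvwxyz")
        elif op == "d":
            del chars[pos]
        elif op == "i":
            chars.insert(pos, rng.choice("abcdefghijklmnopqrstuvwxyz"))
        else:
            chars[pos], chars[pos - 1] = chars[pos - 1], chars[pos]
    return "".join(chars)


def _greekify(rng: random.Random, name: str) -> str:
    for word, char in _GREEK_SWAP:
        if word in name:
            return name.replace(word, char, 1)
    return name


RAW_COLUMNS = [
    "structure_smiles",
    "structure_inchi",
    "structure_name",
    "organism",
    "ref_authors",
    "ref_doi",
    "ref_external",
    "ref_isbn",
    "ref_journal",
    "ref_original",
    "ref_publishingDetails",
    "ref_pubmed",
    "ref_title",
    "ref_split",
]


def _source_mapping(source_id: str) -> SourceMapping:
    return SourceMapping(
        source_id=source_id,
        structure_columns={
            "structure_smiles": "smiles",
            "structure_inchi": "inchi",
            "structure_name": "name",
        },
        organism_column="organism",
        reference_columns={
            f"ref_{sub}": sub
            for sub in (
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
            )
        },
    )


def generate_corpus(spec: CorpusSpec) -> SyntheticCorpus:
    """Deterministic synthetic corpus for the given spec.

    Entries are distinct (structure, organism) combinations, each with its
    own synthesized reference; corruptions are applied per the spec's rates,
    and ``wrong_pair_rate`` swaps in a reference that documents a different
    organism (the entry's validity label is then False).
    """
    spec.validate()
    rng = random.Random(spec.seed)
    vocab = structure_vocabulary().to_dict(orient="records")
    organisms = organism_vocabulary().to_dict(orient="records")
    n_combos = len(vocab) * len(organisms)
    if spec.n_entries > n_combos:
        raise ValueError(
            f"n_entries {spec.n_entries} exceeds the {n_combos} distinct "
            "structure-organism combinations available"
        )
    combos = rng.sample(range(n_combos), spec.n_entries)

    # precompute structure identity
    mols = {}
    for row in vocab:
        mol = Chem.MolFromSmiles(row["smiles"])
        key = rdinchi.MolToInchiKey(mol)
        mols[row["name"]] = (mol, key, key[:14])

    structure_names = {mols[r["name"]][2]: r["name"] for r in vocab}
    chemical_classes = {
        mols[r["name"]][2]: r["chemical_class"] for r in vocab
    }

    references: list[ReferenceCandidate] = []
    raw_rows: dict[str, list[dict]] = {s: [] for s in SOURCES}
    truth_rows: list[dict] = []

    for i, combo in enumerate(combos):
        s_row = vocab[combo // len(organisms)]
        o_row = organisms[combo % len(organisms)]
        mol, inchikey, planar = mols[s_row["name"]]
        valid = rng.random() >= spec.wrong_pair_rate

        if valid:
            ref_subject = o_row["canonical"]
            title = f"Isolation of {s_row['name']} from {ref_subject}"
        else:
            other = organisms[(combo + 7) % len(organisms)]
            ref_subject = other["canonical"]
            title = f"Occurrence of {s_row['name']} in {ref_subject} revisited"
        journal = JOURNALS[3 + (i % (len(JOURNALS) - 3))]  # non-whitelist span
        if i % 9 == 0:
            journal = JOURNALS[i % 3]  # sprinkle the three whitelist journals
        year = str(1960 + (i % 60))
        author = f"{SURNAMES[i % len(SURNAMES)]}-{i:04d}"
        doi = f"10.5281/SYNTH.{i:05d}"
        pmid = str(100000 + i)
        vol = str(10 + i % 90)
        pages = f"{100 + i % 800}-{110 + i % 800}"
        reference = ReferenceCandidate(
            doi=doi,
            title=title,
            journal=journal,
            year=year,
            first_author=author,
            pmid=pmid,
        )
        references.append(reference)

        # ---- structure field
        structure_sub = _choose(rng, spec.structure_mix)
        cells = {c: "" for c in RAW_COLUMNS}
        if structure_sub == "smiles":
            smiles = s_row["smiles"]
            if rng.random() < spec.salt_rate:
                smiles += rng.choice(SALT_SUFFIXES)
            cells["structure_smiles"] = smiles
        elif structure_sub == "inchi":
            cells["structure_inchi"] = rdinchi.MolToInchi(mol)
        else:
            name = s_row["name"]
            if rng.random() < spec.greek_rate:
                name = _greekify(rng, name)
            cells["structure_name"] = name

        # ---- organism field
        organism_sub = _choose(rng, spec.organism_mix)
        vernaculars = [v for v in o_row["vernaculars"].split("|") if v]
        display_name = o_row["canonical"]
        if vernaculars and rng.random() < spec.vernacular_rate:
            display_name = rng.choice(vernaculars)
        if organism_sub == "dirty":
            organism_value = rng.choice(DIRTY_TEMPLATES).format(name=display_name)
        else:
            organism_value = display_name
        cells["organism"] = organism_value

        # ---- reference field
        ref_sub = _choose(rng, spec.reference_mix)
        if ref_sub == "doi":
            value = doi
        elif ref_sub == "pubmed":
            value = pmid
        elif ref_sub == "title":
            value = title
            if rng.random() < spec.citation_corruption_rate:
                value = _corrupt(rng, value)
        elif ref_sub == "original":
            value = f"{author} E. M. K., {title}, {journal}, {vol}, {pages} ({year})."
        elif ref_sub == "split":
            value = f"{title}. {journal} ({year})"
        elif ref_sub == "publishingDetails":
            value = f"{author}, {journal}, {vol}: {pages}, {year}"
        elif ref_sub == "authors":
            value = f"{author} E. M. K."
        elif ref_sub == "journal":
            value = journal
        elif ref_sub == "external":
            value = "also in knapsack"
        else:  # isbn
            value = f"ISBN 978-3-{i:05d}-00-1"
        cells[f"ref_{ref_sub}"] = value

        source = SOURCES[i % len(SOURCES)]
        emit_in = [source]
        if rng.random() < spec.duplicate_rate:
            emit_in.append(SOURCES[(i + 1) % len(SOURCES)])
        for src in emit_in:
            raw_rows[src].append(dict(cells))
            truth_rows.append(
                {
                    "entry_id": i,
                    "source_id": src,
                    "row_id": len(raw_rows[src]) - 1,
                    "structure_name": s_row["name"],
                    "structure_smiles": s_row["smiles"],
                    "inchikey": inchikey,
                    "planar_key": planar,
                    "organism_canonical": o_row["canonical"],
                    "organism_value": organism_value,
                    "organism_subcategory": organism_sub,
                    "reference_doi": doi,
                    "reference_subcategory": ref_sub,
                    "valid": valid,
                }
            )

    tables = {
        src: pd.DataFrame(rows, columns=RAW_COLUMNS)
        for src, rows in raw_rows.items()
    }
    mappings = {src: _source_mapping(src) for src in SOURCES}
    return SyntheticCorpus(
        spec=spec,
        tables=tables,
        mappings=mappings,
        truth=pd.DataFrame(truth_rows),
        references=references,
        structure_names=structure_names,
        chemical_classes=chemical_classes,
    )


def build_fixture_services(corpus: SyntheticCorpus) -> FixtureServices:
    """Fixture services sufficient for 100% resolution of uncorrupted
    entries: local name->structure dictionary, gazetteer, vernacular
    dictionary, candidate-reference store and DOI/PMID/PMCID map."""
    vocab = structure_vocabulary()
    name_table = dict(zip(vocab["name"], vocab["smiles"]))
    chain = ResolverChain([LocalDictionaryResolver(name_table)])

    organisms = organism_vocabulary()
    gazetteer = Gazetteer.from_frame(organisms)
    raw_pairs = []
    for row in organisms.to_dict(orient="records"):
        for vern in str(row["vernaculars"]).split("|"):
            if vern:
                raw_pairs.append((vern, row["canonical"]))
    dictionaries = [build_common_dictionary(raw_pairs)]

    provider = FixtureCandidateProvider(corpus.references)
    id_map = IdMap(
        {"DOI": r.doi, "PMID": r.pmid, "PMCID": f"PMC{r.pmid}"}
        for r in corpus.references
    )
    return FixtureServices(
        resolver_chain=chain,
        gazetteer=gazetteer,
        dictionaries=dictionaries,
        provider=provider,
        id_map=id_map,
        chemical_classes=dict(corpus.chemical_classes),
    )
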