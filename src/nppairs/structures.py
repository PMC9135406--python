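"""Chemical structure translation and sanitization.

Any structure descriptor (SMILES, InChI or chemical name) is translated to an
RDKit molecule, standardized, stripped of counterion/solvent fragments,
neutralized, and reported as canonical SMILES + InChI + InChIKey.  The first
14 characters of the InChIKey (the *planar key*) identify the structure
without stereochemistry; structures whose stereocenters and stereogenic bonds
are all specified are classed as chemical compounds, the rest as groups of
stereoisomers.

Name resolution runs through an ordered :class:`ResolverChain` whose first
member is a local dictionary; remote resolvers (systematic-name parser,
compound-name service, identifier-resolver service) are optional, off by
default, and plug in behind the same one-callable interface, so the whole
pipeline is deterministic and offline with the defaults.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem import inchi as rdinchi
from rdkit.Chem.MolStandardize import rdMolStandardize

from ._data import counterion_data, greek_table
from .ingest import HarmonizedEntry

RDLogger.DisableLog("rdApp.*")

INCHIKEY_RE = re.compile(r"^[A-Z]{14}-[A-Z]{10}-[A-Z]$")

CHEMICAL_COMPOUND = "chemical_compound"
STEREOISOMER_GROUP = "stereoisomer_group"


class StructureError(ValueError):
    pass


@dataclass
class StructureRecord:
    """A resolved and (optionally) sanitized structure with its audit trail."""

    input_value: str
    input_subcategory: str
    mol: object | None = None
    resolved_smiles: str = ""
    resolved_inchi: str = ""
    inchikey: str = ""
    planar_key: str = ""
    stereo_fully_defined: bool = False
    entity_class: str = ""
    status: str = "pending"  # pending | sanitized | unresolved | rejected
    audit: list[tuple[str, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return self.status == "sanitized"

    def log(self, stage: str, outcome: str) -> None:
        self.audit.append((stage, outcome))


Resolver = Callable[[str], str | None]  # prepared name -> SMILES or None


class LocalDictionaryResolver:
    """Name -> SMILES lookup against a local dictionary (case-insensitive)."""

    name = "local_dictionary"

    def __init__(self, table: Mapping[str, str]) -> None:
        self._table = {k.casefold(): v for k, v in table.items()}

    def __call__(self, name: str) -> str | None:
        return self._table.get(name.casefold())


@dataclass
class ResolverChain:
    """Ordered name resolvers; the first success wins.

    The default chain contains only the local dictionary; remote services are
    appended explicitly by the caller when online operation is wanted.
    """

    resolvers: Sequence[Resolver] = ()

    def resolve(self, name: str) -> tuple[str | None, list[tuple[str, str]]]:
        trail = []
        for resolver in self.resolvers:
            label = getattr(resolver, "name", resolver.__class__.__name__)
            smiles = resolver(name)
            if smiles:
                trail.append((label, "hit"))
                return smiles, trail
            trail.append((label, "miss"))
        return None, trail


_SIGN_PREFIX = re.compile(r"^\((?:\+|-|−|\+/-|±)\)-?\s*")


def prepare_name(raw: str) -> str:
    """Normalize a chemical name before resolution.

    Greek letters are replaced by their ASCII words via the packaged table
    (α-pinene -> alpha-pinene), optical-rotation sign prefixes ((+)-, (−)-,
    (±)-) are stripped, and whitespace is collapsed; case is preserved.
    """
    if not raw:
        raise StructureError("empty name")
    out = _SIGN_PREFIX.sub("", raw.strip())
    for char, word in greek_table().items():
        if char in out:
            out = out.replace(char, word)
    return re.sub(r"\s+", " ", out).strip()


def select_descriptor(entry: HarmonizedEntry) -> tuple[str, str]:
    """Pick the preferred structure descriptor of a harmonized entry:
    structural identifiers over names, and SMILES over InChI."""
    for sub in ("smiles", "inchi", "name"):
        value = entry.structure_values.get(sub, "")
        if value:
            return value, sub
    raise StructureError("entry has no structure field")


def resolve_structure(
    value: str, subcategory: str, chain: ResolverChain | None = None
) -> StructureRecord:
    """Translate a descriptor into an (unsanitized) structure record.

    Names go through :func:`prepare_name` and then the resolver chain; InChI
    and SMILES are parsed directly.  Failures leave the record with status
    ``unresolved`` and the failing stage in the audit log.
    """
    rec = StructureRecord(input_value=value, input_subcategory=subcategory)
    mol = None
    if subcategory == "smiles":
        mol = Chem.MolFromSmiles(value)
        rec.log("parse_smiles", "ok" if mol is not None else "fail")
    elif subcategory == "inchi":
        mol = rdinchi.MolFromInchi(value)
        rec.log("parse_inchi", "ok" if mol is not None else "fail")
    elif subcategory == "name":
        prepared = prepare_name(value)
        rec.log("prepare_name", prepared)
        smiles, trail = (chain or ResolverChain()).resolve(prepared)
        rec.audit.extend(trail)
        if smiles is not None:
            mol = Chem.MolFromSmiles(smiles)
            rec.log("parse_resolved_smiles", "ok" if mol is not None else "fail")
    else:
        raise StructureError(f"unknown structure subcategory: {subcategory}")
    if mol is None:
        rec.status = "unresolved"
    else:
        rec.mol = mol
    return rec


_FRAGMENT_REMOVER = None
_UNCHARGER = None


def _tools():
    global _FRAGMENT_REMOVER, _UNCHARGER
    if _FRAGMENT_REMOVER is None:
        _FRAGMENT_REMOVER = rdMolStandardize.FragmentRemoverFromData(
            counterion_data(), leave_last=True
        )
        _UNCHARGER = rdMolStandardize.Uncharger()
    return _FRAGMENT_REMOVER, _UNCHARGER


def sanitize(record: StructureRecord) -> StructureRecord:
    """Standardize a resolved structure in place.

    Stages, in order: standardization (valence check, explicit-H removal,
    metal disconnection, normalization, acid reionization, stereochemistry
    recalculation — rdMolStandardize ``Cleanup``), counterion/solvent
    fragment removal driven by the packaged SMARTS list, neutralization, and
    finally the dimer rule: any structure still containing a ``.`` in its
    SMILES is discarded.  On success fills SMILES/InChI/InChIKey/planar key
    and the stereo entity class; idempotent on already-sanitized records.
    """
    if record.mol is None:
        if record.status == "pending":
            record.status = "unresolved"
        return record
    remover, uncharger = _tools()
    try:
        mol = rdMolStandardize.Cleanup(record.mol)
        record.log("standardize", "ok")
        mol = remover.remove(mol)
        record.log("remove_fragments", "ok")
        mol = uncharger.uncharge(mol)
        record.log("uncharge", "ok")
    except Exception as exc:  # unparsable after standardization
        record.status = "rejected"
        record.log("standardize", f"fail: {exc}")
        return record
    smiles = Chem.MolToSmiles(mol)
    if "." in smiles:
        record.status = "rejected"
        record.log("dimer_rule", "discarded: multiple fragments remain")
        return record
    inchi_str = rdinchi.MolToInchi(mol)
    if not inchi_str:
        record.status = "rejected"
        record.log("to_inchi", "fail")
        return record
    record.mol = mol
    record.resolved_smiles = smiles
    record.resolved_inchi = inchi_str
    record.inchikey = rdinchi.MolToInchiKey(mol)
    record.planar_key = planarize(record.inchikey)
    record.entity_class = stereo_classify(record)
    record.stereo_fully_defined = record.entity_class == CHEMICAL_COMPOUND
    record.status = "sanitized"
    return record


def stereo_classify(record: StructureRecord) -> str:
    """``chemical_compound`` iff every potential stereocenter and stereogenic
    bond is specified (vacuously true for achiral molecules), else
    ``stereoisomer_group``."""
    if record.mol is None:
        raise StructureError("record has no molecule")
    for element in Chem.FindPotentialStereo(record.mol):
        if element.specified != Chem.StereoSpecified.Specified:
            return STEREOISOMER_GROUP
    return CHEMICAL_COMPOUND


def planarize(inchikey: str) -> str:
    """First 14 characters (connectivity block) of a 27-character InChIKey."""
    if not INCHIKEY_RE.match(inchikey or ""):
        raise StructureError(f"malformed InChIKey: {inchikey!r}")
    return inchikey[:14]


def curate_structure(
    value: str, subcategory: str, chain: ResolverChain | None = None
) -> StructureRecord:
    """Resolve then sanitize a single descriptor."""
    return sanitize(resolve_structure(value, subcategory, chain))


def curate_entry_structure(
    entry: HarmonizedEntry, chain: ResolverChain | None = None
) -> StructureRecord:
    value, sub = select_descriptor(entry)
    return curate_structure(value, sub, chain)
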