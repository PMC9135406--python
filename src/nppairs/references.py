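"""Bibliographic reference resolution: candidate retrieval, scoring and
lexicographic re-ranking.

A raw reference field (a DOI, a PMID, a title, or degraded free text) is
resolved to a concrete article via a candidate provider.  Free-text queries
return up to twenty candidates ranked by the provider's tf-idf-style
relevance score; identifier subcategories return at most one, and DOIs are
round-trip verified so dead identifiers are discarded.  Because the relevance
score alone is not informative enough, candidates are re-ranked with three
further metrics before the first one is selected:

* presence of the producing organism's genus in the candidate title (0/1),
* for free-text subcategories, a complement score counting how many of
  {journal, first author's family name, publication year} appear in the
  original string (0-3),
* for identifier/title subcategories, the optimal-string-alignment
  (restricted Damerau-Levenshtein) distance between input and candidate.
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

COMPLEMENT_SUBCATEGORIES = frozenset({"original", "publishingDetails", "split"})
DISTANCE_SUBCATEGORIES = frozenset({"doi", "pubmed", "title"})
RESOLVABLE_SUBCATEGORIES = COMPLEMENT_SUBCATEGORIES | DISTANCE_SUBCATEGORIES


def osa_distance(a: str, b: str) -> int:
    """Optimal string alignment (restricted Damerau-Levenshtein) distance.

    Unit-cost insertions, deletions, substitutions and adjacent
    transpositions, with the restriction that no substring is edited twice —
    hence osa("CA", "ABC") == 3 while the unrestricted variant gives 2.
    """
    n, m = len(a), len(b)
    if n == 0:
        return m
    if m == 0:
        return n
    prev2: list[int] = []
    prev = list(range(m + 1))
    for i in range(1, n + 1):
        cur = [i] + [0] * m
        for j in range(1, m + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost)
            if (
                i > 1
                and j > 1
                and a[i - 1] == b[j - 2]
                and a[i - 2] == b[j - 1]
            ):
                cur[j] = min(cur[j], prev2[j - 2] + 1)
        prev2, prev = prev, cur
    return prev[m]


@dataclass(frozen=True)
class ReferenceCandidate:
    doi: str = ""
    title: str = ""
    journal: str = ""
    year: str = ""
    first_author: str = ""
    pmid: str = ""
    relevance: float = 0.0  # retrieval engine's tf-idf-style score


@dataclass(frozen=True)
class ScoreVector:
    relevance: float
    title_organism: int
    complement: int | None = None  # only for original/publishingDetails/split
    distance: int | None = None  # only for doi/pubmed/title


@dataclass
class ReferenceRecord:
    subcategory: str
    original_value: str
    selected: ReferenceCandidate | None = None
    scores: ScoreVector | None = None
    pmid: str = ""
    pmcid: str = ""
    status: str = "pending"  # resolved | unresolved

    @property
    def ok(self) -> bool:
        return self.status == "resolved"

    @property
    def doi(self) -> str:
        return self.selected.doi if self.selected else ""

    @property
    def title(self) -> str:
        return self.selected.title if self.selected else ""


_TOKEN_RE = re.compile(r"[a-z0-9]+")


def _tokens(text: str) -> list[str]:
    return _TOKEN_RE.findall(text.casefold())


class FixtureCandidateProvider:
    """Offline candidate provider backed by a reference corpus.

    ``query`` ranks the stored references by a deterministic token-overlap
    relevance score: each shared token contributes its inverse document
    frequency, so rare tokens (author names, unusual words) dominate —
    a tf-idf-style score.  Ties preserve store order (stable).
    """

    def __init__(self, candidates: Iterable[ReferenceCandidate]) -> None:
        self._store = list(candidates)
        self._docs = [
            set(
                _tokens(
                    " ".join((c.title, c.journal, c.first_author, c.year))
                )
            )
            for c in self._store
        ]
        df: dict[str, int] = {}
        for doc in self._docs:
            for tok in doc:
                df[tok] = df.get(tok, 0) + 1
        n = max(len(self._store), 1)
        self._idf = {tok: math.log(1 + n / cnt) for tok, cnt in df.items()}
        self._by_doi = {}
        self._by_pmid = {}
        for c in self._store:
            if c.doi:
                self._by_doi.setdefault(c.doi.casefold(), c)
            if c.pmid:
                self._by_pmid.setdefault(str(c.pmid), c)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FixtureCandidateProvider":
        with open(path, encoding="utf-8", newline="") as fh:
            rows = list(csv.DictReader(fh, delimiter="\t"))
        return cls(
            ReferenceCandidate(
                doi=r.get("doi", ""),
                title=r.get("title", ""),
                journal=r.get("journal", ""),
                year=str(r.get("year", "")),
                first_author=r.get("first_author", ""),
                pmid=str(r.get("pmid", "")),
            )
            for r in rows
        )

    def query(self, text: str, limit: int = 20) -> list[ReferenceCandidate]:
        toks = set(_tokens(text))
        scored = []
        for idx, doc in enumerate(self._docs):
            score = sum(self._idf[t] for t in toks & doc)
            if score > 0:
                scored.append((-score, idx))
        scored.sort()
        return [
            ReferenceCandidate(
                **{
                    **self._store[idx].__dict__,
                    "relevance": -neg,
                }
            )
            for neg, idx in scored[:limit]
        ]

    def lookup_doi(self, doi: str) -> ReferenceCandidate | None:
        hit = self._by_doi.get(doi.strip().casefold())
        if hit is None:
            return None
        return ReferenceCandidate(**{**hit.__dict__, "relevance": 1.0})

    def lookup_pmid(self, pmid: str) -> ReferenceCandidate | None:
        hit = self._by_pmid.get(pmid.strip())
        if hit is None:
            return None
        return ReferenceCandidate(**{**hit.__dict__, "relevance": 1.0})


def fetch_candidates(
    value: str,
    subcategory: str,
    provider,
    limit: int = 20,
) -> list[ReferenceCandidate]:
    """Retrieve candidates for a raw reference value.

    Identifier subcategories (``doi``, ``pubmed``) keep a single round-trip
    verified candidate; free-text subcategories keep the first *limit*
    candidates in provider score order.  An empty list means unresolved.
    """
    value = value.strip()
    if not value:
        return []
    if subcategory == "doi":
        hit = provider.lookup_doi(value)
        return [hit] if hit is not None else []
    if subcategory == "pubmed":
        digits = re.sub(r"\D", "", value)
        hit = provider.lookup_pmid(digits or value)
        return [hit] if hit is not None else []
    return provider.query(value, limit=limit)


_PUNCT_RE = re.compile(r"[^\w\s]")


def _clean(text: str) -> str:
    return re.sub(r"\s+", " ", _PUNCT_RE.sub(" ", text.casefold())).strip()


def _contains_word(haystack: str, needle: str) -> bool:
    if not needle:
        return False
    return bool(
        re.search(rf"(?<!\w){re.escape(_clean(needle))}(?!\w)", _clean(haystack))
    )


def score_candidate(
    subcategory: str,
    original_value: str,
    organism_genus: str,
    candidate: ReferenceCandidate,
) -> ScoreVector:
    """Compute the re-ranking score vector for one candidate.

    ``title_organism`` is 1 iff the organism genus occurs (case-insensitive,
    word-bounded) in the candidate title.  For the free-text subcategories
    the complement counts journal, first-author family name and 4-digit
    publication year found in the original string; for identifier/title
    subcategories the OSA distance compares like with like (doi <-> doi,
    pmid <-> pmid, title <-> title) on casefolded text.
    """
    title_organism = 1 if _contains_word(candidate.title, organism_genus) else 0
    complement: int | None = None
    distance: int | None = None
    if subcategory in COMPLEMENT_SUBCATEGORIES:
        complement = 0
        if candidate.journal and _contains_word(original_value, candidate.journal):
            complement += 1
        family = candidate.first_author.split(",")[0].split()[0] if candidate.first_author else ""
        if family and _contains_word(original_value, family):
            complement += 1
        if candidate.year and re.search(
            rf"(?<!\d){re.escape(str(candidate.year))}(?!\d)", original_value
        ):
            complement += 1
    elif subcategory in DISTANCE_SUBCATEGORIES:
        own = {
            "doi": candidate.doi,
            "pubmed": str(candidate.pmid),
            "title": candidate.title,
        }[subcategory]
        distance = osa_distance(original_value.strip().casefold(), own.strip().casefold())
    return ScoreVector(
        relevance=candidate.relevance,
        title_organism=title_organism,
        complement=complement,
        distance=distance,
    )


def rank_and_select(
    subcategory: str,
    original_value: str,
    scored: Sequence[tuple[ReferenceCandidate, ScoreVector]],
) -> ReferenceRecord:
    """Stable lexicographic re-ranking: relevance desc, complement desc
    (where applicable), title-organism desc, distance asc; the first
    candidate is selected."""
    record = ReferenceRecord(subcategory=subcategory, original_value=original_value)
    if not scored:
        record.status = "unresolved"
        return record
    indexed = list(enumerate(scored))
    indexed.sort(
        key=lambda item: (
            -item[1][1].relevance,
            -(item[1][1].complement if item[1][1].complement is not None else 0),
            -item[1][1].title_organism,
            item[1][1].distance if item[1][1].distance is not None else 0,
            item[0],
        )
    )
    _, (candidate, scores) = indexed[0]
    record.selected = candidate
    record.scores = scores
    record.pmid = str(candidate.pmid)
    record.status = "resolved"
    return record


class IdMap:
    """DOI <-> PMID <-> PMCID completion map (PMC-ids style CSV subset)."""

    def __init__(self, rows: Iterable[dict]) -> None:
        self._by_doi: dict[str, tuple[str, str]] = {}
        self._by_pmid: dict[str, tuple[str, str]] = {}
        self.warnings: list[str] = []
        for row in rows:
            doi = (row.get("DOI") or "").strip().casefold()
            pmcid = (row.get("PMCID") or "").strip()
            pmid = (row.get("PMID") or "").strip()
            if not (doi or pmid):
                self.warnings.append(f"skipped malformed row: {row}")
                continue
            if doi:
                if doi in self._by_doi:
                    self.warnings.append(f"duplicate DOI {doi}: first wins")
                else:
                    self._by_doi[doi] = (pmid, pmcid)
            if pmid:
                if pmid in self._by_pmid:
                    self.warnings.append(f"duplicate PMID {pmid}: first wins")
                else:
                    self._by_pmid[pmid] = (doi, pmcid)

    @classmethod
    def from_csv(cls, path: str | Path) -> "IdMap":
        with open(path, encoding="utf-8", newline="") as fh:
            return cls(csv.DictReader(fh))


def map_identifiers(record: ReferenceRecord, id_map: IdMap) -> ReferenceRecord:
    """Complete DOI/PMID/PMCID on a resolved record where the map allows;
    absent mappings leave the fields empty."""
    if not record.ok or record.selected is None:
        return record
    doi = record.selected.doi.strip().casefold()
    if doi and doi in id_map._by_doi:
        pmid, pmcid = id_map._by_doi[doi]
        record.pmid = record.pmid or pmid
        record.pmcid = record.pmcid or pmcid
    elif record.pmid and record.pmid in id_map._by_pmid:
        _, pmcid = id_map._by_pmid[record.pmid]
        record.pmcid = record.pmcid or pmcid
    return record


def curate_reference(
    value: str,
    subcategory: str,
    organism_genus: str,
    provider,
    id_map: IdMap | None = None,
) -> ReferenceRecord:
    """Full resolution of one raw reference field."""
    candidates = fetch_candidates(value, subcategory, provider)
    scored = [
        (c, score_candidate(subcategory, value, organism_genus, c))
        for c in candidates
    ]
    record = rank_and_select(subcategory, value, scored)
    if id_map is not None:
        record = map_identifiers(record, id_map)
    return record
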