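"""Reference resolution: OSA distance, candidate retrieval, scoring,
re-ranking and identifier mapping."""

import random
from functools import lru_cache

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nppairs import (
    FixtureCandidateProvider,
    IdMap,
    ReferenceCandidate,
    fetch_candidates,
    map_identifiers,
    osa_distance,
    rank_and_select,
    score_candidate,
)
from nppairs.references import ReferenceRecord, curate_reference


def osa_oracle(a: str, b: str) -> int:
    """Brute-force recursive formulation of the restricted
    Damerau-Levenshtein distance, memoized; independent of the DP table
    implementation under test."""

    @lru_cache(maxsize=None)
    def go(i: int, j: int) -> int:
        if i == len(a):
            return len(b) - j
        if j == len(b):
            return len(a) - i
        best = min(
            go(i + 1, j) + 1,  # delete
            go(i, j + 1) + 1,  # insert
            go(i + 1, j + 1) + (a[i] != b[j]),  # substitute / match
        )
        if (
            i + 1 < len(a)
            and j + 1 < len(b)
            and a[i] == b[j + 1]
            and a[i + 1] == b[j]
        ):
            best = min(best, go(i + 2, j + 2) + 1)  # adjacent transposition
        return best

    return go(0, 0)


class TestOsaDistance:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("abc", "abc", 0),
            ("ab", "ba", 1),
            ("CA", "ABC", 3),  # witnesses the restricted variant
            ("", "abc", 3),
            ("kitten", "sitting", 3),
        ],
    )
    def test_known_values(self, a, b, expected):
        assert osa_distance(a, b) == expected

    def test_matches_oracle_on_random_pairs(self):
        rng = random.Random(20211220)
        alphabet = "abcdefgh"
        for _ in range(10_000):
            a = "".join(rng.choices(alphabet, k=rng.randint(0, 12)))
            b = "".join(rng.choices(alphabet, k=rng.randint(0, 12)))
            assert osa_distance(a, b) == osa_oracle(a, b)

    @settings(max_examples=200, derandomize=True)
    @given(
        st.text(alphabet="abcde", max_size=15),
        st.text(alphabet="abcde", max_size=15),
        st.text(alphabet="abcde", max_size=15),
    )
    def test_oracle_symmetry_and_bounds(self, a, b, c):
        assert osa_distance(a, b) == osa_oracle(a, b)
        assert osa_distance(a, b) == osa_distance(b, a)
        assert abs(len(a) - len(b)) <= osa_distance(a, b) <= max(len(a), len(b))

    def test_metric_properties(self):
        rng = random.Random(5)
        for _ in range(300):
            a = "".join(rng.choices("abcd", k=rng.randint(0, 8)))
            b = "".join(rng.choices("abcd", k=rng.randint(0, 8)))
            d = osa_distance(a, b)
            assert d == osa_distance(b, a)
            assert (d == 0) == (a == b)
            assert d <= max(len(a), len(b))


@pytest.fixture
def provider():
    return FixtureCandidateProvider(
        [
            ReferenceCandidate(
                doi="10.1/AAA",
                title="Alkaloids from Cyathocalyx species",
                journal="Journal of Natural Products",
                year="1995",
                first_author="Wijeratne",
                pmid="11111",
            ),
            ReferenceCandidate(
                doi="10.1/BBB",
                title="Terpenoids of Abies alba needles",
                journal="Phytochemistry",
                year="1999",
                first_author="Muller",
                pmid="22222",
            ),
            ReferenceCandidate(
                doi="10.1/CCC",
                title="Steroids from marine sponges",
                journal="Planta Medica",
                year="2005",
                first_author="Garcia",
                pmid="33333",
            ),
        ]
    )


class TestFetchCandidates:
    def test_doi_subcategory_single_candidate(self, provider):
        hits = fetch_candidates("10.1/AAA", "doi", provider)
        assert len(hits) == 1
        assert hits[0].title.startswith("Alkaloids")

    def test_dead_doi_unresolved(self, provider):
        assert fetch_candidates("10.9/DEAD", "doi", provider) == []

    def test_pubmed_lookup(self, provider):
        hits = fetch_candidates("PMID: 22222", "pubmed", provider)
        assert len(hits) == 1
        assert hits[0].doi == "10.1/BBB"

    def test_free_text_cap(self):
        many = FixtureCandidateProvider(
            [
                ReferenceCandidate(doi=f"10.1/{i}", title=f"shared topic paper {i}")
                for i in range(25)
            ]
        )
        hits = many.query("shared topic", limit=20)
        assert len(hits) == 20
        # store-score order: ties keep store order
        assert hits[0].doi == "10.1/0"

    def test_empty_value_unresolved(self, provider):
        assert fetch_candidates("   ", "title", provider) == []


class TestScoreCandidate:
    def test_genus_in_title_scores_one(self, provider):
        candidate = provider.query("Cyathocalyx")[0]
        scores = score_candidate("original", "whatever", "Cyathocalyx", candidate)
        assert scores.title_organism == 1
        scores = score_candidate("original", "whatever", "Rosa", candidate)
        assert scores.title_organism == 0

    def test_identical_titles_distance_zero(self, provider):
        candidate = provider.query("Cyathocalyx")[0]
        scores = score_candidate(
            "title", "Alkaloids from Cyathocalyx species", "X", candidate
        )
        assert scores.distance == 0
        assert scores.complement is None

    def test_complement_counts_journal_author_year(self, provider):
        candidate = provider.query("Cyathocalyx")[0]
        original = "Wijeratne et al. (1995) some alkaloid paper"
        scores = score_candidate("original", original, "X", candidate)
        assert scores.complement == 2  # author + year, journal absent
        assert scores.distance is None
        full = "Wijeratne, Journal of Natural Products, 1995"
        assert score_candidate("original", full, "X", candidate).complement == 3


class TestRankAndSelect:
    def _scored(self, *pairs):
        return [(c, s) for c, s in pairs]

    def test_title_organism_breaks_relevance_tie(self, provider):
        a = ReferenceCandidate(doi="10.1/a", title="no genus here", relevance=5.0)
        b = ReferenceCandidate(doi="10.1/b", title="Cyathocalyx paper", relevance=5.0)
        record = rank_and_select(
            "original",
            "x",
            [
                (a, score_candidate("original", "x", "Cyathocalyx", a)),
                (b, score_candidate("original", "x", "Cyathocalyx", b)),
            ],
        )
        assert record.selected.doi == "10.1/b"

    def test_single_candidate_selected(self, provider):
        c = provider.query("sponges")[0]
        record = rank_and_select(
            "title", "Steroids", [(c, score_candidate("title", "Steroids", "X", c))]
        )
        assert record.ok and record.selected.doi == "10.1/CCC"

    def test_full_tie_keeps_input_order(self):
        a = ReferenceCandidate(doi="10.1/a", title="same", relevance=1.0)
        b = ReferenceCandidate(doi="10.1/b", title="same", relevance=1.0)
        record = rank_and_select(
            "original",
            "x",
            [
                (a, score_candidate("original", "x", "X", a)),
                (b, score_candidate("original", "x", "X", b)),
            ],
        )
        assert record.selected.doi == "10.1/a"

    def test_order_invariance_except_ties(self):
        candidates = [
            ReferenceCandidate(doi=f"10.1/{i}", title="t", relevance=float(i))
            for i in range(5)
        ]
        scored = [
            (c, score_candidate("original", "x", "X", c)) for c in candidates
        ]
        forward = rank_and_select("original", "x", scored)
        backward = rank_and_select("original", "x", scored[::-1])
        assert forward.selected.doi == backward.selected.doi == "10.1/4"

    def test_empty_candidates_unresolved(self):
        record = rank_and_select("title", "x", [])
        assert record.status == "unresolved"


class TestIdMap:
    def test_doi_to_pmcid(self):
        id_map = IdMap(
            [{"DOI": "10.1/AAA", "PMCID": "PMC9", "PMID": "11111"}]
        )
        record = ReferenceRecord(
            subcategory="doi",
            original_value="10.1/AAA",
            selected=ReferenceCandidate(doi="10.1/AAA"),
            status="resolved",
        )
        record = map_identifiers(record, id_map)
        assert (record.pmid, record.pmcid) == ("11111", "PMC9")

    def test_absent_doi_leaves_fields_empty(self):
        id_map = IdMap([{"DOI": "10.1/AAA", "PMCID": "PMC9", "PMID": "1"}])
        record = ReferenceRecord(
            subcategory="doi",
            original_value="10.1/ZZZ",
            selected=ReferenceCandidate(doi="10.1/ZZZ"),
            status="resolved",
        )
        record = map_identifiers(record, id_map)
        assert (record.pmid, record.pmcid) == ("", "")

    def test_conflicting_duplicates_first_wins_with_warning(self):
        id_map = IdMap(
            [
                {"DOI": "10.1/AAA", "PMCID": "PMC1", "PMID": "1"},
                {"DOI": "10.1/AAA", "PMCID": "PMC2", "PMID": "2"},
            ]
        )
        assert id_map._by_doi["10.1/aaa"] == ("1", "PMC1")
        assert any("duplicate" in w for w in id_map.warnings)

    def test_malformed_row_skipped_with_warning(self):
        id_map = IdMap([{"DOI": "", "PMCID": "PMC1", "PMID": ""}])
        assert any("malformed" in w for w in id_map.warnings)


class TestCurateReference:
    def test_free_text_citation_resolves_to_best_candidate(self, provider):
        record = curate_reference(
            "Wijeratne E. M. K., J. Nat. Prod., 58, 459-462 (1995).",
            "original",
            "Cyathocalyx",
            provider,
        )
        assert record.ok
        assert record.doi == "10.1/AAA"
        assert record.scores.complement == 2  # author + year in the original
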