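"""Distribution, specificity and intersection statistics."""

import itertools
import random

import numpy as np
import pandas as pd
import pytest

from nppairs import (
    distribution_stats,
    family_filter,
    jaccard_specificity,
    jsd_specificity,
    source_intersections,
    specificity_table,
)


def make_table(rows):
    """rows: (planar_key, chemical_class, organism, family, kingdom, domain,
    source)"""
    return pd.DataFrame(
        rows,
        columns=[
            "planar_key",
            "chemical_class",
            "organism",
            "family",
            "kingdom",
            "domain",
            "source",
        ],
    )


PLANT = ("Archaeplastida", "Eukaryota")
FUNGUS = ("Fungi", "Eukaryota")


def row(key, cls, org, family="F1", kingdom="Archaeplastida", domain="Eukaryota", source="A"):
    return (key, cls, org, family, kingdom, domain, source)


class TestDistributionStats:
    def test_two_structures_one_organism(self):
        table = make_table([row("K1", "c", "O1"), row("K2", "c", "O1")])
        stats = distribution_stats(table)
        assert stats.mean_structures_per_organism == 2
        assert stats.mean_organisms_per_structure == 1

    def test_single_pair_all_ones(self):
        stats = distribution_stats(make_table([row("K1", "c", "O1")]))
        assert stats.mean_organisms_per_structure == 1
        assert stats.median_structures_per_organism == 1

    def test_duplicate_rows_do_not_inflate(self):
        table = make_table([row("K1", "c", "O1"), row("K1", "c", "O1", source="B")])
        stats = distribution_stats(table)
        assert stats.mean_organisms_per_structure == 1

    def test_empty_table_error(self):
        with pytest.raises(ValueError):
            distribution_stats(make_table([]))


class TestSpecificityTable:
    def test_structure_in_one_group_is_specific(self):
        table = make_table(
            [
                row("K1", "c1", "O1"),
                row("K2", "c2", "O2", kingdom="Fungi"),
            ]
        )
        result = specificity_table(table)
        assert result.loc["Plantae", "specific_structures"] == 1
        assert result.loc["Fungi", "specific_structures"] == 1

    def test_shared_structure_specific_to_neither(self):
        table = make_table(
            [
                row("K1", "c1", "O1"),
                row("K1", "c1", "O2", kingdom="Fungi"),
            ]
        )
        result = specificity_table(table)
        assert result.loc["Plantae", "specific_structures"] == 0
        assert result.loc["Fungi", "specific_structures"] == 0
        # and it contributes to at most one group's specific column overall
        assert result["specific_structures"].sum() == 0

    def test_excluded_group_ignored(self):
        table = make_table(
            [
                row("K1", "c1", "O1"),
                row("K2", "c2", "O3", kingdom="NA"),  # Eukaryota_NA -> excluded
            ]
        )
        result = specificity_table(table)
        assert result["structures"].sum() == 1

    def test_counts_equal_exhaustive_enumeration(self):
        rng = random.Random(3)
        kingdoms = ["Archaeplastida", "Fungi", "Metazoa"]
        rows = []
        for _ in range(60):
            k = f"K{rng.randint(1, 10)}"
            kd = rng.choice(kingdoms)
            rows.append(row(k, f"c{rng.randint(1,4)}", f"O{rng.randint(1,8)}_{kd}", kingdom=kd))
        table = make_table(rows)
        result = specificity_table(table)
        # brute-force set oracle
        group_of = {"Archaeplastida": "Plantae", "Fungi": "Fungi", "Metazoa": "Animalia"}
        seen: dict[str, set] = {}
        for r in rows:
            seen.setdefault(r[0], set()).add(group_of[r[4]])
        for group in ("Plantae", "Fungi", "Animalia"):
            expected_structures = {k for k, g in seen.items() if group in g}
            expected_specific = {k for k, g in seen.items() if g == {group}}
            assert result.loc[group, "structures"] == len(expected_structures)
            assert result.loc[group, "specific_structures"] == len(expected_specific)


class TestJsd:
    def test_identical_distributions_give_zero(self):
        # single class: its distribution equals the background
        table = make_table(
            [row("K1", "c1", "O1", family="Fa"), row("K2", "c1", "O2", family="Fb")]
        )
        assert jsd_specificity(table, "c1", "family") == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_supports_give_one(self):
        # many background pairs in Fb, the focal class confined to Fa
        rows = [row(f"K{i}", "bg", f"O{i}", family="Fb") for i in range(400)]
        rows.append(row("KX", "focal", "OX", family="Fa"))
        table = make_table(rows)
        assert jsd_specificity(table, "focal", "family") == pytest.approx(1.0, abs=0.02)

    def test_symmetry_and_bounds(self):
        from scipy.spatial.distance import jensenshannon

        rng = np.random.default_rng(11)
        for _ in range(50):
            p = rng.random(6)
            q = rng.random(6)
            d1 = jensenshannon(p, q, base=2) ** 2
            d2 = jensenshannon(q, p, base=2) ** 2
            assert d1 == pytest.approx(d2, abs=1e-12)
            assert -1e-12 <= d1 <= 1 + 1e-12

    def test_unknown_level_error(self):
        with pytest.raises(ValueError):
            jsd_specificity(make_table([row("K1", "c", "O1")]), "c", "no_such_level")


class TestJaccard:
    def test_identical_sets(self):
        table = make_table([row("K1", "c1", "O1", family="Fa")])
        assert jaccard_specificity(table, "c1", "Fa") == 1.0

    def test_disjoint_sets(self):
        table = make_table(
            [row("K1", "c1", "O1", family="Fa"), row("K2", "c2", "O2", family="Fb")]
        )
        assert jaccard_specificity(table, "c1", "Fb") == 0.0

    def test_one_third_overlap(self):
        # class {a, b}; family {b, c}
        table = make_table(
            [
                row("a", "c1", "O1", family="Fx"),
                row("b", "c1", "O2", family="Fy"),
                row("b", "c2", "O2", family="Fy"),
                row("c", "c2", "O3", family="Fy"),
            ]
        )
        assert jaccard_specificity(table, "c1", "Fy") == pytest.approx(1 / 3)

    def test_empty_sets_error(self):
        with pytest.raises(ValueError):
            jaccard_specificity(make_table([row("K1", "c1", "O1")]), "zz", "Fz")


class TestSourceIntersections:
    def test_exclusive_combination_counts(self):
        table = make_table(
            [
                row("K1", "c", "O1", source="A"),
                row("K1", "c", "O2", source="A"),
                row("K1", "c", "O2", source="B"),
            ]
        )
        combos = source_intersections(table, structure="K1")
        assert combos == {frozenset({"A"}): 1, frozenset({"A", "B"}): 1}

    def test_single_source(self):
        table = make_table([row("K1", "c", f"O{i}", source="A") for i in range(4)])
        assert source_intersections(table, structure="K1") == {frozenset({"A"}): 4}

    def test_matches_power_set_enumeration(self):
        rng = random.Random(8)
        sources = list("ABCDEFGHIJ")[: rng.randint(3, 10)]
        rows = []
        for _ in range(100):
            rows.append(
                row("K", "c", f"O{rng.randint(1, 12)}", source=rng.choice(sources))
            )
        table = make_table(rows)
        combos = source_intersections(table, structure="K")
        # brute-force: for every subset of sources, count organisms whose
        # exact source set equals it
        membership: dict[str, set] = {}
        for r in rows:
            membership.setdefault(r[2], set()).add(r[6])
        for size in range(1, len(sources) + 1):
            for subset in itertools.combinations(sources, size):
                expected = sum(
                    1 for s in membership.values() if s == set(subset)
                )
                assert combos.get(frozenset(subset), 0) == expected

    def test_organism_focus(self):
        table = make_table(
            [
                row("K1", "c", "O1", source="A"),
                row("K2", "c", "O1", source="B"),
            ]
        )
        combos = source_intersections(table, organism="O1")
        assert combos == {frozenset({"A"}): 1, frozenset({"B"}): 1}

    def test_requires_exactly_one_focus(self):
        table = make_table([row("K1", "c", "O1")])
        with pytest.raises(ValueError):
            source_intersections(table)


class TestFamilyFilter:
    def test_threshold_boundary(self):
        rows = [row(f"K{i}", "c", "O1", family="Fa") for i in range(49)]
        rows += [row(f"K{i}", "c", "O2", family="Fb") for i in range(50)]
        table = make_table(rows)
        filtered = family_filter(table, min_structures=50)
        assert set(filtered["family"]) == {"Fb"}

    def test_min_zero_is_identity(self):
        table = make_table([row("K1", "c", "O1")])
        assert family_filter(table, 0).equals(table)

    def test_matches_manual_count(self):
        rng = random.Random(2)
        rows = [
            row(f"K{rng.randint(1, 30)}", "c", "O", family=f"F{rng.randint(1, 5)}")
            for _ in range(80)
        ]
        table = make_table(rows)
        counts = {
            fam: len({r[0] for r in rows if r[3] == fam})
            for fam in {r[3] for r in rows}
        }
        filtered = family_filter(table, min_structures=8)
        assert set(filtered["family"]) == {f for f, c in counts.items() if c >= 8}
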