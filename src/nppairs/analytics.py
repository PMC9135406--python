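"""Dataset-level statistics on curated structure-organism pairs.

All metrics work on a *pair table*: one row per (planar structure key,
organism) observation with the chemical class label, taxonomy lineage
(family, kingdom, domain) and source identifier.  Counting is always over
distinct (planar key, taxon) pairs so that multiply-referenced occurrences do
not inflate any statistic.

The chemotaxonomic specificity scores:

* per chemical class, a Jensen-Shannon divergence (base-2 logarithm, hence
  bounded by [0, 1]) between the class's distribution over taxa at a chosen
  level and the background distribution of all pairs — 1 means the class is
  confined to taxa where little else occurs (highly specific), 0 that it is
  distributed like the background (ubiquitous);
* per (chemical class, biological family), a Jaccard index between the two
  sets of planar structure keys.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon

from .organisms import EXCLUDED, group_kingdom

#: Expected pair-table columns.
PAIR_COLUMNS = [
    "planar_key",
    "chemical_class",
    "organism",
    "family",
    "kingdom",
    "domain",
    "source",
]


def _distinct_pairs(table: pd.DataFrame) -> pd.DataFrame:
    return table.drop_duplicates(subset=["planar_key", "organism"])


@dataclass(frozen=True)
class DistributionStats:
    organisms_per_structure: pd.Series
    structures_per_organism: pd.Series
    mean_organisms_per_structure: float
    median_organisms_per_structure: float
    mean_structures_per_organism: float
    median_structures_per_organism: float


def distribution_stats(table: pd.DataFrame) -> DistributionStats:
    """Marginal count distributions over distinct (planar key, organism)
    pairs, with their means and medians."""
    if table.empty:
        raise ValueError("empty pair table")
    pairs = _distinct_pairs(table)
    ops = pairs.groupby("planar_key")["organism"].nunique()
    spo = pairs.groupby("organism")["planar_key"].nunique()
    return DistributionStats(
        organisms_per_structure=ops,
        structures_per_organism=spo,
        mean_organisms_per_structure=float(ops.mean()),
        median_organisms_per_structure=float(ops.median()),
        mean_structures_per_organism=float(spo.mean()),
        median_structures_per_organism=float(spo.median()),
    )


def specificity_table(table: pd.DataFrame) -> pd.DataFrame:
    """Per-reservoir (Plantae / Fungi / Animalia / Bacteria) counts of
    organisms, distinct 2D pairs, planar structures, reservoir-specific
    structures, chemical classes and reservoir-specific classes.

    'Specific' means present in exactly one of the four groups; rows mapping
    outside the four groups are excluded.
    """
    work = table.copy()
    work["group"] = [
        group_kingdom(d, k) for d, k in zip(work["domain"], work["kingdom"])
    ]
    work = work[work["group"] != EXCLUDED]
    pairs = work.drop_duplicates(subset=["planar_key", "organism", "group"])
    structure_groups = pairs.groupby("planar_key")["group"].agg(set)
    class_pairs = work[work["chemical_class"] != ""].drop_duplicates(
        subset=["chemical_class", "group"]
    )
    class_groups = class_pairs.groupby("chemical_class")["group"].agg(set)
    rows = []
    for group in ("Plantae", "Fungi", "Animalia", "Bacteria"):
        sub = pairs[pairs["group"] == group]
        structures = set(sub["planar_key"])
        specific = {s for s in structures if structure_groups[s] == {group}}
        classes = set(
            work.loc[
                (work["group"] == group) & (work["chemical_class"] != ""),
                "chemical_class",
            ]
        )
        specific_classes = {c for c in classes if class_groups[c] == {group}}
        rows.append(
            {
                "group": group,
                "organisms": sub["organism"].nunique(),
                "pairs": len(sub),
                "structures": len(structures),
                "specific_structures": len(specific),
                "specific_structures_pct": 100 * len(specific) / len(structures)
                if structures
                else 0.0,
                "classes": len(classes),
                "specific_classes": len(specific_classes),
                "specific_classes_pct": 100 * len(specific_classes) / len(classes)
                if classes
                else 0.0,
            }
        )
    return pd.DataFrame(rows).set_index("group")


def jensen_shannon(p, q) -> float:
    """Base-2 Jensen-Shannon divergence between two non-negative weight
    vectors (normalized internally): 0 for identical distributions, 1 for
    disjoint supports."""
    distance = jensenshannon(np.asarray(p, float), np.asarray(q, float), base=2)
    value = float(distance * distance)
    if np.isnan(value):
        return 0.0
    return float(min(max(value, 0.0), 1.0))


def jsd_specificity(table: pd.DataFrame, class_label: str, level: str) -> float:
    """Base-2 Jensen-Shannon divergence between the class's distribution of
    distinct (planar key, taxon) pairs over taxa at *level* and the same
    distribution over all pairs; 0 for identical distributions, 1 for
    disjoint supports."""
    if level not in table.columns:
        raise ValueError(f"unknown lineage level: {level}")
    work = table[table[level] != ""]
    pairs = work.drop_duplicates(subset=["planar_key", level])
    class_pairs = pairs[pairs["chemical_class"] == class_label]
    if class_pairs.empty:
        raise ValueError(f"class {class_label!r} has no pairs at level {level!r}")
    taxa = sorted(set(pairs[level]))
    p = class_pairs[level].value_counts().reindex(taxa, fill_value=0).to_numpy(float)
    q = pairs[level].value_counts().reindex(taxa, fill_value=0).to_numpy(float)
    return jensen_shannon(p, q)


def jaccard_specificity(table: pd.DataFrame, class_label: str, family: str) -> float:
    """Jaccard index between the planar-key sets of a chemical class and a
    biological family."""
    class_set = set(table.loc[table["chemical_class"] == class_label, "planar_key"])
    family_set = set(table.loc[table["family"] == family, "planar_key"])
    union = class_set | family_set
    if not union:
        raise ValueError("both sets are empty")
    return len(class_set & family_set) / len(union)


def source_intersections(
    table: pd.DataFrame,
    structure: str | None = None,
    organism: str | None = None,
) -> dict[frozenset, int]:
    """Exclusive source-combination counts (UpSet semantics).

    For a focal planar key, the count of organisms per exact source
    combination; for a focal organism, the count of planar keys per
    combination.
    """
    if (structure is None) == (organism is None):
        raise ValueError("pass exactly one of structure= or organism=")
    if structure is not None:
        sub = table[table["planar_key"] == structure]
        member_col = "organism"
    else:
        sub = table[table["organism"] == organism]
        member_col = "planar_key"
    combos: dict[frozenset, int] = {}
    for _, sources in sub.groupby(member_col)["source"].agg(set).items():
        key = frozenset(sources)
        combos[key] = combos.get(key, 0) + 1
    return combos


def family_filter(table: pd.DataFrame, min_structures: int = 50) -> pd.DataFrame:
    """Keep only rows whose biological family covers at least
    ``min_structures`` distinct planar keys."""
    counts = table.groupby("family")["planar_key"].nunique()
    keep = set(counts[counts >= min_structures].index)
    return table[table["family"].isin(keep)].reset_index(drop=True)


def frozen_to_pair_table(
    frame: pd.DataFrame, classes: dict[str, str] | None = None
) -> pd.DataFrame:
    """Adapt a frozen export frame to the pair-table schema, attaching
    chemical class labels per planar key from the enrichment interface."""
    classes = classes or {}
    table = pd.DataFrame(
        {
            "planar_key": frame["structure_planar_key"],
            "chemical_class": [
                classes.get(k, "") for k in frame["structure_planar_key"]
            ],
            "organism": frame["organism_canonical"],
            "family": frame["organism_family"],
            "kingdom": frame["organism_kingdom"],
            "domain": frame["organism_domain"],
            "source": frame["sources"].str.split("|")
            if "sources" in frame
            else [[""]] * len(frame),
        }
    )
    return table.explode("source").reset_index(drop=True)
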