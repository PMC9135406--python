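"""Automatic validation filter and its precision-weighted evaluation.

Curated pairs are accepted automatically when the resolved reference is
trustworthy enough:

[A] it came from a DOI or PMID identifier, or
[B] from a title whose OSA distance to the resolved title is strictly below
    ten, or
[C] it resolved to one of the three journals where natural-product
    occurrences are routinely published (*Journal of Natural Products*,
    *Phytochemistry*, *Journal of Agricultural and Food Chemistry*), or
[D] it came from free text (original / publishingDetails / split) in which at
    least two of {publication year, journal, first author} of the resolved
    reference were found.

A pair passing a clause must additionally have the organism's genus in the
resolved title; this title filter is waived for DOI-based references except
those sourced from COCONUT.  Filter quality is measured against manual labels
with the F(beta) score, beta = 0.5, weighting precision twice as much as
recall.
"""

from __future__ import annotations

import random
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .organisms import OrganismRecord
from .references import (
    COMPLEMENT_SUBCATEGORIES,
    ReferenceRecord,
    osa_distance,
)
from .structures import StructureRecord

JOURNAL_WHITELIST = frozenset(
    j.casefold()
    for j in (
        "Journal of Natural Products",
        "Phytochemistry",
        "Journal of Agricultural and Food Chemistry",
    )
)

TITLE_DISTANCE_THRESHOLD = 10  # accept strictly below

MANUALLY_VALIDATED = "manually_validated"
MANUALLY_REJECTED = "manually_rejected"
AUTO_VALIDATED = "auto_validated"
AUTO_REJECTED = "auto_rejected"


@dataclass
class CuratedPair:
    """A realigned (structure, organism, reference) triple with provenance."""

    structure: StructureRecord
    organism: OrganismRecord
    reference: ReferenceRecord
    sources: list[str] = field(default_factory=list)
    validation_status: str = ""
    filter_reason: str = ""

    @property
    def organism_genus(self) -> str:
        name = self.organism.canonical
        return name.split()[0] if name else ""


@dataclass(frozen=True)
class FilterDecision:
    accepted: bool
    reason: str  # clause that decided: A|B|C|D, or rejection reason


def _genus_in_title(title: str, genus: str) -> bool:
    import re

    if not genus:
        return False
    return bool(
        re.search(rf"(?<!\w){re.escape(genus)}(?!\w)", title, re.IGNORECASE)
    )


def passes_filter(
    pair: CuratedPair, distance_threshold: int = TITLE_DISTANCE_THRESHOLD
) -> FilterDecision:
    """Pure acceptance decision for one curated pair, with the clause (or
    rejection reason) as an audit code."""
    ref = pair.reference
    if ref is None or not ref.ok or ref.selected is None:
        return FilterDecision(False, "unresolved_reference")
    sub = ref.subcategory
    clause = None
    if sub in ("doi", "pubmed"):
        clause = "A"
    elif (
        sub == "title"
        and ref.scores is not None
        and ref.scores.distance is not None
        and ref.scores.distance < distance_threshold
    ):
        clause = "B"
    elif ref.selected.journal.casefold() in JOURNAL_WHITELIST:
        clause = "C"
    elif (
        sub in COMPLEMENT_SUBCATEGORIES
        and ref.scores is not None
        and ref.scores.complement is not None
        and ref.scores.complement >= 2
    ):
        clause = "D"
    if clause is None:
        return FilterDecision(False, "no_clause")
    # title filter: genus must appear in the resolved title, waived for
    # DOI-based references except those sourced from COCONUT
    waived = sub == "doi" and not any(
        s.casefold() == "coconut" for s in pair.sources
    )
    if not waived and not _genus_in_title(ref.selected.title, pair.organism_genus):
        return FilterDecision(False, "title_genus")
    return FilterDecision(True, clause)


def apply_filter(pairs: Sequence[CuratedPair]) -> None:
    """Stamp every pair with its automatic validation status and reason."""
    for pair in pairs:
        decision = passes_filter(pair)
        pair.validation_status = AUTO_VALIDATED if decision.accepted else AUTO_REJECTED
        pair.filter_reason = decision.reason


def f_beta(precision: float, recall: float, beta: float = 0.5) -> float:
    """F(beta) = (1 + beta^2) * P * R / (beta^2 * P + R); 0 when the
    denominator vanishes."""
    if not (0.0 <= precision <= 1.0 and 0.0 <= recall <= 1.0):
        raise ValueError("precision and recall must lie in [0, 1]")
    if beta <= 0:
        raise ValueError("beta must be positive")
    denominator = beta * beta * precision + recall
    if denominator == 0:
        return 0.0
    return (1 + beta * beta) * precision * recall / denominator


@dataclass(frozen=True)
class ValidationMetrics:
    precision: float
    recall: float
    beta: float
    f_beta: float
    true_positives: int
    false_positives: int
    false_negatives: int
    true_negatives: int

    @property
    def accepted_true_positive_rate(self) -> float:
        """Share of accepted entries that are actually valid."""
        accepted = self.true_positives + self.false_positives
        return self.true_positives / accepted if accepted else 0.0


def evaluate(
    labels: Mapping[object, bool] | Sequence[bool],
    predictions: Mapping[object, bool] | Sequence[bool],
    beta: float = 0.5,
) -> ValidationMetrics:
    """Confusion counts and precision / recall / F(beta) of filter
    predictions against manual accept/reject labels (aligned by key or
    position)."""
    if isinstance(labels, Mapping):
        keys = list(labels.keys())
        if set(keys) != set(predictions.keys()):
            raise ValueError("labels and predictions must cover the same pairs")
        y_true = [bool(labels[k]) for k in keys]
        y_pred = [bool(predictions[k]) for k in keys]
    else:
        if len(labels) != len(predictions):
            raise ValueError("labels and predictions must be aligned")
        y_true = [bool(v) for v in labels]
        y_pred = [bool(v) for v in predictions]
    if not y_true:
        raise ValueError("empty label set")
    tp = sum(1 for t, p in zip(y_true, y_pred) if t and p)
    fp = sum(1 for t, p in zip(y_true, y_pred) if not t and p)
    fn = sum(1 for t, p in zip(y_true, y_pred) if t and not p)
    tn = sum(1 for t, p in zip(y_true, y_pred) if not t and not p)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    return ValidationMetrics(
        precision=precision,
        recall=recall,
        beta=beta,
        f_beta=f_beta(precision, recall, beta),
        true_positives=tp,
        false_positives=fp,
        false_negatives=fn,
        true_negatives=tn,
    )


def stratified_sample(
    pairs: Sequence[CuratedPair],
    total: int,
    min_per_subcategory: int,
    seed: int,
) -> list[CuratedPair]:
    """Deterministic sample for manual validation: every present reference
    subcategory is represented with at least ``min_per_subcategory`` entries
    and the remainder is allocated proportionally (largest remainder)."""
    by_sub: dict[str, list[int]] = {}
    for idx, pair in enumerate(pairs):
        by_sub.setdefault(pair.reference.subcategory, []).append(idx)
    subs = sorted(by_sub)
    if total < min_per_subcategory * len(subs):
        raise ValueError(
            f"total {total} cannot cover {len(subs)} subcategories at "
            f"{min_per_subcategory} each"
        )
    shortfall = {
        s: min_per_subcategory - len(by_sub[s])
        for s in subs
        if len(by_sub[s]) < min_per_subcategory
    }
    if shortfall:
        raise ValueError(f"subcategories below the minimum: {shortfall}")
    counts = {s: min_per_subcategory for s in subs}
    remainder = total - min_per_subcategory * len(subs)
    pool = {s: len(by_sub[s]) - min_per_subcategory for s in subs}
    pool_total = sum(pool.values())
    if remainder > pool_total:
        raise ValueError(
            f"total {total} exceeds available pairs ({len(pairs)})"
        )
    if remainder and pool_total:
        quotas = {s: remainder * pool[s] / pool_total for s in subs}
        for s in subs:
            counts[s] += int(quotas[s])
        leftover = remainder - sum(int(quotas[s]) for s in subs)
        by_frac = sorted(subs, key=lambda s: (-(quotas[s] - int(quotas[s])), s))
        for s in by_frac[:leftover]:
            counts[s] += 1
    rng = random.Random(seed)
    chosen: list[int] = []
    for s in subs:
        chosen.extend(rng.sample(by_sub[s], counts[s]))
    return [pairs[i] for i in sorted(chosen)]
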