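"""Per-position aggregation, top-5% hotspot calling and per-hotspot
gene/disease breakdowns.

A hotspot of a disease class is a reference position whose mutation count
is in the top ``quantile`` (default 5%) of positions carrying at least
one mutation of that class. The candidate set is mutated positions, not
all alignment columns, so the number of hotspots tracks the data rather
than the domain length; all positions tied with the cut-off count are
included, which keeps selection deterministic and order-independent.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .errors import ConfigError
from .model import (
    BENIGN,
    CANCER,
    NONCANCER,
    ClassifiedVariant,
    MappingStatus,
)

CLASSES = (CANCER, NONCANCER, BENIGN)


@dataclass
class PositionCounts:
    """Per reference position: cancer count c_i, non-cancer count n_i,
    benign count b_i; class totals are the sums over positions."""

    by_position: dict[int, dict[str, int]] = field(default_factory=dict)

    def get(self, position: int, cls: str) -> int:
        return self.by_position.get(position, {}).get(cls, 0)

    def add(self, position: int, cls: str, amount: int = 1) -> None:
        if cls not in CLASSES:
            raise ConfigError(f"unknown class {cls!r}")
        self.by_position.setdefault(position, {c: 0 for c in CLASSES})[cls] += amount

    def total(self, cls: str) -> int:
        return sum(counts.get(cls, 0) for counts in self.by_position.values())

    @property
    def positions(self) -> list[int]:
        return sorted(self.by_position)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "position": pos,
                "cancer": self.get(pos, CANCER),
                "non_cancer": self.get(pos, NONCANCER),
                "benign": self.get(pos, BENIGN),
            }
            for pos in self.positions
        ]
        return pd.DataFrame(rows, columns=["position", "cancer", "non_cancer", "benign"])


@dataclass(frozen=True)
class HotspotReport:
    """One hotspot with its gene (inner) and gene/condition (outer)
    breakdown; the condition layer may exceed the gene layer because one
    mutation can be related to several diseases."""

    position: int
    disease_class: str
    count: int
    rank: int
    genes: dict[str, int]
    diseases: dict[tuple[str, str], int]

    def to_dict(self) -> dict:
        nested: dict[str, dict[str, int]] = {}
        for (gene, condition), n in sorted(self.diseases.items()):
            nested.setdefault(gene, {})[condition] = n
        return {
            "position": self.position,
            "class": self.disease_class,
            "count": self.count,
            "rank": self.rank,
            "genes": dict(sorted(self.genes.items())),
            "diseases": nested,
        }


def _collapse_key(cv: ClassifiedVariant, collapse_aa: bool):
    if collapse_aa:
        return (cv.gene, str(cv.mapped.variant.substitution))
    return cv.record_id


def count_by_position(
    classified: list[ClassifiedVariant], collapse_aa: bool = False
) -> PositionCounts:
    """Aggregate mapped, classified variants into per-position counts.

    Each variant contributes +1 to each class it belongs to at its
    reference position; the dedup unit is record x class (or distinct
    gene/amino-acid change x class with ``collapse_aa``).
    """
    counts = PositionCounts()
    seen: set[tuple] = set()
    for cv in classified:
        if cv.mapped.status is not MappingStatus.MAPPED:
            raise ConfigError(
                f"count_by_position received unmapped record {cv.record_id!r}"
            )
        for cls in cv.classes:
            key = (_collapse_key(cv, collapse_aa), cv.position, cls)
            if key in seen:
                continue
            seen.add(key)
            counts.add(cv.position, cls)
    return counts


def select_hotspots(
    counts: PositionCounts, disease_class: str, quantile: float = 0.05
) -> list[int]:
    """Top-``quantile`` mutated positions of one class, ties included.

    With m candidate positions, k = ceil(quantile * m); positions are
    sorted by count descending then residue number ascending, and every
    position tied with the k-th count is returned.
    """
    if not (0 < quantile < 1):
        raise ConfigError(f"quantile: must be in (0, 1), got {quantile}")
    candidates = [
        (pos, counts.get(pos, disease_class))
        for pos in counts.positions
        if counts.get(pos, disease_class) > 0
    ]
    if not candidates:
        warnings.warn(f"no positions carry {disease_class} mutations", stacklevel=2)
        return []
    candidates.sort(key=lambda pc: (-pc[1], pc[0]))
    k = math.ceil(quantile * len(candidates))
    threshold = candidates[k - 1][1]
    return [pos for pos, count in candidates if count >= threshold]


def position_breakdown(
    classified: list[ClassifiedVariant],
    position: int,
    disease_class: str,
    rank: int = 0,
    collapse_aa: bool = False,
) -> HotspotReport:
    """Gene and gene/condition breakdown of one hotspot position,
    restricted to conditions of the given class."""
    genes: Counter = Counter()
    diseases: Counter = Counter()
    seen: set = set()
    for cv in classified:
        if cv.position != position or disease_class not in cv.classes:
            continue
        key = _collapse_key(cv, collapse_aa)
        if key in seen:
            continue
        seen.add(key)
        genes[cv.gene] += 1
        for condition, cls in cv.condition_classes:
            if cls == disease_class:
                diseases[(cv.gene, condition)] += 1
        if disease_class == BENIGN and not cv.condition_classes:
            diseases[(cv.gene, "benign")] += 1
    if not genes:
        raise ConfigError(
            f"position {position} has no {disease_class} mutations to break down"
        )
    return HotspotReport(
        position=position,
        disease_class=disease_class,
        count=sum(genes.values()),
        rank=rank,
        genes=dict(genes),
        diseases=dict(diseases),
    )


def rank_genes(
    classified: list[ClassifiedVariant], disease_class: str, collapse_aa: bool = False
) -> pd.DataFrame:
    """Per-gene mutation totals for one class, sorted by count descending
    then gene name (the per-gene ranking behind the top-genes table)."""
    counter: Counter = Counter()
    seen: set = set()
    for cv in classified:
        if disease_class not in cv.classes:
            continue
        key = (_collapse_key(cv, collapse_aa), cv.position)
        if key in seen:
            continue
        seen.add(key)
        counter[cv.gene] += 1
    rows = sorted(counter.items(), key=lambda gc: (-gc[1], gc[0]))
    return pd.DataFrame(rows, columns=["gene", "count"])
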