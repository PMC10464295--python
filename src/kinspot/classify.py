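"""Record filters and disease-class assignment.

The cancer/non-cancer split of clinical conditions was a manual curation
step in the original analysis; here it is a reproducible surrogate: a
keyword lexicon plus an exact-match override table, with an audit table
of every distinct condition and the class it received.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

from .errors import ConfigError, FormatError
from .model import (
    BENIGN,
    CANCER,
    IGNORE,
    NONCANCER,
    ExclusionRecord,
    VariantRecord,
)

#: substrings (lowercase) that mark a condition as cancer-related
DEFAULT_CANCER_KEYWORDS: tuple[str, ...] = (
    "cancer",
    "carcinoma",
    "melanoma",
    "leukemia",
    "leukaemia",
    "lymphoma",
    "neoplas",  # neoplasm / neoplasia / neoplastic
    "tumor",
    "tumour",
    "sarcoma",
    "blastoma",
    "myeloma",
    "adenoma",
    "glioma",
    "gastrointestinal stromal",
    "gist",
    "malignan",
    "myelodysplastic",
    "polycythemia",
    "thrombocythemia",
    "myelofibrosis",
    "mastocytosis",
)

#: uninformative ClinVar condition strings, ignored rather than classified
DEFAULT_OVERRIDES: dict[str, str] = {
    "not provided": IGNORE,
    "not specified": IGNORE,
    "see cases": IGNORE,
}


def _norm(text: str) -> str:
    return re.sub(r"\s+", " ", text.strip().lower())


@dataclass(frozen=True)
class DiseaseClassLexicon:
    cancer_keywords: tuple[str, ...] = DEFAULT_CANCER_KEYWORDS
    overrides: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_OVERRIDES))

    def __post_init__(self) -> None:
        if not self.cancer_keywords:
            raise ConfigError("cancer_keywords: must be non-empty")
        for key, value in self.overrides.items():
            if value not in (CANCER, NONCANCER, IGNORE):
                raise ConfigError(f"overrides[{key!r}]: unknown class {value!r}")


def load_lexicon(overrides_path=None) -> DiseaseClassLexicon:
    """Default lexicon, optionally extended by a ``condition<TAB>class``
    override table (classes: cancer, non-cancer, ignore)."""
    overrides = dict(DEFAULT_OVERRIDES)
    if overrides_path is not None:
        df = pd.read_csv(
            overrides_path, sep="\t", header=None, names=["condition", "class"],
            dtype=str, comment="#",
        )
        for _, row in df.iterrows():
            cls = _norm(row["class"])
            if cls not in (CANCER, NONCANCER, IGNORE):
                raise FormatError(
                    f"lexicon override {row['condition']!r}: unknown class {cls!r}"
                )
            overrides[_norm(row["condition"])] = cls
    return DiseaseClassLexicon(overrides=overrides)


def classify_condition(condition: str, lexicon: DiseaseClassLexicon) -> str:
    """Class of one condition string: override first, then cancer iff any
    cancer keyword is a substring, else non-cancer."""
    key = _norm(condition)
    if key in lexicon.overrides:
        return lexicon.overrides[key]
    if any(kw in key for kw in lexicon.cancer_keywords):
        return CANCER
    return NONCANCER


def condition_classes(
    record: VariantRecord, lexicon: DiseaseClassLexicon
) -> tuple[tuple[str, str], ...]:
    """(condition, class) pairs for every non-ignored condition."""
    pairs = []
    for condition in record.conditions:
        cls = classify_condition(condition, lexicon)
        if cls != IGNORE:
            pairs.append((condition, cls))
    return tuple(pairs)


def assign_classes(record: VariantRecord, lexicon: DiseaseClassLexicon) -> frozenset[str]:
    """Union of per-condition classes; a record with both cancer and
    non-cancer conditions belongs to both classes (counted once per class
    downstream). Empty when every condition is ignored."""
    return frozenset(cls for _, cls in condition_classes(record, lexicon))


# ---------------------------------------------------------------------------
# significance filters


def significance_labels(text: str) -> frozenset[str]:
    """Normalized label set of a clinical-significance string;
    composites like "Pathogenic/Likely pathogenic" become two labels."""
    parts = re.split(r"[/;,]", text.lower())
    labels = set()
    for part in parts:
        label = re.sub(r"[^a-z ]", " ", part)
        label = re.sub(r"\s+", " ", label).strip()
        if label:
            labels.add(label)
    return frozenset(labels)


_PATHOGENIC = frozenset({"pathogenic", "likely pathogenic"})


def filter_pathogenic(
    records: list[VariantRecord],
) -> tuple[list[VariantRecord], list[ExclusionRecord]]:
    """Keep exactly the records asserted Pathogenic or Likely pathogenic
    (case- and punctuation-insensitive, composites accepted); log the rest."""
    kept, excluded = [], []
    for r in records:
        if significance_labels(r.clinical_significance) & _PATHOGENIC:
            kept.append(r)
        else:
            excluded.append(
                ExclusionRecord(
                    r.record_id, r.gene, r.protein_change,
                    "not_pathogenic", r.clinical_significance,
                )
            )
    return kept, excluded


def filter_benign(
    records: list[VariantRecord],
    af_threshold: float = 0.01,
    include_likely_benign: bool = False,
) -> tuple[list[VariantRecord], list[ExclusionRecord]]:
    """Keep benign records with population allele frequency >= threshold
    (inclusive). Records lacking an allele frequency are dropped and
    logged. "Likely benign" is excluded unless requested."""
    wanted = {"benign"} | ({"likely benign"} if include_likely_benign else set())
    kept, excluded = [], []
    for r in records:
        labels = significance_labels(r.clinical_significance)
        if not (labels & wanted):
            excluded.append(
                ExclusionRecord(
                    r.record_id, r.gene, r.protein_change,
                    "not_benign", r.clinical_significance,
                )
            )
            continue
        if r.allele_frequency is None:
            excluded.append(
                ExclusionRecord(
                    r.record_id, r.gene, r.protein_change,
                    "missing_allele_frequency", "",
                )
            )
            continue
        if r.allele_frequency >= af_threshold:
            kept.append(r)
        else:
            excluded.append(
                ExclusionRecord(
                    r.record_id, r.gene, r.protein_change,
                    "allele_frequency_below_threshold",
                    f"{r.allele_frequency} < {af_threshold}",
                )
            )
    return kept, excluded


def audit_conditions(
    records: list[VariantRecord], lexicon: DiseaseClassLexicon
) -> pd.DataFrame:
    """Audit table: every distinct condition with its class, whether it
    came from an override or a keyword, and how many records carry it."""
    counts: dict[str, int] = {}
    for r in records:
        for condition in r.conditions:
            counts[condition] = counts.get(condition, 0) + 1
    rows = []
    for condition in sorted(counts):
        cls = classify_condition(condition, lexicon)
        source = "override" if _norm(condition) in lexicon.overrides else "keyword"
        rows.append(
            {
                "condition": condition,
                "class": cls,
                "source": source,
                "n_records": counts[condition],
            }
        )
    return pd.DataFrame(rows, columns=["condition", "class", "source", "n_records"])
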