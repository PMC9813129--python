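"""Multi-label disease categorization of studies.

Each study's recorded conditions and MeSH terms are searched against a
category lexicon (category name -> disease term list, in the style of the
clinicaltrials.gov condition browse categories). A study may fall under
several categories or none. The same token-level n-gram matching
convention as the eligibility search features is used; n-grams are built
within each condition/MeSH item so that two adjacent items can never
splice into a spurious multi-word match.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._normalize import ngrams, normalize_tokens
from .registry import TrialRecord, StudyLabel


@dataclass(slots=True)
class CategoryLexicon:
    """Mapping category name -> set of normalized disease term tuples."""

    categories: dict[str, set[tuple[str, ...]]]

    @classmethod
    def from_mapping(cls, raw: Mapping[str, Iterable[str]]) -> "CategoryLexicon":
        cats = {}
        for name, terms in raw.items():
            normalized = {normalize_tokens(t) for t in terms}
            normalized.discard(())
            if not normalized:
                raise ValueError(f"category {name!r} has no usable terms")
            cats[name] = normalized
        return cls(cats)

    @classmethod
    def from_json(cls, path) -> "CategoryLexicon":
        with open(path, encoding="utf-8") as fh:
            return cls.from_mapping(json.load(fh))

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {c: sorted(" ".join(t) for t in ts) for c, ts in self.categories.items()},
                fh,
                indent=1,
            )


@dataclass(slots=True, frozen=True)
class CategoryAssignment:
    registry_id: str
    categories: frozenset[str]


def assign_categories(record: TrialRecord, lexicon: CategoryLexicon) -> CategoryAssignment:
    """Assign every category with a lexicon term occurring in the study's
    conditions or MeSH terms (token n-gram match, per item)."""
    if not lexicon.categories:
        raise ValueError("lexicon must be non-empty")
    grams: set[tuple[str, ...]] = set()
    max_n = max(len(t) for ts in lexicon.categories.values() for t in ts)
    for item in (*record.conditions, *record.mesh_terms):
        grams |= ngrams(normalize_tokens(item), max_n)
    assigned = frozenset(
        c for c, terms in lexicon.categories.items() if terms & grams
    )
    return CategoryAssignment(record.registry_id, assigned)


def category_failure_rates(
    assignments: Sequence[CategoryAssignment], labels: Sequence[StudyLabel]
) -> dict[str, tuple[float, float]]:
    """Per category: (percent completed, percent terminated-or-withdrawn).

    Percentages are over the studies assigned to the category and sum to
    100; categories with no studies are omitted.
    """
    label_by_id = {l.registry_id: l.label for l in labels}
    totals: dict[str, int] = {}
    completed: dict[str, int] = {}
    for a in assignments:
        y = label_by_id[a.registry_id]
        for c in a.categories:
            totals[c] = totals.get(c, 0) + 1
            completed[c] = completed.get(c, 0) + y
    return {
        c: (100.0 * completed.get(c, 0) / n, 100.0 * (n - completed.get(c, 0)) / n)
        for c, n in totals.items()
    }


def encode_category_features(
    assignments: Sequence[CategoryAssignment], category_order: Sequence[str]
) -> np.ndarray:
    """Binary records x categories indicator matrix in the given order."""
    index = {c: j for j, c in enumerate(category_order)}
    out = np.zeros((len(assignments), len(category_order)), dtype=np.int8)
    for i, a in enumerate(assignments):
        for c in a.categories:
            if c in index:
                out[i, index[c]] = 1
    return out


#: Small illustrative lexicon in the spirit of the registry's condition
#: browse categories. Real analyses should pass their own lexicon file.
DEFAULT_LEXICON_TERMS: dict[str, list[str]] = {
    "neoplasms": [
        "neoplasm", "carcinoma", "tumor", "cancer", "lymphoma", "leukemia",
        "melanoma", "sarcoma", "metastatic",
    ],
    "cardiovascular diseases": [
        "heart failure", "myocardial infarction", "hypertension", "stroke",
        "atrial fibrillation", "coronary artery disease", "cardiomyopathy",
    ],
    "blood lymph conditions": [
        "anemia", "thrombocytopenia", "hemophilia", "sickle cell",
        "lymphedema", "neutropenia",
    ],
    "respiratory tract diseases": [
        "asthma", "copd", "pneumonia", "pulmonary fibrosis", "bronchitis",
        "respiratory distress",
    ],
    "nervous system diseases": [
        "epilepsy", "parkinson disease", "multiple sclerosis", "alzheimer",
        "migraine", "neuropathy",
    ],
    "digestive system diseases": [
        "crohn disease", "ulcerative colitis", "cirrhosis", "hepatitis",
        "pancreatitis", "irritable bowel",
    ],
    "nutritional and metabolic diseases": [
        "diabetes", "obesity", "hyperlipidemia", "metabolic syndrome",
        "malnutrition",
    ],
    "immune system diseases": [
        "rheumatoid arthritis", "lupus", "psoriasis", "allergy",
        "immunodeficiency",
    ],
    "mental disorders": [
        "depression", "anxiety", "schizophrenia", "bipolar disorder",
        "substance abuse", "addiction",
    ],
    "infections": [
        "hiv", "tuberculosis", "influenza", "sepsis", "malaria",
        "viral infection",
    ],
}


def default_lexicon() -> CategoryLexicon:
    return CategoryLexicon.from_mapping(DEFAULT_LEXICON_TERMS)
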