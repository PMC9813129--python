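"""Eligibility-criteria text features.

The registry's eligibility field is free text with "Inclusion Criteria" /
"Exclusion Criteria" sections. This module splits the sections, segments
bulleted criteria, computes descriptive statistics (criterion counts, word
counts), and — the interesting part — builds *search features*: an
annotated corpus of (side, entity category, value) terms is normalized,
filtered to at most five tokens, and each surviving term becomes one
binary column scored 1 for a study iff the term's token sequence occurs
contiguously in the study's corresponding section. The result is a sparse
binary record x term matrix that is concatenated to the design matrix.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

from ._normalize import ngrams, normalize_tokens

SIDES = ("inclusion", "exclusion")
CATEGORIES = (
    "Condition",
    "Procedure",
    "Person",
    "Temporal",
    "Drug",
    "Observation",
    "Mood",
    "Visit",
)

_HEADER_RE = re.compile(r"(inclusion|exclusion)\s+criteria\s*:?", re.IGNORECASE)
_BULLET_RE = re.compile(r"^\s*(?:[-*•·‣▪]+|\d+[.)])\s*")


@dataclass(slots=True)
class EligibilityDocument:
    """Parsed eligibility text for one study."""

    registry_id: str
    inclusion_text: str = ""
    exclusion_text: str = ""
    inclusion_criteria: list[str] = field(default_factory=list)
    exclusion_criteria: list[str] = field(default_factory=list)

    def section(self, side: str) -> str:
        return self.inclusion_text if side == "inclusion" else self.exclusion_text


@dataclass(slots=True, frozen=True)
class SearchTerm:
    """One (side, category, normalized value) search feature.

    ``value`` is the normalized token sequence; ``token_count`` = len(value)
    and never exceeds the 5-token cap.
    """

    term_id: int
    side: str
    category: str
    value: tuple[str, ...]

    @property
    def token_count(self) -> int:
        return len(self.value)

    @property
    def name(self) -> str:
        return f"{self.side}|{self.category}|{' '.join(self.value)}"


@dataclass(slots=True)
class SearchFeatureMatrix:
    """Sparse binary record x term match matrix with aligned identifiers."""

    row_ids: list[str]
    terms: list[SearchTerm]
    matrix: sparse.csr_matrix

    @property
    def col_ids(self) -> list[int]:
        return [t.term_id for t in self.terms]

    def to_files(self, mtx_path, sidecar_path) -> None:
        from scipy.io import mmwrite

        mmwrite(str(mtx_path), self.matrix.astype(np.int8))
        meta = {
            "row_ids": self.row_ids,
            "terms": [
                {
                    "term_id": t.term_id,
                    "side": t.side,
                    "category": t.category,
                    "value": " ".join(t.value),
                }
                for t in self.terms
            ],
        }
        with open(sidecar_path, "w", encoding="utf-8") as fh:
            json.dump(meta, fh)


def split_sections(raw_text: str | None) -> tuple[str, str]:
    """Split raw eligibility text into (inclusion_text, exclusion_text).

    Text after a case-insensitive "exclusion criteria" header goes to the
    exclusion section; text after an "inclusion criteria" header — or before
    any header at all — goes to the inclusion section. Headers themselves
    are dropped. Missing text yields two empty sections.
    """
    if not raw_text:
        return "", ""
    pieces = {"inclusion": [], "exclusion": []}
    matches = list(_HEADER_RE.finditer(raw_text))
    if not matches:
        return raw_text.strip(), ""
    lead = raw_text[: matches[0].start()].strip()
    if lead:
        pieces["inclusion"].append(lead)
    for i, m in enumerate(matches):
        end = matches[i + 1].start() if i + 1 < len(matches) else len(raw_text)
        chunk = raw_text[m.end() : end].strip()
        if chunk:
            pieces[m.group(1).lower()].append(chunk)
    return "\n".join(pieces["inclusion"]), "\n".join(pieces["exclusion"])


def segment_criteria(section_text: str) -> list[str]:
    """Split a section into individual criteria.

    Criteria are newline-separated; leading bullet markers (-, *, numbers
    like "1.") are stripped; empty fragments are dropped; order preserved.
    """
    out = []
    for line in section_text.splitlines():
        stripped = _BULLET_RE.sub("", line).strip()
        if stripped:
            out.append(stripped)
    return out


def parse_document(registry_id: str, raw_text: str | None) -> EligibilityDocument:
    inc, exc = split_sections(raw_text)
    return EligibilityDocument(
        registry_id=registry_id,
        inclusion_text=inc,
        exclusion_text=exc,
        inclusion_criteria=segment_criteria(inc),
        exclusion_criteria=segment_criteria(exc),
    )


def criteria_stats(doc: EligibilityDocument) -> dict[str, float]:
    """Descriptive statistics: criterion counts, total and average words."""
    n_inc = len(doc.inclusion_criteria)
    n_exc = len(doc.exclusion_criteria)
    total_words = len(doc.inclusion_text.split()) + len(doc.exclusion_text.split())
    n = n_inc + n_exc
    return {
        "n_inclusion": float(n_inc),
        "n_exclusion": float(n_exc),
        "total_words": float(total_words),
        "avg_words_per_criterion": total_words / n if n else 0.0,
    }


def build_search_terms(
    corpus_rows: Iterable[tuple[str, str, str]], max_words: int = 5
) -> list[SearchTerm]:
    """Turn annotated (side, category, value) rows into search terms.

    Values are normalized (lower-case, punctuation stripped, tokenized);
    terms longer than ``max_words`` tokens are dropped, duplicates after
    normalization collapse to one term, and term ids are assigned by a
    deterministic (side, category, value) sort. Rows with an unknown
    category are skipped with a warning.
    """
    seen: set[tuple[str, str, tuple[str, ...]]] = set()
    skipped = 0
    for side, category, value in corpus_rows:
        side = str(side).strip().lower()
        category = str(category).strip()
        if side not in SIDES or category not in CATEGORIES:
            skipped += 1
            continue
        tokens = normalize_tokens(value)
        if not tokens or len(tokens) > max_words:
            continue
        seen.add((side, category, tokens))
    if skipped:
        warnings.warn(f"skipped {skipped} corpus row(s) with unknown side/category", stacklevel=2)
    ordered = sorted(seen)
    return [
        SearchTerm(term_id=i, side=s, category=c, value=v)
        for i, (s, c, v) in enumerate(ordered)
    ]


def read_term_corpus(path) -> list[tuple[str, str, str]]:
    """Read a side,category,value CSV corpus export."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return list(zip(df["side"], df["category"], df["value"]))


def write_search_terms(terms: Sequence[SearchTerm], path) -> None:
    pd.DataFrame(
        {
            "term_id": [t.term_id for t in terms],
            "side": [t.side for t in terms],
            "category": [t.category for t in terms],
            "value": [" ".join(t.value) for t in terms],
        }
    ).to_csv(path, index=False)


def read_search_terms(path) -> list[SearchTerm]:
    df = pd.read_csv(path, dtype={"term_id": int}, keep_default_na=False)
    return [
        SearchTerm(
            term_id=int(r.term_id),
            side=r.side,
            category=r.category,
            value=tuple(str(r.value).split()),
        )
        for r in df.itertuples()
    ]


def match_terms(
    docs: Sequence[EligibilityDocument], terms: Sequence[SearchTerm]
) -> SearchFeatureMatrix:
    """Score every (document, term) pair with contiguous n-gram matching.

    Cell (i, j) is 1 iff term j's token sequence occurs contiguously in
    the normalized text of document i's section matching term j's side:
    inclusion terms are searched only in inclusion text, exclusion terms
    only in exclusion text. Matching is token-exact after normalization
    (never substring), with windows of at most five tokens.
    """
    if not terms:
        raise ValueError("terms must be non-empty")
    max_n = max(t.token_count for t in terms)
    by_value: dict[tuple[str, tuple[str, ...]], list[int]] = {}
    for j, t in enumerate(terms):
        by_value.setdefault((t.side, t.value), []).append(j)

    rows, cols = [], []
    for i, doc in enumerate(docs):
        for side in SIDES:
            tokens = normalize_tokens(doc.section(side))
            if not tokens:
                continue
            for gram in ngrams(tokens, max_n):
                for j in by_value.get((side, gram), ()):
                    rows.append(i)
                    cols.append(j)
    matrix = sparse.csr_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)),
        shape=(len(docs), len(terms)),
    )
    matrix.data = np.minimum(matrix.data, 1)  # duplicates collapse to binary
    return SearchFeatureMatrix(
        row_ids=[d.registry_id for d in docs], terms=list(terms), matrix=matrix
    )


def naive_match_scan(
    docs: Sequence[EligibilityDocument], terms: Sequence[SearchTerm]
) -> np.ndarray:
    """Brute-force O(docs x terms x positions) token-window matcher.

    Independent reference for :func:`match_terms`: slides a window of the
    term's length over the normalized section tokens and compares position
    by position. Dense output; intended for small verification instances.
    """
    out = np.zeros((len(docs), len(terms)), dtype=np.int8)
    for i, doc in enumerate(docs):
        section_tokens = {s: normalize_tokens(doc.section(s)) for s in SIDES}
        for j, term in enumerate(terms):
            tokens = section_tokens[term.side]
            n = term.token_count
            for p in range(len(tokens) - n + 1):
                if tuple(tokens[p : p + n]) == term.value:
                    out[i, j] = 1
                    break
    return out
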