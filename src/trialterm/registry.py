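"""Registry-record ingestion, filtering, labelling and characteristics.

Consumes a flat delimited export of a clinicaltrials.gov-style registry
(one row per study) and produces :class:`TrialRecord` objects, the binary
success/failure labels used for supervised training, per-phase study
subsets, and the missing-data-by-year diagnostic that motivates the
registration-year cutoff.
"""

from __future__ import annotations

import csv
import re
import warnings
from dataclasses import dataclass, fields as dc_fields
from typing import Iterable, Mapping, Sequence

import pandas as pd

PHASES = ("early_phase1", "phase1", "phase2", "phase3", "phase4")

#: The 14 overall-status values a registry export may carry. Anything else
#: is normalized to "other", which the filters remove.
STATUSES = frozenset(
    {
        "completed",
        "terminated",
        "withdrawn",
        "recruiting",
        "not_yet_recruiting",
        "active_not_recruiting",
        "enrolling_by_invitation",
        "suspended",
        "unknown",
        "approved_for_marketing",
        "available",
        "no_longer_available",
        "temporarily_not_available",
        "withheld",
    }
)

STUDY_TYPES = frozenset({"interventional", "observational", "patient_registry"})

FAILURE_STATUSES = frozenset({"terminated", "withdrawn"})
FINAL_STATUSES = frozenset({"completed", "terminated", "withdrawn"})


class ConfigurationError(ValueError):
    """A column map or field list names something that does not exist."""


class InvalidStatusError(ValueError):
    """A label was requested for a study whose status is not final."""


@dataclass(slots=True, frozen=True)
class TrialRecord:
    """One registry study: design characteristics, status and free text.

    Scalar fields use ``None`` for missing; multi-valued fields use empty
    tuples/frozensets. Counts are non-negative when present.
    """

    registry_id: str
    study_type: str | None = None
    overall_status: str | None = None
    start_year: int | None = None
    phases: frozenset[str] = frozenset()
    enrollment: float | None = None
    enrollment_type: str | None = None
    n_sites: float | None = None
    n_arms: float | None = None
    n_primary_outcomes: float | None = None
    n_secondary_outcomes: float | None = None
    n_countries: float | None = None
    randomized: str | None = None
    intervention_model: str | None = None
    intervention_types: frozenset[str] = frozenset()
    masking: str | None = None
    fda_regulated: str | None = None
    accepts_healthy_volunteers: str | None = None
    gender_eligibility: str | None = None
    age_min: float | None = None
    age_max: float | None = None
    conditions: tuple[str, ...] = ()
    mesh_terms: tuple[str, ...] = ()
    eligibility_text: str | None = None
    why_stopped: str | None = None


@dataclass(slots=True, frozen=True)
class StudyLabel:
    """Binary outcome: 1 = success (completed), 0 = failure (terminated/withdrawn)."""

    registry_id: str
    label: int


#: Fields whose missingness is tracked in the by-year diagnostic: every
#: record field except the identifier (24 fields).
DEFAULT_MISSING_FIELDS: tuple[str, ...] = tuple(
    f.name for f in dc_fields(TrialRecord) if f.name != "registry_id"
)

#: Default source-column -> field mapping for exports written by
#: :mod:`trialterm.synthetic` (AACT-flavoured column names).
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "nct_id": "registry_id",
    "study_type": "study_type",
    "overall_status": "overall_status",
    "start_year": "start_year",
    "phase": "phases",
    "enrollment": "enrollment",
    "enrollment_type": "enrollment_type",
    "number_of_facilities": "n_sites",
    "number_of_arms": "n_arms",
    "number_of_primary_outcomes": "n_primary_outcomes",
    "number_of_secondary_outcomes": "n_secondary_outcomes",
    "number_of_countries": "n_countries",
    "allocation": "randomized",
    "intervention_model": "intervention_model",
    "intervention_types": "intervention_types",
    "masking": "masking",
    "is_fda_regulated_drug": "fda_regulated",
    "healthy_volunteers": "accepts_healthy_volunteers",
    "gender": "gender_eligibility",
    "minimum_age": "age_min",
    "maximum_age": "age_max",
    "conditions": "conditions",
    "mesh_terms": "mesh_terms",
    "eligibility_criteria": "eligibility_text",
    "why_stopped": "why_stopped",
}

_NUMERIC_FIELDS = {
    "enrollment",
    "n_sites",
    "n_arms",
    "n_primary_outcomes",
    "n_secondary_outcomes",
    "n_countries",
}
_LIST_FIELDS = {"conditions", "mesh_terms"}
_SET_FIELDS = {"intervention_types"}
_TEXT_FIELDS = {
    "eligibility_text",
    "why_stopped",
    "enrollment_type",
    "intervention_model",
    "masking",
    "gender_eligibility",
}
_TRISTATE_FIELDS = {"fda_regulated", "accepts_healthy_volunteers", "randomized"}

_AGE_RE = re.compile(r"^\s*(\d+(?:\.\d+)?)\s*(year|month|week|day|hour|minute)s?\s*$", re.I)
_AGE_UNIT_YEARS = {
    "year": 1.0,
    "month": 1.0 / 12.0,
    "week": 7.0 / 365.25,
    "day": 1.0 / 365.25,
    "hour": 1.0 / (365.25 * 24),
    "minute": 1.0 / (365.25 * 24 * 60),
}

_MISSING_STRINGS = {"", "na", "n/a", "nan", "none", "null", "missing", "-", "."}


def _is_missing_cell(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and pd.isna(value):
        return True
    return isinstance(value, str) and value.strip().lower() in _MISSING_STRINGS


def normalize_status(value) -> str | None:
    """Case-insensitive status normalization; unknown strings -> 'other'."""
    if _is_missing_cell(value):
        return None
    s = re.sub(r"[\s,/-]+", "_", str(value).strip().lower()).strip("_")
    if s == "unknown_status":
        s = "unknown"
    return s if s in STATUSES else "other"


def normalize_study_type(value) -> str | None:
    if _is_missing_cell(value):
        return None
    s = re.sub(r"[\s/-]+", "_", str(value).strip().lower())
    return s if s in STUDY_TYPES else "other"


def parse_age_years(value) -> float | None:
    """Convert registry age strings ("18 Years", "6 Months") to years."""
    if _is_missing_cell(value):
        return None
    if isinstance(value, (int, float)):
        return float(value)
    m = _AGE_RE.match(str(value))
    if m:
        return float(m.group(1)) * _AGE_UNIT_YEARS[m.group(2).lower()]
    try:
        return float(str(value).strip())
    except ValueError:
        return None


def parse_phases(value) -> frozenset[str]:
    """Parse "Phase 2/Phase 3"-style strings into the phase enum set."""
    if _is_missing_cell(value):
        return frozenset()
    out = set()
    for part in re.split(r"[/;|]", str(value)):
        token = re.sub(r"[\s_]+", "", part.strip().lower())
        if token in {"earlyphase1", "early1"}:
            out.add("early_phase1")
        elif token in {"phase1", "phase2", "phase3", "phase4"}:
            out.add("phase" + token[-1])
    return frozenset(out)


def _parse_year(value) -> int | None:
    if _is_missing_cell(value):
        return None
    m = re.search(r"(\d{4})", str(value))
    return int(m.group(1)) if m else None


def _parse_number(value) -> float | None:
    if _is_missing_cell(value):
        return None
    try:
        x = float(str(value).strip())
    except ValueError:
        return None
    return x if x >= 0 else None


def _parse_tristate(value) -> str | None:
    if _is_missing_cell(value):
        return None
    s = str(value).strip().lower()
    if s in {"yes", "true", "1", "randomized", "accepts healthy volunteers"}:
        return "yes"
    if s in {"no", "false", "0", "non-randomized", "no healthy volunteers"}:
        return "no"
    return None


def _parse_list(value) -> tuple[str, ...]:
    if _is_missing_cell(value):
        return ()
    return tuple(p.strip() for p in str(value).split(";") if p.strip())


def record_from_row(row: Mapping[str, object], column_map: Mapping[str, str]) -> TrialRecord:
    """Build a TrialRecord from one raw export row; bad numerics become missing."""
    kw: dict[str, object] = {}
    for src, field in column_map.items():
        value = row.get(src)
        if field == "registry_id":
            kw[field] = "" if _is_missing_cell(value) else str(value).strip()
        elif field == "study_type":
            kw[field] = normalize_study_type(value)
        elif field == "overall_status":
            kw[field] = normalize_status(value)
        elif field == "start_year":
            kw[field] = _parse_year(value)
        elif field == "phases":
            kw[field] = parse_phases(value)
        elif field in ("age_min", "age_max"):
            kw[field] = parse_age_years(value)
        elif field in _NUMERIC_FIELDS:
            kw[field] = _parse_number(value)
        elif field in _TRISTATE_FIELDS:
            kw[field] = _parse_tristate(value)
        elif field in _LIST_FIELDS:
            kw[field] = _parse_list(value)
        elif field in _SET_FIELDS:
            kw[field] = frozenset(_parse_list(value))
        else:
            kw[field] = None if _is_missing_cell(value) else str(value)
    return TrialRecord(**kw)


def read_registry_table(
    path,
    delimiter: str = "|",
    column_map: Mapping[str, str] | None = None,
) -> list[TrialRecord]:
    """Read a delimited registry export into TrialRecords, one per row.

    Unparseable numeric cells become missing values rather than errors;
    the row count is always preserved.
    """
    column_map = dict(column_map or DEFAULT_COLUMN_MAP)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        header = reader.fieldnames
        if header is None:
            warnings.warn(f"empty registry export: {path}", stacklevel=2)
            return []
        missing_cols = [c for c in column_map if c not in header]
        if missing_cols:
            raise ConfigurationError(
                f"mapped column(s) not in export header: {', '.join(sorted(missing_cols))}"
            )
        return [record_from_row(row, column_map) for row in reader]


def filter_records(
    records: Iterable[TrialRecord], min_year: int = 2011
) -> list[TrialRecord]:
    """Keep interventional studies with a final status registered >= min_year.

    A record survives iff it is interventional, its status is completed,
    terminated or withdrawn, and its start year is known and >= ``min_year``.
    Order is preserved and the operation is idempotent.
    """
    return [
        r
        for r in records
        if r.study_type == "interventional"
        and r.overall_status in FINAL_STATUSES
        and r.start_year is not None
        and r.start_year >= min_year
    ]


def assign_label(record: TrialRecord) -> StudyLabel:
    """Completed -> 1 (success); terminated/withdrawn -> 0 (failure)."""
    status = record.overall_status
    if status == "completed":
        return StudyLabel(record.registry_id, 1)
    if status in FAILURE_STATUSES:
        return StudyLabel(record.registry_id, 0)
    raise InvalidStatusError(
        f"cannot label study {record.registry_id!r} with status {status!r}; "
        "labels are defined only for completed/terminated/withdrawn"
    )


def phase_subsets(
    records: Sequence[TrialRecord],
) -> dict[str, list[TrialRecord]]:
    """Per-phase study subsets; a k-phase record appears in all k of them.

    The extra key ``"all"`` holds every record regardless of phase.
    """
    out: dict[str, list[TrialRecord]] = {p: [] for p in PHASES}
    out["all"] = list(records)
    for r in records:
        for p in r.phases:
            out[p].append(r)
    return {k: v for k, v in out.items() if k == "all" or v}


def _field_missing(record: TrialRecord, field: str) -> bool:
    v = getattr(record, field)
    if v is None:
        return True
    if isinstance(v, (tuple, frozenset)):
        return len(v) == 0
    if isinstance(v, str):
        return not v.strip()
    return False


def missing_rate_by_year(
    records: Iterable[TrialRecord],
    feature_names: Sequence[str] = DEFAULT_MISSING_FIELDS,
) -> dict[int, float]:
    """Average number of missing fields per study, by registration year.

    rate(y) = (total missing cells among ``feature_names`` over studies
    started in year y) / (number of studies started in year y); bounded by
    ``len(feature_names)``. Years with no records are absent.
    """
    if not feature_names:
        raise ConfigurationError("feature_names must be non-empty")
    valid = {f.name for f in dc_fields(TrialRecord)}
    unknown = [f for f in feature_names if f not in valid]
    if unknown:
        raise ConfigurationError(f"unknown record field(s): {', '.join(unknown)}")
    missing: dict[int, int] = {}
    counts: dict[int, int] = {}
    for r in records:
        if r.start_year is None:
            continue
        counts[r.start_year] = counts.get(r.start_year, 0) + 1
        missing[r.start_year] = missing.get(r.start_year, 0) + sum(
            _field_missing(r, f) for f in feature_names
        )
    return {y: missing[y] / counts[y] for y in sorted(counts)}


#: Characteristics emitted by default: administrative, logistic and design
#: features plus one indicator per phase.
DEFAULT_CHARACTERISTIC_NUMERIC = (
    "enrollment",
    "n_sites",
    "n_arms",
    "n_primary_outcomes",
    "n_secondary_outcomes",
    "n_countries",
    "age_min",
    "age_max",
)
DEFAULT_CHARACTERISTIC_CATEGORICAL = (
    "randomized",
    "intervention_model",
    "masking",
    "fda_regulated",
    "accepts_healthy_volunteers",
    "gender_eligibility",
    "enrollment_type",
)


def extract_characteristics(
    record: TrialRecord,
    numeric: Sequence[str] = DEFAULT_CHARACTERISTIC_NUMERIC,
    categorical: Sequence[str] = DEFAULT_CHARACTERISTIC_CATEGORICAL,
) -> dict[str, object]:
    """Study-characteristics feature mapping; missing values preserved.

    Numeric and categorical scalars pass through untouched (imputation and
    one-hot encoding are downstream concerns); multi-valued intervention
    types and recorded phases become one binary indicator each.
    """
    out: dict[str, object] = {}
    for f in numeric:
        out[f] = getattr(record, f)
    for f in categorical:
        out[f] = getattr(record, f)
    out["intervention_types"] = record.intervention_types
    for p in PHASES:
        out[f"phase_{p}"] = int(p in record.phases)
    return out
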