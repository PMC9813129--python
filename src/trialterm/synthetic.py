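"""Synthetic trial registries with a known termination mechanism.

Generates the three inputs the pipeline consumes — a delimited registry
export, an annotated (side, category, value) criteria corpus, and a
disease-category lexicon — with ground truth exposed so that recovery
tests are sharp. Records emulate the shapes of a clinicaltrials.gov
export: log-normal enrollment, Poisson site/outcome counts, categorical
design fields, a phase mix loosely matching the registry's published
phase table, eligibility free text with "Inclusion Criteria"/"Exclusion
Criteria" headers and bulleted criteria, and configurable MCAR
missingness. Success labels are drawn from a logistic model over record
features plus planted eligibility-term indicators, with the intercept
calibrated by bisection so the empirical failure rate hits the 15%
target characteristic of the real registry.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .categories import CategoryLexicon, default_lexicon
from .registry import PHASES, TrialRecord, StudyLabel
from ._normalize import normalize_tokens


@dataclass(slots=True)
class SyntheticConfig:
    """Knobs of the generator; defaults mirror the study conditions."""

    n_records: int = 1000
    failure_rate_target: float = 0.15
    n_terms: int = 200
    n_planted_signal_terms: int = 10
    planted_coefficient: float = -1.6
    characteristic_coefficient_scale: float = 0.3
    category_coefficient_scale: float = 0.3
    planted_prevalence: float = 0.30
    term_embed_probability: float = 0.35
    missingness: dict[str, float] = field(default_factory=lambda: {
        "enrollment": 0.05,
        "n_sites": 0.10,
        "n_countries": 0.10,
        "n_arms": 0.05,
        "masking": 0.10,
        "intervention_model": 0.10,
        "randomized": 0.08,
        "fda_regulated": 0.15,
        "accepts_healthy_volunteers": 0.05,
        "age_max": 0.20,
        "age_min": 0.03,
        "enrollment_type": 0.10,
        "eligibility_text": 0.02,
        "mesh_terms": 0.15,
    })
    frac_noninterventional: float = 0.05
    frac_nonfinal_status: float = 0.05
    frac_pre_cutoff_year: float = 0.05
    year_range: tuple[int, int] = (2011, 2022)
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.failure_rate_target < 1:
            raise ValueError("failure_rate_target must be in (0, 1)")
        if self.n_planted_signal_terms > self.n_terms:
            raise ValueError("cannot plant more signal terms than terms")
        for f, r in self.missingness.items():
            if not 0 <= r <= 1:
                raise ValueError(f"missingness rate for {f!r} out of [0, 1]")


@dataclass(slots=True)
class GroundTruth:
    """The generating logistic model, exposed for recovery tests."""

    intercept: float
    coefficients: dict[str, float]
    planted_terms: list[dict[str, str]]
    linear_predictor: list[float]
    registry_ids: list[str]


# word bank per entity category; values are 1-3 token seeds that modifiers
# extend up to 6 tokens
_CATEGORY_BANK: dict[str, list[str]] = {
    "Condition": [
        "diabetes", "hypertension", "asthma", "dry eye", "inflammation",
        "renal impairment", "heart failure", "hepatitis", "anemia",
        "depression", "addiction", "inability", "chronic pain", "obesity",
        "epilepsy", "migraine", "psoriasis", "sepsis",
    ],
    "Procedure": [
        "dialysis", "surgery", "organ transplant", "chemotherapy",
        "radiation therapy", "biopsy", "catheterization",
    ],
    "Person": [
        "age", "adult", "elderly", "pregnant women", "pediatric patients",
        "healthy volunteers",
    ],
    "Temporal": [
        "active", "recent", "chronic", "within six months",
        "prior treatment", "ongoing",
    ],
    "Drug": [
        "metformin", "warfarin", "insulin", "corticosteroids",
        "immunosuppressants", "anticoagulants", "statins",
    ],
    "Observation": [
        "blood pressure", "body mass index", "creatinine clearance",
        "liver enzymes", "ejection fraction",
    ],
    "Mood": ["confirmed", "suspected", "possible", "documented"],
    "Visit": ["screening visit", "baseline visit", "follow up", "outpatient clinic"],
}

_MODIFIERS = [
    "severe", "mild", "moderate", "uncontrolled", "documented", "clinically",
    "significant", "stable", "acute", "persistent", "recurrent", "known",
]

_FILLER = (
    "subject must have adequate organ function and provide written informed "
    "consent before any study procedure is performed"
).split()

_WHY_STOPPED = (
    "slow recruitment", "lack of funding", "sponsor decision",
    "safety concerns", "low enrollment",
)


def generate_term_corpus(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> tuple[list[tuple[str, str, str]], list[dict[str, str]]]:
    """Annotated (side, category, value) rows plus the planted-term list.

    Token counts span 1-6 — a handful of rows deliberately exceed the
    downstream 5-token filter — and planted signal terms are guaranteed
    to survive it (<= 5 tokens, exclusion side).
    """
    rng = rng or np.random.default_rng(config.seed)
    categories = list(_CATEGORY_BANK)
    rows: list[tuple[str, str, str]] = []
    seen: set[tuple[str, str, str]] = set()

    def add(side: str, category: str, value: str) -> bool:
        key = (side, category, " ".join(normalize_tokens(value)))
        if key in seen:
            return False
        seen.add(key)
        rows.append((side, category, value))
        return True

    planted: list[dict[str, str]] = []
    bank = _CATEGORY_BANK["Condition"]
    while len(planted) < config.n_planted_signal_terms:
        seedling = bank[rng.integers(len(bank))]
        n_mod = int(rng.integers(0, 3))
        mods = list(rng.choice(_MODIFIERS, size=n_mod, replace=False))
        value = " ".join(mods + [seedling])
        if len(value.split()) <= 5 and add("exclusion", "Condition", value):
            planted.append(
                {"side": "exclusion", "category": "Condition",
                 "value": " ".join(normalize_tokens(value))}
            )

    six_token_rows = 0
    while len(rows) < config.n_terms:
        side = "inclusion" if rng.random() < 0.5 else "exclusion"
        category = categories[rng.integers(len(categories))]
        base = _CATEGORY_BANK[category][rng.integers(len(_CATEGORY_BANK[category]))]
        want_six = six_token_rows < max(1, config.n_terms // 50)
        target_tokens = 6 if want_six else int(rng.integers(1, 6))
        base_tokens = base.split()
        n_mod = max(0, target_tokens - len(base_tokens))
        mods = list(rng.choice(_MODIFIERS, size=min(n_mod, len(_MODIFIERS)), replace=False))
        value = " ".join(mods + base_tokens)
        if add(side, category, value) and len(value.split()) >= 6:
            six_token_rows += 1
    return rows, planted


def write_term_corpus(rows: Sequence[tuple[str, str, str]], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["side", "category", "value"])
        w.writerows(rows)


def generate_lexicon(config: SyntheticConfig | None = None) -> CategoryLexicon:
    """The bundled illustrative disease-category lexicon."""
    return default_lexicon()


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def _calibrate_intercept(lp: np.ndarray, success_target: float) -> float:
    """Bisect the intercept so mean sigmoid(c + lp) hits the target."""
    lo, hi = -20.0, 20.0
    f = lambda c: float(np.mean(_sigmoid(c + lp))) - success_target
    if f(lo) > 0 or f(hi) < 0:
        raise ValueError("failure_rate_target unreachable for these coefficients")
    for _ in range(80):
        mid = (lo + hi) / 2
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


_PHASE_MIX: list[tuple[frozenset[str], float]] = [
    (frozenset(), 0.34),
    (frozenset({"early_phase1"}), 0.01),
    (frozenset({"phase1"}), 0.15),
    (frozenset({"phase1", "phase2"}), 0.04),
    (frozenset({"phase2"}), 0.18),
    (frozenset({"phase2", "phase3"}), 0.02),
    (frozenset({"phase3"}), 0.14),
    (frozenset({"phase4"}), 0.12),
]


def generate_records(
    config: SyntheticConfig,
    corpus: Sequence[tuple[str, str, str]] | None = None,
    lexicon: CategoryLexicon | None = None,
) -> tuple[list[TrialRecord], list[StudyLabel], GroundTruth]:
    """Sample records, draw labels from the logistic mechanism, inject MCAR.

    Returns the records, success/failure labels for every record whose
    status is final, and the full generating ground truth.
    """
    # records use their own stream so that supplying a pre-generated corpus
    # (from the same config) yields byte-identical records
    rng = np.random.default_rng(config.seed + 1)
    generated_corpus, planted = generate_term_corpus(config)
    if corpus is None:
        corpus = generated_corpus
    lexicon = lexicon or generate_lexicon(config)
    cat_names = sorted(lexicon.categories)
    cat_term_strings = {
        c: sorted(" ".join(t) for t in lexicon.categories[c]) for c in cat_names
    }
    inc_terms = [v for s, _c, v in corpus if s == "inclusion"]
    exc_terms = [v for s, _c, v in corpus if s == "exclusion"]
    planted_values = [p["value"] for p in planted]

    s = config.characteristic_coefficient_scale
    coef: dict[str, float] = {
        "log_enrollment": 0.8 * s,
        "n_sites": 0.5 * s,
        "n_countries": 0.4 * s,
        "accepts_healthy_volunteers": 1.0 * s,
        "n_secondary_outcomes": -0.3 * s,
        "category:neoplasms": -1.0 * config.category_coefficient_scale,
        "category:blood lymph conditions": -0.7 * config.category_coefficient_scale,
    }
    for v in planted_values:
        coef[f"term:exclusion|{v}"] = config.planted_coefficient

    phase_sets = [p for p, _ in _PHASE_MIX]
    phase_w = np.array([w for _, w in _PHASE_MIX])
    phase_w = phase_w / phase_w.sum()

    raw: list[dict] = []
    lp = np.zeros(config.n_records)
    for i in range(config.n_records):
        enrollment = float(np.round(rng.lognormal(mean=4.0, sigma=1.2)))
        n_sites = float(1 + rng.poisson(3))
        n_countries = float(1 + rng.poisson(0.5))
        n_arms = float(1 + rng.poisson(1))
        n_primary = float(1 + rng.poisson(1))
        n_secondary = float(rng.poisson(3))
        healthy = "yes" if rng.random() < 0.3 else "no"
        randomized = "yes" if rng.random() < 0.6 else "no"
        model = ["parallel assignment", "single group assignment",
                 "crossover assignment"][rng.integers(3)]
        masking = ["open label", "single", "double", "quadruple"][rng.integers(4)]
        fda = "yes" if rng.random() < 0.4 else "no"
        gender = ["all", "female", "male"][rng.choice(3, p=[0.8, 0.12, 0.08])]
        age_min = float(rng.choice([0.5, 12.0, 18.0, 18.0, 18.0, 40.0, 65.0]))
        age_max = float(rng.choice([17.0, 65.0, 75.0, 85.0, 99.0]))
        itypes = frozenset(
            rng.choice(
                ["drug", "device", "behavioral", "procedure", "biological"],
                size=int(1 + rng.integers(0, 2)), replace=False,
            )
        )
        phases = phase_sets[rng.choice(len(phase_sets), p=phase_w)]

        n_cats = int(rng.integers(1, 3))
        cats = list(rng.choice(cat_names, size=n_cats, replace=False))
        conditions = tuple(
            cat_term_strings[c][rng.integers(len(cat_term_strings[c]))] for c in cats
        )
        mesh = tuple(
            cat_term_strings[c][rng.integers(len(cat_term_strings[c]))]
            for c in cats
            if rng.random() < 0.6
        )

        present_planted = [v for v in planted_values
                           if rng.random() < config.planted_prevalence]

        def criteria(side_terms: list[str], extra: list[str]) -> list[str]:
            k = int(1 + rng.poisson(3))
            out = []
            for j in range(k):
                words = list(rng.choice(_FILLER, size=int(rng.integers(4, 9)), replace=False))
                if side_terms and rng.random() < config.term_embed_probability:
                    words.insert(int(rng.integers(0, len(words))),
                                 side_terms[rng.integers(len(side_terms))])
                out.append(" ".join(words))
            for term in extra:
                out.append(
                    " ".join([
                        "patients", "with", term, "are", "not", "eligible",
                    ])
                )
            return out

        inc_lines = criteria(inc_terms, [])
        exc_lines = criteria(exc_terms, present_planted)
        eligibility = (
            "Inclusion Criteria:\n"
            + "\n".join(f"- {c}" for c in inc_lines)
            + "\n\nExclusion Criteria:\n"
            + "\n".join(f"- {c}" for c in exc_lines)
        )

        z = (
            coef["log_enrollment"] * (np.log1p(enrollment) - 4.0) / 1.2
            + coef["n_sites"] * (n_sites - 4.0) / 2.0
            + coef["n_countries"] * (n_countries - 1.5)
            + coef["accepts_healthy_volunteers"] * (healthy == "yes")
            + coef["n_secondary_outcomes"] * (n_secondary - 3.0) / 1.7
        )
        for c in cats:
            z += coef.get(f"category:{c}", 0.0)
        for v in present_planted:
            z += coef[f"term:exclusion|{v}"]
        lp[i] = z

        raw.append(dict(
            registry_id=f"NCT{90000000 + i}",
            enrollment=enrollment, n_sites=n_sites, n_countries=n_countries,
            n_arms=n_arms, n_primary_outcomes=n_primary,
            n_secondary_outcomes=n_secondary,
            accepts_healthy_volunteers=healthy, randomized=randomized,
            intervention_model=model, masking=masking, fda_regulated=fda,
            gender_eligibility=gender, age_min=age_min, age_max=age_max,
            intervention_types=itypes, phases=phases, conditions=conditions,
            mesh_terms=mesh, eligibility_text=eligibility,
            enrollment_type="anticipated" if rng.random() < 0.5 else "actual",
        ))

    intercept = _calibrate_intercept(lp, 1.0 - config.failure_rate_target)
    success = rng.random(config.n_records) < _sigmoid(intercept + lp)

    lo_year, hi_year = config.year_range
    records: list[TrialRecord] = []
    labels: list[StudyLabel] = []
    for i, kw in enumerate(raw):
        if rng.random() < config.frac_pre_cutoff_year:
            year = int(rng.integers(max(1999, lo_year - 8), lo_year))
        else:
            year = int(rng.integers(lo_year, hi_year + 1))
        kw["start_year"] = year
        kw["study_type"] = (
            ["observational", "patient_registry"][rng.integers(2)]
            if rng.random() < config.frac_noninterventional
            else "interventional"
        )
        if rng.random() < config.frac_nonfinal_status:
            kw["overall_status"] = ["recruiting", "unknown", "active_not_recruiting",
                                    "suspended"][rng.integers(4)]
            kw["why_stopped"] = None
        elif success[i]:
            kw["overall_status"] = "completed"
            kw["why_stopped"] = None
        else:
            kw["overall_status"] = "terminated" if rng.random() < 0.7 else "withdrawn"
            kw["why_stopped"] = _WHY_STOPPED[rng.integers(len(_WHY_STOPPED))]

        for f, rate in config.missingness.items():
            if rng.random() < rate:
                kw[f] = (
                    () if f in ("conditions", "mesh_terms")
                    else frozenset() if f == "intervention_types"
                    else None
                )
        record = TrialRecord(**kw)
        records.append(record)
        if record.overall_status in ("completed", "terminated", "withdrawn"):
            labels.append(StudyLabel(record.registry_id, int(success[i])))

    truth = GroundTruth(
        intercept=intercept,
        coefficients=coef,
        planted_terms=planted,
        linear_predictor=[float(v) for v in lp],
        registry_ids=[r.registry_id for r in records],
    )
    return records, labels, truth


_EXPORT_STATUS = {
    "completed": "Completed", "terminated": "Terminated",
    "withdrawn": "Withdrawn", "recruiting": "Recruiting",
    "unknown": "Unknown status", "active_not_recruiting": "Active, not recruiting",
    "suspended": "Suspended",
}
_EXPORT_PHASE = {
    "early_phase1": "Early Phase 1", "phase1": "Phase 1", "phase2": "Phase 2",
    "phase3": "Phase 3", "phase4": "Phase 4",
}
_EXPORT_TYPE = {
    "interventional": "Interventional", "observational": "Observational",
    "patient_registry": "Patient Registry",
}


def write_registry_export(
    records: Sequence[TrialRecord], path, delimiter: str = "|"
) -> None:
    """Write records as a delimited export readable by registry ingestion.

    The round trip through :func:`trialterm.registry.read_registry_table`
    with the default column map is field-equal.
    """
    cols = [
        "nct_id", "study_type", "overall_status", "start_year", "phase",
        "enrollment", "enrollment_type", "number_of_facilities",
        "number_of_arms", "number_of_primary_outcomes",
        "number_of_secondary_outcomes", "number_of_countries", "allocation",
        "intervention_model", "intervention_types", "masking",
        "is_fda_regulated_drug", "healthy_volunteers", "gender",
        "minimum_age", "maximum_age", "conditions", "mesh_terms",
        "eligibility_criteria", "why_stopped",
    ]

    def fmt_num(v):
        return "" if v is None else repr(float(v))

    def fmt_age(v):
        return "" if v is None else f"{v:g} Years"

    def fmt_tri(v, yes="Yes", no="No"):
        return "" if v is None else (yes if v == "yes" else no)

    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter=delimiter, quoting=csv.QUOTE_MINIMAL)
        w.writerow(cols)
        for r in records:
            w.writerow([
                r.registry_id,
                _EXPORT_TYPE.get(r.study_type, r.study_type or ""),
                _EXPORT_STATUS.get(r.overall_status, r.overall_status or ""),
                "" if r.start_year is None else str(r.start_year),
                "/".join(_EXPORT_PHASE[p] for p in sorted(r.phases, key=PHASES.index)),
                fmt_num(r.enrollment),
                r.enrollment_type or "",
                fmt_num(r.n_sites),
                fmt_num(r.n_arms),
                fmt_num(r.n_primary_outcomes),
                fmt_num(r.n_secondary_outcomes),
                fmt_num(r.n_countries),
                fmt_tri(r.randomized, "Randomized", "Non-Randomized"),
                r.intervention_model or "",
                ";".join(sorted(r.intervention_types)),
                r.masking or "",
                fmt_tri(r.fda_regulated),
                fmt_tri(r.accepts_healthy_volunteers),
                r.gender_eligibility or "",
                fmt_age(r.age_min),
                fmt_age(r.age_max),
                ";".join(r.conditions),
                ";".join(r.mesh_terms),
                r.eligibility_text or "",
                r.why_stopped or "",
            ])
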