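"""Registry ingestion: parsing, filtering, labelling, phase subsets."""

import pytest

from trialterm.registry import (
    ConfigurationError,
    DEFAULT_MISSING_FIELDS,
    InvalidStatusError,
    TrialRecord,
    assign_label,
    extract_characteristics,
    filter_records,
    missing_rate_by_year,
    parse_age_years,
    phase_subsets,
    read_registry_table,
)
from trialterm.synthetic import write_registry_export


def make_record(**kw):
    base = dict(
        registry_id="NCT0001",
        study_type="interventional",
        overall_status="completed",
        start_year=2015,
    )
    base.update(kw)
    return TrialRecord(**base)


class TestReadRegistryTable:
    def test_row_count_preserved(self, tmp_path):
        p = tmp_path / "x.psv"
        p.write_text(
            "nct_id|study_type|overall_status|start_year|enrollment\n"
            "A|Interventional|Completed|2015|100\n"
            "B|Observational|Terminated|2016|50\n"
            "C|Interventional|Recruiting|2017|N/A\n"
        )
        cmap = {"nct_id": "registry_id", "study_type": "study_type",
                "overall_status": "overall_status", "start_year": "start_year",
                "enrollment": "enrollment"}
        records = read_registry_table(p, "|", cmap)
        assert len(records) == 3
        assert records[0].enrollment == 100.0
        # unparseable numeric becomes missing, not an error
        assert records[2].enrollment is None

    def test_missing_mapped_column_is_config_error(self, tmp_path):
        p = tmp_path / "x.psv"
        p.write_text("nct_id|foo\nA|1\n")
        with pytest.raises(ConfigurationError, match="enrollment"):
            read_registry_table(p, "|", {"nct_id": "registry_id",
                                         "enrollment": "enrollment"})

    def test_empty_file_warns_and_returns_empty(self, tmp_path):
        p = tmp_path / "empty.psv"
        p.write_text("")
        with pytest.warns(UserWarning, match="empty"):
            assert read_registry_table(p, "|", {}) == []

    def test_synthetic_round_trip_field_equal(self, small_registry, tmp_path):
        records, _, _ = small_registry
        p = tmp_path / "export.psv"
        write_registry_export(records, p)
        assert read_registry_table(p, "|") == records


class TestFilterRecords:
    def test_non_final_status_removed(self):
        assert filter_records([make_record(overall_status="recruiting")]) == []
        assert filter_records([make_record(overall_status="unknown")]) == []

    def test_year_cutoff_boundary(self):
        kept_2011 = make_record(start_year=2011)
        assert filter_records([make_record(start_year=2010), kept_2011]) == [kept_2011]

    def test_observational_removed_even_if_terminated(self):
        r = make_record(study_type="observational", overall_status="terminated")
        assert filter_records([r]) == []

    def test_missing_year_removed(self):
        assert filter_records([make_record(start_year=None)]) == []

    def test_idempotent_and_order_preserving(self, small_registry):
        records, _, _ = small_registry
        once = filter_records(records)
        assert filter_records(once) == once
        positions = {r.registry_id: i for i, r in enumerate(records)}
        assert sorted(once, key=lambda r: positions[r.registry_id]) == once


class TestAssignLabel:
    @pytest.mark.parametrize("status,label", [
        ("completed", 1), ("terminated", 0), ("withdrawn", 0),
    ])
    def test_final_statuses(self, status, label):
        assert assign_label(make_record(overall_status=status)).label == label

    def test_non_final_status_raises(self):
        with pytest.raises(InvalidStatusError):
            assign_label(make_record(overall_status="recruiting"))

    def test_label_partition_over_filtered_cohort(self, small_registry):
        records, _, _ = small_registry
        filtered = filter_records(records)
        labels = [assign_label(r).label for r in filtered]
        assert len(labels) == len(filtered)
        assert set(labels) <= {0, 1}


class TestPhaseSubsets:
    def test_two_phase_record_in_both_subsets(self):
        r = make_record(phases=frozenset({"phase2", "phase3"}))
        subsets = phase_subsets([r])
        assert r in subsets["phase2"] and r in subsets["phase3"]

    def test_single_phase_record_only_in_its_subset_and_all(self):
        r = make_record(phases=frozenset({"phase1"}))
        subsets = phase_subsets([r])
        membership = [k for k, v in subsets.items() if r in v]
        assert sorted(membership) == ["all", "phase1"]

    def test_multiplicity_conservation(self, small_registry):
        records, _, _ = small_registry
        subsets = phase_subsets(records)
        total = sum(len(v) for k, v in subsets.items() if k != "all")
        assert total == sum(len(r.phases) for r in records)
        assert len(subsets["all"]) == len(records)


class TestMissingRateByYear:
    def test_hand_counted_rate(self):
        fields = list(DEFAULT_MISSING_FIELDS)
        assert len(fields) == 24
        complete = make_record(
            start_year=2015,
            phases=frozenset({"phase1"}), enrollment=1.0, enrollment_type="actual",
            n_sites=1.0, n_arms=1.0, n_primary_outcomes=1.0,
            n_secondary_outcomes=1.0, n_countries=1.0, randomized="yes",
            intervention_model="parallel", intervention_types=frozenset({"drug"}),
            masking="double", fda_regulated="yes", accepts_healthy_volunteers="no",
            gender_eligibility="all", age_min=18.0, age_max=65.0,
            conditions=("asthma",), mesh_terms=("asthma",),
            eligibility_text="Inclusion Criteria: adults.", why_stopped="n/a-filled",
        )
        # remove 6 of the 24 tracked fields
        partial = TrialRecord(**{
            **{f: getattr(complete, f) for f in complete.__dataclass_fields__},
            "enrollment": None, "n_sites": None, "masking": None,
            "age_max": None, "mesh_terms": (), "why_stopped": None,
            "registry_id": "NCT0002",
        })
        rates = missing_rate_by_year([complete, partial], fields)
        assert rates == {2015: 3.0}

    def test_bounded_by_field_count_and_order_invariant(self, small_registry):
        records, _, _ = small_registry
        rates = missing_rate_by_year(records)
        assert all(0 <= v <= 24 for v in rates.values())
        assert missing_rate_by_year(list(reversed(records))) == rates

    def test_unknown_field_is_config_error(self):
        with pytest.raises(ConfigurationError, match="no_such"):
            missing_rate_by_year([make_record()], ["no_such_field"])


class TestExtractCharacteristics:
    def test_outcome_counts_are_two_distinct_features(self):
        r = make_record(n_primary_outcomes=2.0, n_secondary_outcomes=5.0)
        feats = extract_characteristics(r)
        assert feats["n_primary_outcomes"] == 2.0
        assert feats["n_secondary_outcomes"] == 5.0

    def test_missing_preserved_and_count_matches_config(self):
        feats = extract_characteristics(make_record(n_sites=None))
        assert feats["n_sites"] is None
        # 8 numeric + 7 categorical + intervention_types + 5 phase flags
        assert len(feats) == 21

    def test_phase_indicators(self):
        feats = extract_characteristics(
            make_record(phases=frozenset({"phase2", "phase3"}))
        )
        assert feats["phase_phase2"] == 1 and feats["phase_phase3"] == 1
        assert feats["phase_phase1"] == 0


@pytest.mark.parametrize("raw,expected", [
    ("18 Years", 18.0), ("6 Months", 0.5), ("2 weeks", 14.0 / 365.25),
    ("garbage", None), (None, None), (30, 30.0),
])
def test_age_parsing(raw, expected):
    got = parse_age_years(raw)
    if expected is None:
        assert got is None
    else:
        assert got == pytest.approx(expected)
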