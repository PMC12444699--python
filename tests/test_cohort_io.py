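import numpy as np
import pandas as pd
import pytest

from asthmacast.cohort import (
    AdmissionRecord,
    aggregate_records_to_series,
    classify_admission,
)
from asthmacast.io import (
    CsvFormatError,
    RunConfig,
    read_admissions_csv,
    write_admissions_csv,
)
from asthmacast.synthetic import reference_config, generate_series

from conftest import daily


def _record(**kw):
    base = dict(
        primary_code="J45.901",
        secondary_codes=(),
        has_exacerbation_or_status=True,
        exclusion_flags=frozenset(),
        admit_date="2020-03-01",
    )
    base.update(kw)
    return AdmissionRecord(**base)


class TestClassifyAdmission:
    def test_primary_asthma_with_exacerbation_qualifies(self):
        assert classify_admission(_record())

    def test_requires_exacerbation_or_status(self):
        assert not classify_admission(_record(has_exacerbation_or_status=False))

    def test_exclusion_condition_disqualifies(self):
        assert not classify_admission(
            _record(exclusion_flags=frozenset({"cystic_fibrosis"}))
        )

    def test_secondary_pathway(self):
        rec = _record(primary_code="J18.9", secondary_codes=("J45.41",))
        assert classify_admission(rec)
        # respiratory primary without a secondary J45 does not qualify
        assert not classify_admission(_record(primary_code="J18.9"))
        # non-respiratory primary with secondary J45 does not qualify
        assert not classify_admission(
            _record(primary_code="K21.9", secondary_codes=("J45.41",))
        )

    def test_flipping_any_required_condition_flips_result(self):
        base = _record(primary_code="J45.42")
        assert classify_admission(base)
        variants = [
            _record(primary_code="K21.9"),  # lose the asthma pathway
            _record(primary_code="J45.42", has_exacerbation_or_status=False),
            _record(primary_code="J45.42", exclusion_flags=frozenset({"sickle_cell"})),
        ]
        for v in variants:
            assert not classify_admission(v)

    def test_malformed_code_rejected(self):
        with pytest.raises(ValueError, match="malformed"):
            AdmissionRecord(primary_code="asthma")


class TestAggregateRecords:
    def test_empty_records_give_zero_series(self):
        s = aggregate_records_to_series([], "2020-01-01", "2020-01-10")
        assert len(s) == 10 and s.counts.sum() == 0

    def test_mixed_day_counts_qualifying_only(self):
        recs = [_record() for _ in range(3)] + [
            _record(has_exacerbation_or_status=False) for _ in range(2)
        ]
        s = aggregate_records_to_series(recs, "2020-03-01", "2020-03-03")
        assert list(s.counts) == [3, 0, 0]

    def test_agrees_with_brute_force_filter(self):
        rng = np.random.default_rng(3)
        dates = pd.date_range("2021-01-01", "2021-01-31")
        primaries = ["J45.901", "J18.9", "K21.9", "R05"]
        records = []
        for _ in range(200):
            records.append(
                AdmissionRecord(
                    primary_code=primaries[rng.integers(4)],
                    secondary_codes=("J45.41",) if rng.random() < 0.5 else (),
                    has_exacerbation_or_status=bool(rng.random() < 0.7),
                    exclusion_flags=frozenset(
                        {"tracheostomy"} if rng.random() < 0.1 else set()
                    ),
                    admit_date=dates[rng.integers(31)],
                )
            )
        s = aggregate_records_to_series(records, dates[0], dates[-1])
        for i, d in enumerate(dates):
            expected = sum(
                1
                for r in records
                if r.admit_date == d and classify_admission(r)
            )
            assert s.counts[i] == expected


class TestSeriesCsv:
    def test_round_trip_identity(self, tmp_path):
        series = generate_series(reference_config(7), "2021-01-01", "2021-06-30")
        path = tmp_path / "series.csv"
        write_admissions_csv(series, path)
        back = read_admissions_csv(path)
        assert (back.counts == series.counts).all()
        assert (back.dates == series.dates).all()

    def test_duplicate_date_reported(self, tmp_path):
        p = tmp_path / "dup.csv"
        p.write_text("date,count\n2020-01-01,1\n2020-01-01,2\n")
        with pytest.raises(CsvFormatError, match="2020-01-01"):
            read_admissions_csv(p)

    def test_gap_errors_unless_fill_zeros(self, tmp_path):
        p = tmp_path / "gap.csv"
        p.write_text("date,count\n2020-01-01,1\n2020-01-03,2\n")
        with pytest.raises(CsvFormatError, match="missing dates"):
            read_admissions_csv(p)
        s = read_admissions_csv(p, fill_zeros=True)
        assert list(s.counts) == [1, 0, 2]

    def test_negative_count_line_number(self, tmp_path):
        p = tmp_path / "neg.csv"
        p.write_text("date,count\n2020-01-01,1\n2020-01-02,-3\n")
        with pytest.raises(CsvFormatError, match="line 3"):
            read_admissions_csv(p)


class TestRunConfig:
    def test_yaml_round_trip(self, tmp_path):
        cfg = RunConfig(seed=17, training_years=3)
        path = tmp_path / "run.yaml"
        cfg.to_yaml(path)
        back = RunConfig.from_yaml(path)
        assert back.seed == 17
        assert back.training_years == 3
        assert back.generator.to_dict() == cfg.generator.to_dict()
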