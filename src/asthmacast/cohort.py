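"""Admission-definition classifier on diagnosis records.

An admission counts toward the daily asthma series when:

* the primary diagnosis is an asthma (J45*) ICD-10-CM code, or the
  primary diagnosis belongs to a configurable set of respiratory
  presentations (respiratory infection, cough, non-chronic respiratory
  failure, shortness of breath, hypoxemia) with a secondary J45* code; and
* a code for acute exacerbation or status asthmaticus is present; and
* none of the exclusion conditions applies (cystic fibrosis, congenital
  heart disease, chronic respiratory failure, sickle cell disease,
  tracheostomy, ventilator dependence).

The exact institutional code lists for the secondary pathway are not
public, so the primary-diagnosis set is explicit configuration; the
default below is an approximation assembled from the standard ICD-10-CM
chapters for those presentations.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .series import DailySeries

__all__ = [
    "AdmissionRecord",
    "classify_admission",
    "aggregate_records_to_series",
    "DEFAULT_RESPIRATORY_PRIMARY_PREFIXES",
    "EXCLUSION_CONDITIONS",
]

_ICD_PATTERN = re.compile(r"^[A-Z]\d{2}(\.\w{1,4})?$")

EXCLUSION_CONDITIONS = frozenset(
    {
        "cystic_fibrosis",
        "congenital_heart_disease",
        "chronic_respiratory_failure",
        "sickle_cell",
        "tracheostomy",
        "ventilator_dependent",
    }
)

# Approximate prefix list for the respiratory-presentation primary pathway:
# respiratory infections (J00-J22, J40), cough (R05), acute respiratory
# failure (J96.0), shortness of breath (R06.0), hypoxemia (R09.02).
DEFAULT_RESPIRATORY_PRIMARY_PREFIXES = (
    "J0", "J1", "J2", "J40", "R05", "J96.0", "R06.0", "R09.02",
)


@dataclass(frozen=True)
class AdmissionRecord:
    primary_code: str
    secondary_codes: tuple[str, ...] = ()
    has_exacerbation_or_status: bool = False
    exclusion_flags: frozenset = frozenset()
    admit_date: pd.Timestamp | None = None

    def __post_init__(self) -> None:
        for code in (self.primary_code, *self.secondary_codes):
            if not _ICD_PATTERN.match(code):
                raise ValueError(f"malformed ICD-10-CM code: {code!r}")
        bad = set(self.exclusion_flags) - EXCLUSION_CONDITIONS
        if bad:
            raise ValueError(f"unknown exclusion flags: {sorted(bad)}")
        object.__setattr__(self, "secondary_codes", tuple(self.secondary_codes))
        object.__setattr__(self, "exclusion_flags", frozenset(self.exclusion_flags))
        if self.admit_date is not None:
            object.__setattr__(self, "admit_date", pd.Timestamp(self.admit_date))


def classify_admission(
    record: AdmissionRecord,
    respiratory_primary_set: tuple[str, ...] = DEFAULT_RESPIRATORY_PRIMARY_PREFIXES,
) -> bool:
    """Pure predicate: does the record count as an asthma admission?"""
    if record.exclusion_flags:
        return False
    if not record.has_exacerbation_or_status:
        return False
    if record.primary_code.startswith("J45"):
        return True
    primary_respiratory = any(
        record.primary_code.startswith(p) for p in respiratory_primary_set
    )
    secondary_asthma = any(c.startswith("J45") for c in record.secondary_codes)
    return primary_respiratory and secondary_asthma


def aggregate_records_to_series(
    records: list[AdmissionRecord],
    start,
    end,
    respiratory_primary_set: tuple[str, ...] = DEFAULT_RESPIRATORY_PRIMARY_PREFIXES,
) -> DailySeries:
    """Daily qualifying-admission counts over [start, end]; 0 on empty days."""
    start, end = pd.Timestamp(start), pd.Timestamp(end)
    dates = pd.date_range(start, end, freq="D")
    pos = {d: i for i, d in enumerate(dates)}
    counts = np.zeros(len(dates), dtype=np.int64)
    for rec in records:
        if rec.admit_date is None:
            raise ValueError("record has no admit_date")
        if rec.admit_date not in pos:
            raise ValueError(
                f"record dated {rec.admit_date.date()} outside "
                f"[{start.date()}, {end.date()}]"
            )
        if classify_admission(rec, respiratory_primary_set):
            counts[pos[rec.admit_date]] += 1
    return DailySeries(dates, counts)
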