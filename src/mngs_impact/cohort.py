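"""Patient-level cohort model: schema, CSV I/O, exclusion filtering, aggregation.

A cohort is a list of :class:`PatientRecord` rows, one per patient, covering
two arms: a confirmed-infection arm (etiology one of five pathogen
categories) and an autoimmune-encephalitis arm (etiology ``none``).  The
resource-use fields record what the standard-of-care workup actually
consumed: lumbar punctures, etiologic/microbiological tests, and days until
an etiologic diagnosis (infectious arm) or until infection was ruled out
(autoimmune arm).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Exact on-disk column order for cohort CSV files.
COHORT_COLUMNS = [
    "patient_id",
    "cohort_arm",
    "etiology",
    "lp_count",
    "test_count",
    "days_to_outcome",
    "diagnosed_within_48h",
    "record_complete",
]


class CohortArm(str, enum.Enum):
    INFECTIOUS = "infectious"
    AUTOIMMUNE = "autoimmune"


class Etiology(str, enum.Enum):
    DNA_VIRUS = "dna_virus"
    RNA_VIRUS = "rna_virus"
    BACTERIA = "bacteria"
    FUNGUS = "fungus"
    PARASITE = "parasite"
    NONE = "none"  # autoimmune arm only


#: Infectious pathogen categories in canonical display order.
INFECTIOUS_ETIOLOGIES = (
    Etiology.DNA_VIRUS,
    Etiology.RNA_VIRUS,
    Etiology.BACTERIA,
    Etiology.FUNGUS,
    Etiology.PARASITE,
)


class CohortValidationError(ValueError):
    """A record violates the cohort schema or an invariant."""


class CohortSchemaError(ValueError):
    """A cohort file is missing required columns."""


class EmptyCategoryError(ValueError):
    """No included records exist for the requested etiology."""


@dataclass(frozen=True)
class PatientRecord:
    """One patient's observed diagnostic resource use and etiology label.

    ``days_to_outcome`` is days to etiologic diagnosis in the infectious arm
    and days to infection rule-out in the autoimmune arm; one field, one
    schema.
    """

    patient_id: str
    cohort_arm: CohortArm
    etiology: Etiology
    lp_count: int
    test_count: int
    days_to_outcome: float
    diagnosed_within_48h: bool
    record_complete: bool

    def __post_init__(self) -> None:
        if (self.etiology is Etiology.NONE) != (self.cohort_arm is CohortArm.AUTOIMMUNE):
            raise CohortValidationError(
                f"patient {self.patient_id!r}: etiology 'none' if and only if "
                f"autoimmune arm (got arm={self.cohort_arm.value}, "
                f"etiology={self.etiology.value})"
            )
        if self.lp_count < 0 or self.test_count < 0:
            raise CohortValidationError(
                f"patient {self.patient_id!r}: negative resource count"
            )
        if self.days_to_outcome < 0:
            raise CohortValidationError(
                f"patient {self.patient_id!r}: negative days_to_outcome"
            )
        if self.days_to_outcome <= 2 and not self.diagnosed_within_48h:
            raise CohortValidationError(
                f"patient {self.patient_id!r}: outcome within 2 days requires "
                "diagnosed_within_48h=True"
            )
        # A CSF test implies at least one lumbar puncture for records that
        # would survive exclusion.
        if (
            self.test_count >= 1
            and self.lp_count < 1
            and self.record_complete
            and not self.diagnosed_within_48h
        ):
            raise CohortValidationError(
                f"patient {self.patient_id!r}: test_count >= 1 requires lp_count >= 1"
            )


@dataclass(frozen=True)
class CategorySummary:
    """Per-etiology aggregate: counts, totals, and unrounded means."""

    etiology: Etiology
    n_patients: int
    total_lps: int
    total_tests: int
    total_days: float
    mean_lps: float
    mean_tests: float
    mean_days: float

    @classmethod
    def from_totals(
        cls,
        etiology: Etiology,
        n_patients: int,
        total_lps: int,
        total_tests: int,
        total_days: float,
    ) -> "CategorySummary":
        if n_patients <= 0:
            raise EmptyCategoryError(f"no patients for etiology {etiology.value!r}")
        return cls(
            etiology=etiology,
            n_patients=n_patients,
            total_lps=total_lps,
            total_tests=total_tests,
            total_days=total_days,
            mean_lps=total_lps / n_patients,
            mean_tests=total_tests / n_patients,
            mean_days=total_days / n_patients,
        )

    @classmethod
    def from_means(
        cls,
        etiology: Etiology,
        n_patients: int,
        mean_lps: float,
        mean_tests: float,
        mean_days: float,
    ) -> "CategorySummary":
        """Build a summary from printed per-patient means (replication input)."""
        if n_patients <= 0:
            raise EmptyCategoryError(f"no patients for etiology {etiology.value!r}")
        return cls(
            etiology=etiology,
            n_patients=n_patients,
            total_lps=round(mean_lps * n_patients),
            total_tests=round(mean_tests * n_patients),
            total_days=mean_days * n_patients,
            mean_lps=mean_lps,
            mean_tests=mean_tests,
            mean_days=mean_days,
        )


def round_half_up(x: float, decimals: int = 1) -> float:
    """Display rounding: half-up to ``decimals`` places (1.15 -> 1.2)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _parse_bool(value: object, row: int, column: str) -> bool:
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text in {"true", "1", "yes"}:
        return True
    if text in {"false", "0", "no"}:
        return False
    raise CohortValidationError(f"row {row}: unparseable boolean {value!r} in {column}")


def load_cohort(path: str | Path, delimiter: str = ",") -> list[PatientRecord]:
    """Read a cohort CSV into validated :class:`PatientRecord` rows.

    The file must carry a header naming every cohort column.  Row order is
    preserved.  Raises :class:`CohortSchemaError` for missing columns and
    :class:`CohortValidationError` with the offending row index for bad
    values.
    """
    path = Path(path)
    df = pd.read_csv(path, delimiter=delimiter, dtype=str, keep_default_na=False)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortSchemaError(f"{path}: missing column(s) {', '.join(missing)}")
    records: list[PatientRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            arm = CohortArm(getattr(row, "cohort_arm"))
            etiology = Etiology(getattr(row, "etiology"))
        except ValueError as exc:
            raise CohortValidationError(f"row {i}: {exc}") from exc
        try:
            lp = int(getattr(row, "lp_count"))
            tests = int(getattr(row, "test_count"))
            days = float(getattr(row, "days_to_outcome"))
        except ValueError as exc:
            raise CohortValidationError(f"row {i}: unparseable numeric: {exc}") from exc
        records.append(
            PatientRecord(
                patient_id=str(getattr(row, "patient_id")),
                cohort_arm=arm,
                etiology=etiology,
                lp_count=lp,
                test_count=tests,
                days_to_outcome=days,
                diagnosed_within_48h=_parse_bool(
                    getattr(row, "diagnosed_within_48h"), i, "diagnosed_within_48h"
                ),
                record_complete=_parse_bool(
                    getattr(row, "record_complete"), i, "record_complete"
                ),
            )
        )
    return records


def cohort_to_frame(records: Iterable[PatientRecord]) -> pd.DataFrame:
    rows = [
        {
            "patient_id": r.patient_id,
            "cohort_arm": r.cohort_arm.value,
            "etiology": r.etiology.value,
            "lp_count": r.lp_count,
            "test_count": r.test_count,
            "days_to_outcome": repr(r.days_to_outcome),
            "diagnosed_within_48h": r.diagnosed_within_48h,
            "record_complete": r.record_complete,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def write_cohort(records: Sequence[PatientRecord], path: str | Path) -> None:
    """Write records as UTF-8 comma-separated text with a header row.

    Floats are serialized with ``repr`` so a write/load round trip is exact.
    """
    cohort_to_frame(records).to_csv(Path(path), index=False)


def apply_exclusions(records: Sequence[PatientRecord]) -> list[PatientRecord]:
    """Drop patients diagnosed within 48 hours and incomplete records.

    The early-diagnosis stratum is removed to isolate the population in which
    an early mNGS result could have changed the workup; incomplete medical
    records cannot contribute resource counts.  Input is untouched; the
    operation is idempotent.
    """
    excluded_48h = sum(1 for r in records if r.diagnosed_within_48h)
    excluded_incomplete = sum(
        1 for r in records if not r.record_complete and not r.diagnosed_within_48h
    )
    kept = [r for r in records if not r.diagnosed_within_48h and r.record_complete]
    logger.info(
        "exclusions: %d diagnosed within 48h, %d incomplete records; %d of %d kept",
        excluded_48h,
        excluded_incomplete,
        len(kept),
        len(records),
    )
    return kept


def summarize(records: Iterable[PatientRecord], etiology: Etiology) -> CategorySummary:
    """Aggregate one etiology category: exact totals and unrounded means.

    Raises :class:`EmptyCategoryError` when the category has no records —
    an empty category is a configuration problem, never a zero-filled row.
    """
    subset = [r for r in records if r.etiology is etiology]
    if not subset:
        raise EmptyCategoryError(f"no records with etiology {etiology.value!r}")
    return CategorySummary.from_totals(
        etiology=etiology,
        n_patients=len(subset),
        total_lps=sum(r.lp_count for r in subset),
        total_tests=sum(r.test_count for r in subset),
        total_days=sum(r.days_to_outcome for r in subset),
    )


def summarize_all(records: Sequence[PatientRecord]) -> dict[Etiology, CategorySummary]:
    """Summaries for every etiology present, in canonical order."""
    present = [e for e in Etiology if any(r.etiology is e for r in records)]
    return {e: summarize(records, e) for e in present}


def summaries_to_frame(
    summaries: Iterable[CategorySummary], display_decimals: int = 1
) -> pd.DataFrame:
    """Tabulate summaries with both unrounded and display-rounded means."""
    rows = []
    for s in summaries:
        rows.append(
            {
                "etiology": s.etiology.value,
                "n_patients": s.n_patients,
                "total_lps": s.total_lps,
                "total_tests": s.total_tests,
                "total_days": s.total_days,
                "mean_lps": s.mean_lps,
                "mean_tests": s.mean_tests,
                "mean_days": s.mean_days,
                "mean_lps_display": round_half_up(s.mean_lps, display_decimals),
                "mean_tests_display": round_half_up(s.mean_tests, display_decimals),
                "mean_days_display": round_half_up(s.mean_days, display_decimals),
            }
        )
    return pd.DataFrame(rows)
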