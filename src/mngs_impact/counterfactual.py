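"""Early-mNGS counterfactual: expected concordant patients and resources avoided.

The model contrasts observed standard-of-care resource use with a simplified
early-mNGS pathway.  Patients whose result would be concordant (true
positives in the infection arm, true negatives in the autoimmune arm) are
assigned a fixed scenario — 1 LP, 1 etiologic test and 2 days for a positive
result; 1 LP, 0 further tests and 2 days for a negative one — and the
difference from the observed per-patient averages, summed over concordant
patients and floored, is the projected saving.

Floor rounding is applied at both stages: the expected concordant count is
``floor(predictive_value * n)`` and each savings column is
``floor(n_concordant * (observed mean - scenario))``, clamped at zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .bayes import PretestPrior, TestCharacteristics, adjusted_npv, adjusted_ppv
from .cohort import CategorySummary, Etiology, round_half_up

logger = logging.getLogger(__name__)

#: Guard against binary-float products landing epsilon below an integer.
_FLOOR_EPS = 1e-9


class ConfigurationError(ValueError):
    """Inconsistent model inputs (e.g. a prior without a matching summary)."""


@dataclass(frozen=True)
class CounterfactualScenario:
    """Fixed per-patient resource use under the early-mNGS pathway."""

    lps_per_patient: int
    tests_per_patient: int
    days_to_result: float

    def __post_init__(self) -> None:
        if min(self.lps_per_patient, self.tests_per_patient, self.days_to_result) < 0:
            raise ValueError("scenario resource use must be non-negative")


#: True-positive pathway: one diagnostic LP, one confirmatory test, ~48 h result.
POSITIVE_SCENARIO = CounterfactualScenario(1, 1, 2.0)
#: True-negative pathway: one LP, no further microbiological workup, ~48 h result.
NEGATIVE_SCENARIO = CounterfactualScenario(1, 0, 2.0)


@dataclass(frozen=True)
class ImpactEstimate:
    """One output row: projected savings for an etiology category."""

    etiology: Etiology
    predictive_value: float
    n_patients: int
    n_concordant: int
    lps_avoided: int
    tests_avoided: int
    days_saved: int

    def __post_init__(self) -> None:
        if self.n_concordant > self.n_patients:
            raise ValueError("n_concordant cannot exceed n_patients")
        if min(self.lps_avoided, self.tests_avoided, self.days_saved) < 0:
            raise ValueError("savings must be non-negative")


def _floor(x: float) -> int:
    return math.floor(x + _FLOOR_EPS)


def expected_concordant(predictive_value: float, n: int) -> int:
    """Expected number of concordant mNGS results among n patients.

    floor(predictive_value * n): the model counts whole patients and never
    rounds a fractional patient up.
    """
    if not (0.0 <= predictive_value <= 1.0):
        raise ValueError(f"predictive_value must be in [0, 1], got {predictive_value}")
    if n < 0:
        raise ValueError(f"n must be non-negative, got {n}")
    return _floor(predictive_value * n)


def _savings_column(n_concordant: int, observed_mean: float, scenario_value: float, label: str) -> int:
    diff = observed_mean - scenario_value
    if diff < 0:
        logger.warning(
            "scenario %s (%g) exceeds observed mean (%g); clamping saving to 0",
            label,
            scenario_value,
            observed_mean,
        )
        return 0
    return _floor(n_concordant * diff)


def category_savings(
    summary: CategorySummary,
    n_concordant: int,
    scenario: CounterfactualScenario,
    predictive_value: float = float("nan"),
    *,
    replication_mode: bool = False,
) -> ImpactEstimate:
    """Savings for one category given its concordant-patient count.

    In replication mode the observed means enter at 1-decimal printed
    precision (half-up), matching arithmetic done from a published table; by
    default the unrounded means are used.
    """
    if n_concordant > summary.n_patients:
        raise ValueError(
            f"n_concordant={n_concordant} exceeds category size {summary.n_patients}"
        )
    if replication_mode:
        mean_lps = round_half_up(summary.mean_lps, 1)
        mean_tests = round_half_up(summary.mean_tests, 1)
        mean_days = round_half_up(summary.mean_days, 1)
    else:
        mean_lps, mean_tests, mean_days = (
            summary.mean_lps,
            summary.mean_tests,
            summary.mean_days,
        )
    return ImpactEstimate(
        etiology=summary.etiology,
        predictive_value=predictive_value,
        n_patients=summary.n_patients,
        n_concordant=n_concordant,
        lps_avoided=_savings_column(
            n_concordant, mean_lps, scenario.lps_per_patient, "LPs"
        ),
        tests_avoided=_savings_column(
            n_concordant, mean_tests, scenario.tests_per_patient, "tests"
        ),
        days_saved=_savings_column(
            n_concordant, mean_days, scenario.days_to_result, "days"
        ),
    )


def impact_table(
    summaries: Mapping[Etiology, CategorySummary],
    tc: TestCharacteristics,
    priors: Sequence[PretestPrior],
    positive_scenario: CounterfactualScenario = POSITIVE_SCENARIO,
    negative_scenario: CounterfactualScenario = NEGATIVE_SCENARIO,
    *,
    infection_prior: float = 0.10,
    replication_mode: bool = False,
    autoimmune_n_concordant: int | None = None,
) -> list[ImpactEstimate]:
    """Full impact table: one row per infectious etiology plus the autoimmune row.

    Infectious rows use the Bayes-adjusted PPV for each category's pretest
    prior and the positive scenario.  The autoimmune row (etiology ``none``,
    if present among the summaries) uses the NPV at a single overall
    ``infection_prior`` and the negative scenario; ``autoimmune_n_concordant``
    overrides its floor-derived concordant count when replicating a published
    table that applied an extra adjustment.
    """
    rows: list[ImpactEstimate] = []
    for prior in priors:
        if prior.etiology not in summaries:
            raise ConfigurationError(
                f"prior given for etiology {prior.etiology.value!r} "
                "but no matching summary"
            )
        summary = summaries[prior.etiology]
        ppv = adjusted_ppv(tc, prior)
        n_conc = expected_concordant(ppv, summary.n_patients)
        rows.append(
            category_savings(
                summary,
                n_conc,
                positive_scenario,
                predictive_value=ppv,
                replication_mode=replication_mode,
            )
        )
    if Etiology.NONE in summaries:
        summary = summaries[Etiology.NONE]
        npv = adjusted_npv(tc, infection_prior)
        n_conc = expected_concordant(npv, summary.n_patients)
        if autoimmune_n_concordant is not None:
            if autoimmune_n_concordant != n_conc:
                logger.info(
                    "autoimmune n_concordant overridden: floor gives %d, using %d",
                    n_conc,
                    autoimmune_n_concordant,
                )
            n_conc = autoimmune_n_concordant
        rows.append(
            category_savings(
                summary,
                n_conc,
                negative_scenario,
                predictive_value=npv,
                replication_mode=replication_mode,
            )
        )
    return rows


def impact_to_frame(estimates: Sequence[ImpactEstimate]) -> pd.DataFrame:
    """Tabular form with columns mirroring the published table headers."""
    return pd.DataFrame(
        [
            {
                "etiology": e.etiology.value,
                "predictive_value": e.predictive_value,
                "total_patients": e.n_patients,
                "expected_concordant": e.n_concordant,
                "lps_avoided": e.lps_avoided,
                "tests_avoided": e.tests_avoided,
                "days_saved": e.days_saved,
            }
            for e in estimates
        ]
    )


def render_markdown(estimates: Sequence[ImpactEstimate]) -> str:
    """Human-readable table: 3-decimal predictive values, '∼' on estimates."""
    header = (
        "| Etiology | Adjusted PV | Patients | Concordant | LPs avoided "
        "| Tests avoided | Days saved |"
    )
    sep = "|---|---|---|---|---|---|---|"
    lines = [header, sep]
    for e in estimates:
        lines.append(
            f"| {e.etiology.value} | {e.predictive_value:.3f} | {e.n_patients} "
            f"| ∼{e.n_concordant} | {e.lps_avoided} | {e.tests_avoided} "
            f"| {e.days_saved} |"
        )
    return "\n".join(lines)
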