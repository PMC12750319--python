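"""Uncertainty quantification: probabilistic and one-way sensitivity analysis.

The deterministic pipeline takes point values for sensitivity, specificity
and the per-category pretest prevalences.  The PSA replaces each with a Beta
distribution — Beta(alpha, beta) for assay characteristics, the
uniform-prior posterior Beta(k+1, n-k+1) for a prevalence observed as k of n
— and pushes every joint draw through the full Bayes + counterfactual
pipeline, reporting percentile intervals per quantity and etiology.
Percentile (not normal-approximation) intervals are used because the savings
columns are floored integers and heavily non-normal; flooring happens per
draw so each draw remains an interpretable table row.

Any parameter may instead be pinned to a point mass (a bare float), in which
case the PSA collapses to the deterministic pipeline for that parameter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np

from .bayes import TestCharacteristics, adjusted_npv, adjusted_ppv
from .cohort import CategorySummary, Etiology
from .config import ModelConfig
from .counterfactual import (
    NEGATIVE_SCENARIO,
    POSITIVE_SCENARIO,
    CounterfactualScenario,
    category_savings,
    expected_concordant,
    impact_table,
)

logger = logging.getLogger(__name__)

__all__ = [
    "UncertaintySpec",
    "IntervalEstimate",
    "TornadoEffect",
    "draw_parameters",
    "psa",
    "tornado",
]

#: A distribution spec: (alpha, beta) Beta shapes, or a bare float point mass.
BetaOrPoint = tuple[float, float] | float


def _validate_beta(name: str, value: BetaOrPoint) -> None:
    if isinstance(value, (int, float)):
        if not (0.0 <= value <= 1.0):
            raise ValueError(f"{name}: point mass {value} outside [0, 1]")
        return
    a, b = value
    if a <= 0 or b <= 0:
        raise ValueError(f"{name}: Beta shapes must be positive, got ({a}, {b})")


def _sample(rng: np.random.Generator, value: BetaOrPoint, size: int) -> np.ndarray:
    if isinstance(value, (int, float)):
        return np.full(size, float(value))
    a, b = value
    return rng.beta(a, b, size=size)


@dataclass(frozen=True)
class UncertaintySpec:
    """Parameter distributions driving the PSA.

    ``prevalence_counts`` maps each infectious etiology to its observed
    (k, n); draws use Beta(k+1, n-k+1), a proper posterior even for k = 0.
    ``infection_prior`` is the single overall pretest probability of
    infection used for the autoimmune arm's NPV.
    """

    se_beta: BetaOrPoint
    sp_beta: BetaOrPoint
    prevalence_counts: Mapping[Etiology, tuple[int, int]]
    infection_prior: BetaOrPoint = 0.10
    n_draws: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise ValueError(f"n_draws must be >= 1, got {self.n_draws}")
        _validate_beta("se_beta", self.se_beta)
        _validate_beta("sp_beta", self.sp_beta)
        _validate_beta("infection_prior", self.infection_prior)
        for e, (k, n) in self.prevalence_counts.items():
            if not (0 <= k <= n) or n <= 0:
                raise ValueError(f"prevalence_counts[{e.value}]: bad counts ({k}, {n})")


@dataclass(frozen=True)
class IntervalEstimate:
    """Percentile summary of one quantity for one etiology."""

    quantity: str  # ppv | npv | lps_avoided | tests_avoided | days_saved
    etiology: Etiology
    median: float
    lower95: float
    upper95: float

    def __post_init__(self) -> None:
        if not (self.lower95 <= self.median <= self.upper95):
            raise ValueError("interval must satisfy lower95 <= median <= upper95")


def draw_parameters(
    spec: UncertaintySpec,
) -> Iterator[tuple[TestCharacteristics, dict[Etiology, float], float]]:
    """Yield n_draws of (assay characteristics, prevalences, infection prior).

    Reproducible given ``spec.seed``; each etiology's prevalence is drawn
    from its Beta(k+1, n-k+1) posterior independently of the others and of
    Se/Sp.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_draws
    se = _sample(rng, spec.se_beta, n)
    sp = _sample(rng, spec.sp_beta, n)
    pi_inf = _sample(rng, spec.infection_prior, n)
    prev = {
        e: _sample(rng, (k + 1.0, n_cat - k + 1.0), n)
        for e, (k, n_cat) in spec.prevalence_counts.items()
    }
    for i in range(n):
        tc = TestCharacteristics(float(se[i]), float(sp[i]), ideal=True)
        yield tc, {e: float(v[i]) for e, v in prev.items()}, float(pi_inf[i])


def psa(
    spec: UncertaintySpec,
    summaries: Mapping[Etiology, CategorySummary],
    positive_scenario: CounterfactualScenario = POSITIVE_SCENARIO,
    negative_scenario: CounterfactualScenario = NEGATIVE_SCENARIO,
    *,
    replication_mode: bool = False,
) -> list[IntervalEstimate]:
    """Probabilistic sensitivity analysis over the full pipeline.

    Each draw runs the Bayes adjustment and the counterfactual savings end
    to end; 2.5/50/97.5 percentiles are reported per quantity per etiology.
    A draw that fails aborts with the seed and draw index in the message.
    """
    for e in spec.prevalence_counts:
        if e not in summaries:
            raise ValueError(f"spec covers etiology {e.value!r} with no summary")
    samples: dict[tuple[str, Etiology], list[float]] = {}

    def record(quantity: str, etiology: Etiology, value: float) -> None:
        samples.setdefault((quantity, etiology), []).append(value)

    for i, (tc, prevalences, pi_inf) in enumerate(draw_parameters(spec)):
        try:
            for etiology, pi in prevalences.items():
                summary = summaries[etiology]
                ppv = adjusted_ppv(tc, pi)
                est = category_savings(
                    summary,
                    expected_concordant(ppv, summary.n_patients),
                    positive_scenario,
                    predictive_value=ppv,
                    replication_mode=replication_mode,
                )
                record("ppv", etiology, ppv)
                record("lps_avoided", etiology, est.lps_avoided)
                record("tests_avoided", etiology, est.tests_avoided)
                record("days_saved", etiology, est.days_saved)
            if Etiology.NONE in summaries:
                summary = summaries[Etiology.NONE]
                npv = adjusted_npv(tc, pi_inf)
                est = category_savings(
                    summary,
                    expected_concordant(npv, summary.n_patients),
                    negative_scenario,
                    predictive_value=npv,
                    replication_mode=replication_mode,
                )
                record("npv", Etiology.NONE, npv)
                record("lps_avoided", Etiology.NONE, est.lps_avoided)
                record("tests_avoided", Etiology.NONE, est.tests_avoided)
                record("days_saved", Etiology.NONE, est.days_saved)
        except Exception as exc:
            raise RuntimeError(
                f"PSA draw {i} failed (seed {spec.seed}): {exc}"
            ) from exc

    estimates = []
    for (quantity, etiology), values in samples.items():
        lo, med, hi = np.percentile(values, [2.5, 50.0, 97.5])
        estimates.append(
            IntervalEstimate(
                quantity=quantity,
                etiology=etiology,
                median=float(med),
                lower95=float(lo),
                upper95=float(hi),
            )
        )
    return estimates


@dataclass(frozen=True)
class TornadoEffect:
    """One-way effect of a parameter swept from its low to its high value."""

    parameter: str
    low: float
    high: float
    outcome_low: float
    outcome_high: float

    @property
    def width(self) -> float:
        return abs(self.outcome_high - self.outcome_low)


#: Parameters the tornado sweep understands.
_TORNADO_SCALAR = {"sensitivity", "specificity", "infection_prior"}


def _outcome(
    config: ModelConfig,
    summaries: Mapping[Etiology, CategorySummary],
    quantity: str,
) -> float:
    rows = impact_table(
        summaries,
        config.test_characteristics,
        config.pretest_priors(),
        config.positive_scenario,
        config.negative_scenario,
        infection_prior=config.infection_prior,
        replication_mode=config.replication_mode,
        autoimmune_n_concordant=config.autoimmune_n_concordant,
    )
    return float(sum(getattr(r, quantity) for r in rows))


def tornado(
    base: ModelConfig,
    summaries: Mapping[Etiology, CategorySummary],
    parameter_ranges: Mapping[str, tuple[float, float]],
    quantity: str = "days_saved",
) -> list[TornadoEffect]:
    """One-way sensitivity analysis: sweep each parameter alone over its range.

    ``parameter_ranges`` keys are ``sensitivity``, ``specificity``,
    ``infection_prior`` or ``prevalence:<etiology>`` (which rescales that
    category's prior counts to the given prevalence).  The outcome is the
    chosen savings column summed over all table rows.  Results are sorted by
    descending effect width (ties broken alphabetically), so the ordering is
    independent of input ordering.
    """
    if quantity not in {"lps_avoided", "tests_avoided", "days_saved"}:
        raise ValueError(f"unknown outcome quantity {quantity!r}")
    effects = []
    for name, (low, high) in parameter_ranges.items():
        outs = []
        for value in (low, high):
            cfg = ModelConfig(**{**base.__dict__})
            cfg.priors = dict(base.priors)
            if name in _TORNADO_SCALAR:
                if not (0.0 < value < 1.0):
                    raise ValueError(
                        f"parameter {name!r}: value {value} outside (0, 1)"
                    )
                setattr(cfg, name, value)
            elif name.startswith("prevalence:"):
                etiology = Etiology(name.split(":", 1)[1])
                if etiology not in cfg.priors:
                    raise ValueError(f"no prior configured for {etiology.value!r}")
                _, n = cfg.priors[etiology]
                k_new = value * n
                if not (0.0 <= k_new <= n):
                    raise ValueError(
                        f"parameter {name!r}: prevalence {value} outside [0, 1]"
                    )
                cfg.priors[etiology] = (round(k_new), n)
            else:
                raise ValueError(f"unknown tornado parameter {name!r}")
            outs.append(_outcome(cfg, summaries, quantity))
        effects.append(
            TornadoEffect(
                parameter=name,
                low=low,
                high=high,
                outcome_low=outs[0],
                outcome_high=outs[1],
            )
        )
    return sorted(effects, key=lambda e: (-e.width, e.parameter))
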