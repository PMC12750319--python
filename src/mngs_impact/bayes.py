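"""Bayes-theorem adjustment of predictive values for the modeled mNGS assay.

Sensitivity and specificity are properties of the assay; predictive values
are not — they depend on the pretest probability of disease.  With pretest
prevalence ``pi``:

    PPV = Se * pi / (Se * pi + (1 - Sp) * (1 - pi))
    NPV = Sp * (1 - pi) / (Sp * (1 - pi) + (1 - Se) * pi)

equivalently post-test odds = likelihood ratio x pretest odds, with
LR+ = Se / (1 - Sp) and LR- = (1 - Se) / Sp.  The functions here carry
probabilities at full floating precision; rendering to the 3-decimal style
of published tables is the display layer's job.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

__all__ = [
    "TestCharacteristics",
    "PretestPrior",
    "PosteriorPredictiveValues",
    "prevalence_from_counts",
    "adjusted_ppv",
    "adjusted_npv",
    "likelihood_ratios",
    "implied_lr_positive",
    "posterior_values",
]

from .cohort import Etiology


@dataclass(frozen=True)
class TestCharacteristics:
    """Assay sensitivity and specificity.

    Both must lie strictly inside (0, 1) unless ``ideal`` is set, which
    permits exact 0/1 values and routes the division-guard paths (an
    ideal test has an infinite LR+).
    """

    sensitivity: float
    specificity: float
    ideal: bool = False

    def __post_init__(self) -> None:
        lo, hi = (0.0, 1.0)
        for name, v in (("sensitivity", self.sensitivity), ("specificity", self.specificity)):
            if not (lo <= v <= hi):
                raise ValueError(f"{name} must be a probability, got {v}")
            if not self.ideal and not (lo < v < hi):
                raise ValueError(
                    f"{name}={v} on the boundary requires ideal=True"
                )


@dataclass(frozen=True)
class PretestPrior:
    """Cohort-derived pretest probability for one etiology: k of n cases."""

    etiology: Etiology
    k: int
    n: int

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError(f"cohort size n must be positive, got {self.n}")
        if not (0 <= self.k <= self.n):
            raise ValueError(f"need 0 <= k <= n, got k={self.k}, n={self.n}")

    @property
    def prevalence(self) -> float:
        return self.k / self.n


@dataclass(frozen=True)
class PosteriorPredictiveValues:
    ppv: float
    npv: float
    lr_positive: float
    lr_negative: float


def prevalence_from_counts(etiology: Etiology, k: int, n: int) -> PretestPrior:
    """Pretest prior for an etiology observed in k of n cohort patients."""
    return PretestPrior(etiology=etiology, k=k, n=n)


def _ppv(se: float, sp: float, pi: float) -> float:
    if pi == 0.0:
        return 0.0
    if pi == 1.0:
        return 1.0
    num = se * pi
    den = num + (1.0 - sp) * (1.0 - pi)
    if den == 0.0:
        # Se = 0 with Sp = 1: a positive result is impossible.
        warnings.warn(
            "PPV denominator is zero (no positive results possible); returning 0",
            RuntimeWarning,
            stacklevel=3,
        )
        return 0.0
    return num / den


def _npv(se: float, sp: float, pi: float) -> float:
    if pi == 0.0:
        return 1.0
    if pi == 1.0:
        return 0.0
    num = sp * (1.0 - pi)
    den = num + (1.0 - se) * pi
    if den == 0.0:
        warnings.warn(
            "NPV denominator is zero (no negative results possible); returning 0",
            RuntimeWarning,
            stacklevel=3,
        )
        return 0.0
    return num / den


def adjusted_ppv(tc: TestCharacteristics, prior: PretestPrior | float) -> float:
    """Post-test probability of disease given a positive mNGS result."""
    pi = prior.prevalence if isinstance(prior, PretestPrior) else float(prior)
    if not (0.0 <= pi <= 1.0):
        raise ValueError(f"prevalence must be in [0, 1], got {pi}")
    return _ppv(tc.sensitivity, tc.specificity, pi)


def adjusted_npv(tc: TestCharacteristics, prior: PretestPrior | float) -> float:
    """Post-test probability of no disease given a negative mNGS result."""
    pi = prior.prevalence if isinstance(prior, PretestPrior) else float(prior)
    if not (0.0 <= pi <= 1.0):
        raise ValueError(f"prevalence must be in [0, 1], got {pi}")
    return _npv(tc.sensitivity, tc.specificity, pi)


def likelihood_ratios(tc: TestCharacteristics) -> tuple[float, float]:
    """(LR+, LR-) = (Se/(1-Sp), (1-Se)/Sp).

    A perfectly specific test has an undefined LR+; it is reported as
    ``math.inf`` with a warning rather than raising, since downstream odds
    arithmetic handles the sentinel naturally.
    """
    se, sp = tc.sensitivity, tc.specificity
    if sp == 1.0:
        warnings.warn(
            "specificity = 1: LR+ is infinite", RuntimeWarning, stacklevel=2
        )
        lr_pos = math.inf
    else:
        lr_pos = se / (1.0 - sp)
    if sp == 0.0:
        raise ValueError("specificity = 0: LR- undefined")
    lr_neg = (1.0 - se) / sp
    return lr_pos, lr_neg


def implied_lr_positive(ppv: float, prior: PretestPrior | float) -> float:
    """Back-solve the positive likelihood ratio from a printed PPV and prior.

    Inverts post-test odds = LR+ x pretest odds.  Useful for recovering the
    assay characteristics a published table implicitly used.
    """
    pi = prior.prevalence if isinstance(prior, PretestPrior) else float(prior)
    if not (0.0 < ppv < 1.0):
        raise ValueError(f"ppv must lie strictly in (0, 1), got {ppv}")
    if not (0.0 < pi < 1.0):
        raise ValueError(f"prevalence must lie strictly in (0, 1), got {pi}")
    return (ppv / (1.0 - ppv)) / (pi / (1.0 - pi))


def posterior_values(
    tc: TestCharacteristics, prior: PretestPrior | float
) -> PosteriorPredictiveValues:
    """Bundle PPV, NPV and both likelihood ratios for one prior."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        lr_pos, lr_neg = likelihood_ratios(tc)
    return PosteriorPredictiveValues(
        ppv=adjusted_ppv(tc, prior),
        npv=adjusted_npv(tc, prior),
        lr_positive=lr_pos,
        lr_negative=lr_neg,
    )
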