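"""Independent oracles used by the test suite.

The Monte-Carlo confusion-matrix simulator estimates predictive values by
simulating a population of subjects through disease status and test result,
then counting — deliberately independent of the closed-form Bayes arithmetic
it cross-checks.
"""

import math

import numpy as np


def mc_confusion_matrix(se, sp, prevalence, n_subjects, rng):
    """Simulate n_subjects and return (tp, fp, tn, fn) counts."""
    diseased = rng.binomial(n_subjects, prevalence)
    tp = rng.binomial(diseased, se)
    fn = diseased - tp
    tn = rng.binomial(n_subjects - diseased, sp)
    fp = (n_subjects - diseased) - tn
    return tp, fp, tn, fn


def mc_predictive_values(se, sp, prevalence, n_subjects, rng):
    """(ppv, ppv_se, npv, npv_se) from a simulated confusion matrix."""
    tp, fp, tn, fn = mc_confusion_matrix(se, sp, prevalence, n_subjects, rng)
    pos, neg = tp + fp, tn + fn
    ppv = tp / pos
    npv = tn / neg
    ppv_se = math.sqrt(max(ppv * (1 - ppv), 1e-12) / pos)
    npv_se = math.sqrt(max(npv * (1 - npv), 1e-12) / neg)
    return ppv, ppv_se, npv, npv_se


def random_triples(rng, n):
    """Random (se, sp, prevalence) triples kept away from degenerate corners."""
    return [
        (
            float(rng.uniform(0.55, 0.99)),
            float(rng.uniform(0.55, 0.99)),
            float(rng.uniform(0.05, 0.95)),
        )
        for _ in range(n)
    ]
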