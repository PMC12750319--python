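import pytest

from mngs_impact import CategorySummary, PretestPrior, TestCharacteristics
from mngs_impact.cohort import Etiology, INFECTIOUS_ETIOLOGIES

# Published per-category aggregates of the modeled study cohort:
# (n patients, mean LPs, mean tests, mean days to outcome).  The autoimmune
# arm's mean days to infection rule-out (13.0) is implied by its aggregate
# days-saved figure rather than printed directly.
PUBLISHED_AGGREGATES = {
    Etiology.DNA_VIRUS: (23, 1.1, 5.7, 8.6),
    Etiology.RNA_VIRUS: (5, 1.2, 1.8, 4.8),
    Etiology.BACTERIA: (16, 1.8, 3.2, 11.6),
    Etiology.FUNGUS: (7, 1.5, 5.8, 12.3),
    Etiology.PARASITE: (3, 1.0, 5.3, 6.6),
    Etiology.NONE: (29, 1.1, 4.7, 13.0),
}

INFECTIOUS_N = 54

# Published category-level adjusted PPVs (and the autoimmune NPV under NONE).
PUBLISHED_PREDICTIVE_VALUES = {
    Etiology.DNA_VIRUS: 0.984,
    Etiology.RNA_VIRUS: 0.895,
    Etiology.BACTERIA: 0.974,
    Etiology.FUNGUS: 0.928,
    Etiology.PARASITE: 0.846,
    Etiology.NONE: 0.984,
}


@pytest.fixture(scope="session")
def paper_summaries():
    return {
        e: CategorySummary.from_means(e, n, ml, mt, md)
        for e, (n, ml, mt, md) in PUBLISHED_AGGREGATES.items()
    }


@pytest.fixture(scope="session")
def paper_priors():
    return [
        PretestPrior(etiology=e, k=PUBLISHED_AGGREGATES[e][0], n=INFECTIOUS_N)
        for e in INFECTIOUS_ETIOLOGIES
    ]


@pytest.fixture(scope="session")
def default_tc():
    return TestCharacteristics(sensitivity=0.86, specificity=0.99)
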