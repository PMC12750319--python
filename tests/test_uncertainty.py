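"""PSA and tornado: determinism, degeneracy, containment, coverage."""

import numpy as np
import pytest

from mngs_impact import TestCharacteristics, adjusted_ppv, impact_table
from mngs_impact.cohort import Etiology
from mngs_impact.config import ModelConfig
from mngs_impact.uncertainty import (
    IntervalEstimate,
    UncertaintySpec,
    draw_parameters,
    psa,
    tornado,
)

from conftest import INFECTIOUS_N, PUBLISHED_AGGREGATES


def paper_spec(n_draws=2000, seed=0, **overrides):
    prevalence_counts = {
        e: (PUBLISHED_AGGREGATES[e][0], INFECTIOUS_N)
        for e in PUBLISHED_AGGREGATES
        if e is not Etiology.NONE
    }
    kwargs = dict(
        se_beta=(86.0, 14.0),
        sp_beta=(99.0, 1.0),
        prevalence_counts=prevalence_counts,
        infection_prior=0.10,
        n_draws=n_draws,
        seed=seed,
    )
    kwargs.update(overrides)
    return UncertaintySpec(**kwargs)


class TestDrawParameters:
    def test_identical_seed_gives_identical_streams(self):
        a = list(draw_parameters(paper_spec(n_draws=50, seed=42)))
        b = list(draw_parameters(paper_spec(n_draws=50, seed=42)))
        assert a == b

    def test_beta_sample_mean_matches_shape_mean(self):
        spec = paper_spec(n_draws=100_000, seed=1)
        ses = [tc.sensitivity for tc, _, _ in draw_parameters(spec)]
        assert abs(np.mean(ses) - 0.86) < 0.005

    def test_point_masses_collapse_to_constants(self):
        spec = paper_spec(
            n_draws=10,
            se_beta=0.86,
            sp_beta=0.99,
            prevalence_counts={},
            infection_prior=0.10,
        )
        for tc, _, pi in draw_parameters(spec):
            assert (tc.sensitivity, tc.specificity, pi) == (0.86, 0.99, 0.10)

    def test_bad_shapes_rejected(self):
        with pytest.raises(ValueError, match="se_beta"):
            paper_spec(se_beta=(0.0, 5.0))
        with pytest.raises(ValueError, match="n_draws"):
            paper_spec(n_draws=0)


class TestPSA:
    def test_point_mass_spec_reproduces_deterministic_pipeline(
        self, paper_summaries, paper_priors, default_tc
    ):
        # point-mass Se/Sp; prevalences pinned through huge pseudo-counts,
        # Beta(k*s+1, (n-k)*s+1) -> k/n as s grows
        deterministic = impact_table(
            paper_summaries, default_tc, paper_priors, replication_mode=True
        )
        scale = 10**7
        spec = UncertaintySpec(
            se_beta=0.86,
            sp_beta=0.99,
            prevalence_counts={
                p.etiology: (p.k * scale, p.n * scale) for p in paper_priors
            },
            infection_prior=0.10,
            n_draws=64,
            seed=3,
        )
        intervals = psa(spec, paper_summaries, replication_mode=True)
        det = {(("ppv", r.etiology)): r.predictive_value for r in deterministic}
        for quantity in ("lps_avoided", "tests_avoided", "days_saved"):
            det.update(
                {(quantity, r.etiology): getattr(r, quantity) for r in deterministic}
            )
        for iv in intervals:
            if iv.quantity in ("ppv", "npv") and iv.etiology is not Etiology.NONE:
                assert iv.upper95 - iv.lower95 < 1e-4
                assert iv.median == pytest.approx(det[("ppv", iv.etiology)], abs=1e-4)
            elif iv.quantity not in ("ppv", "npv"):
                assert iv.lower95 == iv.median == iv.upper95
                assert iv.median == det[(iv.quantity, iv.etiology)]

    def test_seeded_determinism_bit_identical(self, paper_summaries):
        a = psa(paper_spec(n_draws=300, seed=5), paper_summaries)
        b = psa(paper_spec(n_draws=300, seed=5), paper_summaries)
        assert a == b

    def test_wider_sensitivity_prior_weakly_widens_ppv_intervals(
        self, paper_summaries
    ):
        narrow = psa(paper_spec(n_draws=3000, seed=8), paper_summaries)
        wide = psa(
            paper_spec(n_draws=3000, seed=8, se_beta=(8.6, 1.4)), paper_summaries
        )

        def width(intervals, etiology):
            iv = next(
                i for i in intervals if i.quantity == "ppv" and i.etiology is etiology
            )
            return iv.upper95 - iv.lower95

        for e in (Etiology.DNA_VIRUS, Etiology.BACTERIA):
            assert width(wide, e) >= width(narrow, e)

    def test_bacteria_days_interval_contains_deterministic_value(
        self, paper_summaries
    ):
        intervals = psa(
            paper_spec(n_draws=4000, seed=2), paper_summaries, replication_mode=True
        )
        iv = next(
            i
            for i in intervals
            if i.quantity == "days_saved" and i.etiology is Etiology.BACTERIA
        )
        assert iv.lower95 <= 144 <= iv.upper95

    def test_medians_converge_to_deterministic_within_floor_granularity(
        self, paper_summaries, paper_priors, default_tc
    ):
        deterministic = {
            r.etiology: r
            for r in impact_table(
                paper_summaries, default_tc, paper_priors, replication_mode=True
            )
        }
        intervals = psa(
            paper_spec(n_draws=30_000, seed=4), paper_summaries, replication_mode=True
        )
        for iv in intervals:
            if iv.quantity in ("ppv", "npv") or iv.etiology is Etiology.NONE:
                continue
            det = getattr(deterministic[iv.etiology], iv.quantity)
            granularity = max(
                 1.0,
                 # one concordant patient's worth of the underlying resource
                 abs(det) / max(deterministic[iv.etiology].n_concordant, 1),
            )
            assert abs(iv.median - det) <= granularity

    def test_missing_summary_rejected(self, paper_summaries):
        incomplete = {Etiology.BACTERIA: paper_summaries[Etiology.BACTERIA]}
        with pytest.raises(ValueError, match="no summary"):
            psa(paper_spec(n_draws=10), incomplete)

    def test_interval_ordering_enforced(self):
        with pytest.raises(ValueError):
            IntervalEstimate("ppv", Etiology.BACTERIA, 0.5, 0.6, 0.7)


class TestCoverage:
    def test_ppv_interval_covers_truth_in_most_replicates(self, paper_summaries):
        """95% intervals from Beta posteriors should cover the true PPV
        in at least ~90% of replicated studies simulated from known truth."""
        se_true, sp_true, pi_true = 0.86, 0.95, 0.30
        truth = adjusted_ppv(TestCharacteristics(se_true, sp_true), pi_true)
        rng = np.random.default_rng(123)
        summaries = {Etiology.BACTERIA: paper_summaries[Etiology.BACTERIA]}
        n_rep, covered = 200, 0
        for rep in range(n_rep):
            k = int(rng.binomial(54, pi_true))
            s_se = int(rng.binomial(100, se_true))
            s_sp = int(rng.binomial(200, sp_true))
            spec = UncertaintySpec(
                se_beta=(s_se + 1.0, 100 - s_se + 1.0),
                sp_beta=(s_sp + 1.0, 200 - s_sp + 1.0),
                prevalence_counts={Etiology.BACTERIA: (k, 54)},
                n_draws=400,
                seed=int(rng.integers(2**31)),
            )
            intervals = psa(spec, summaries)
            iv = next(i for i in intervals if i.quantity == "ppv")
            if iv.lower95 <= truth <= iv.upper95:
                covered += 1
        assert covered / n_rep >= 0.90


class TestTornado:
    def base_config(self, paper_priors):
        return ModelConfig(
            replication_mode=True,
            autoimmune_n_concordant=27,
            priors={p.etiology: (p.k, p.n) for p in paper_priors},
        )

    def test_zero_width_ranges_give_zero_effects(self, paper_summaries, paper_priors):
        cfg = self.base_config(paper_priors)
        effects = tornado(
            cfg,
            paper_summaries,
            {"sensitivity": (0.86, 0.86), "specificity": (0.99, 0.99)},
        )
        assert all(e.width == 0 for e in effects)

    def test_specificity_range_moves_savings(self, paper_summaries, paper_priors):
        cfg = self.base_config(paper_priors)
        effects = tornado(
            cfg, paper_summaries, {"specificity": (0.90, 0.999)}, quantity="days_saved"
        )
        assert effects[0].width > 0

    def test_ordering_independent_of_input_order(self, paper_summaries, paper_priors):
        cfg = self.base_config(paper_priors)
        ranges_a = {"sensitivity": (0.70, 0.95), "specificity": (0.95, 0.999)}
        ranges_b = dict(reversed(list(ranges_a.items())))
        ea = tornado(cfg, paper_summaries, ranges_a)
        eb = tornado(cfg, paper_summaries, ranges_b)
        assert [e.parameter for e in ea] == [e.parameter for e in eb]
        assert [e.width for e in ea] == [e.width for e in eb]

    def test_out_of_domain_range_names_parameter(self, paper_summaries, paper_priors):
        cfg = self.base_config(paper_priors)
        with pytest.raises(ValueError, match="sensitivity"):
            tornado(cfg, paper_summaries, {"sensitivity": (0.5, 1.5)})

    def test_prevalence_sweep(self, paper_summaries, paper_priors):
        cfg = self.base_config(paper_priors)
        effects = tornado(
            cfg, paper_summaries, {"prevalence:bacteria": (0.1, 0.5)}
        )
        assert effects[0].parameter == "prevalence:bacteria"
        assert effects[0].width >= 0
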