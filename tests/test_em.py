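import math

import numpy as np
import pytest

from hsrecomb.em import (
    FamilyData,
    em_fit,
    em_fit_batch,
    estimate_allele_freq,
    pool_counts_by_phase,
)
from hsrecomb.likelihood import (
    LDParams,
    LocusPairCounts,
    SirePhase,
    genotype_probs,
    ld_to_haplo,
)
from hsrecomb.simulate import run_study_one
from helpers import random_count_table


def family_from_table(tab, phase=SirePhase.COUPLING):
    return [FamilyData(LocusPairCounts(tab), phase)]


class TestEstimateAlleleFreq:
    @pytest.mark.parametrize(
        "nAA, nAB, nBB, expected",
        [(30, 40, 30, 0.5), (10, 0, 30, 0.25), (7, 100, 0, 1.0)],
    )
    def test_values(self, nAA, nAB, nBB, expected):
        assert estimate_allele_freq(nAA, nAB, nBB) == pytest.approx(expected)

    def test_no_homozygotes_is_missing(self):
        assert math.isnan(estimate_allele_freq(0, 50, 0))


class TestEmFit:
    def test_fixed_point_at_truth(self):
        """Expected counts + start at truth: EM is stationary immediately."""
        true = LDParams(0.15, 0.05, 0.45, 0.55)
        pi = genotype_probs(true, SirePhase.COUPLING)
        fams = family_from_table(500 * pi)
        res = em_fit(fams, true.theta, ld_to_haplo(0.05, 0.45, 0.55))
        assert res.converged
        assert res.n_iter <= 3
        assert res.theta_hat == pytest.approx(true.theta, abs=1e-6)
        assert res.D_dam_hat == pytest.approx(0.05, abs=1e-6)

    def test_recovers_truth_from_default_start(self):
        true = LDParams.from_theta(0.2, 0.05, 0.4, 0.4)
        pi = genotype_probs(true, SirePhase.COUPLING)
        res = em_fit(
            family_from_table(100_000 * pi), 0.0, ld_to_haplo(0.0, 0.4, 0.4)
        )
        assert res.theta_hat == pytest.approx(0.2, abs=1e-3)
        assert res.D_dam_hat == pytest.approx(0.05, abs=1e-3)

    def test_repulsion_phase_orientation(self):
        """A repulsion-phase family with the same parameters must recover the
        same theta; its table is the coupling table with D_sire negated."""
        true_c = LDParams.from_theta(0.2, 0.05, 0.4, 0.4)
        flipped = LDParams(-true_c.D_sire, 0.05, 0.4, 0.4)
        pi_rep = genotype_probs(flipped, SirePhase.COUPLING)
        res = em_fit(
            family_from_table(50_000 * pi_rep, SirePhase.REPULSION),
            0.0,
            ld_to_haplo(0.0, 0.4, 0.4),
        )
        assert res.theta_hat == pytest.approx(0.2, abs=1e-3)

    def test_multi_family_shared_parameters(self):
        """Coupling and repulsion families share (theta, dam haplotypes)."""
        true = LDParams.from_theta(0.25, 0.08, 0.45, 0.6)
        pi_c = genotype_probs(true, SirePhase.COUPLING)
        pi_r = genotype_probs(true, SirePhase.REPULSION)
        fams = [
            FamilyData(LocusPairCounts(30_000 * pi_c), SirePhase.COUPLING, "F1"),
            FamilyData(LocusPairCounts(30_000 * pi_r), SirePhase.REPULSION, "F2"),
        ]
        res = em_fit(fams, 0.0, ld_to_haplo(0.0, 0.45, 0.6))
        assert res.n_families == 2
        assert res.theta_hat == pytest.approx(0.25, abs=1e-3)
        assert res.D_dam_hat == pytest.approx(0.08, abs=1e-3)

    def test_estimates_stay_in_space(self, rng):
        for _ in range(50):
            tab, _ = random_count_table(rng)
            res = em_fit(family_from_table(tab), rng.uniform(0, 1), ld_to_haplo(0, 0.5, 0.5))
            assert 0.0 <= res.theta_hat <= 1.0
            h = res.haplo.as_array()
            assert np.all(h >= 0) and h.sum() == pytest.approx(1.0, abs=1e-9)

    def test_theta_max_restriction(self, rng):
        """The interference-free option keeps theta in [0, 0.5]."""
        flipped = LDParams(-0.2, 0.05, 0.5, 0.5)  # theta = 0.9 in coupling terms
        pi = genotype_probs(flipped, SirePhase.COUPLING)
        res = em_fit(
            family_from_table(1000 * pi), 0.4, ld_to_haplo(0, 0.5, 0.5), theta_max=0.5
        )
        assert res.theta_hat <= 0.5

    def test_monotonic_loglik_paths(self, rng):
        for _ in range(150):
            tab, _ = random_count_table(rng)
            res = em_fit(
                family_from_table(tab),
                rng.uniform(0, 1),
                ld_to_haplo(0, rng.uniform(0.2, 0.8), rng.uniform(0.2, 0.8)),
                record_path=True,
            )
            path = res.loglik_path
            assert np.all(np.diff(path) >= -1e-8)

    def test_errors(self):
        with pytest.raises(ValueError, match="at least one family"):
            em_fit([], 0.0, ld_to_haplo(0, 0.5, 0.5))
        with pytest.raises(ValueError, match="observation"):
            em_fit(family_from_table(np.zeros((3, 3))), 0.0, ld_to_haplo(0, 0.5, 0.5))


class TestBatchEngine:
    def test_batch_matches_single_fits(self, rng):
        tables = [random_count_table(rng)[0] for _ in range(25)]
        counts2 = np.zeros((25, 2, 3, 3))
        counts2[:, 0] = np.stack(tables)
        theta0 = np.full(25, 0.3)
        h0 = np.tile(ld_to_haplo(0.02, 0.5, 0.5).as_array(), (25, 1))
        batch = em_fit_batch(counts2, theta0, h0)
        for r, tab in enumerate(tables):
            single = em_fit(family_from_table(tab), 0.3, ld_to_haplo(0.02, 0.5, 0.5))
            assert batch["theta"][r] == pytest.approx(single.theta_hat, abs=1e-9)
            assert batch["loglik"][r] == pytest.approx(single.loglik, abs=1e-9)
            assert batch["loglik_star"][r] == pytest.approx(single.loglik_star, abs=1e-9)

    def test_boundary_start_without_nudge_fails_cleanly(self):
        """theta0 = 0 exactly makes a recombinant-only cell impossible."""
        n = np.zeros((2, 3, 3))
        n[0, 0, 2] = 5  # AA,BB requires a recombinant paternal gamete
        n[0, 0, 0] = 5
        out = em_fit_batch(
            n[None].reshape(1, 2, 3, 3),
            np.array([0.0]),
            np.full((1, 4), 0.25),
        )
        assert out["failed"][0]
        assert out["loglik"][0] == -math.inf


class TestParameterRecovery:
    @pytest.mark.parametrize("scenario, freq", [("II", "b"), ("III", "c")])
    def test_bias_shrinks_with_sample_size(self, scenario, freq):
        """|bias| at N=1000 below |bias| at N=100 for every start strategy.

        Checked away from p1 = p2 = 0.5: with both frequencies at 0.5 the
        two likelihood modes keep equal height at any N, mode selection
        stays a coin flip, and the strategies that can land on the wrong
        mode do not gain from more offspring.
        """
        small = run_study_one((scenario,), (freq,), n_offspring=100, n_replicates=400, seed=5)
        large = run_study_one((scenario,), (freq,), n_offspring=1000, n_replicates=400, seed=5)
        for strat in ("EMT0", "EMT05", "EMDP"):
            b_small = abs(small.loc[small.strategy == strat, "bias_theta"].iloc[0])
            b_large = abs(large.loc[large.strategy == strat, "bias_theta"].iloc[0])
            d_small = abs(small.loc[small.strategy == strat, "bias_ddam"].iloc[0])
            d_large = abs(large.loc[large.strategy == strat, "bias_ddam"].iloc[0])
            assert b_large < b_small
            assert d_large < d_small


def test_pool_counts_by_phase():
    a = FamilyData(LocusPairCounts(np.full((3, 3), 1.0)), SirePhase.COUPLING)
    b = FamilyData(LocusPairCounts(np.full((3, 3), 2.0)), SirePhase.COUPLING)
    c = FamilyData(LocusPairCounts(np.full((3, 3), 5.0)), SirePhase.REPULSION)
    pooled = pool_counts_by_phase([a, b, c])
    assert pooled[0].sum() == 27 and pooled[1].sum() == 45
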