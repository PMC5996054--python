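import numpy as np
import pytest
from scipy import stats as sps

from hsrecomb.likelihood import (
    DomainError,
    LDParams,
    SirePhase,
    genotype_probs,
)
from hsrecomb.simulate import (
    Move,
    SimConfig,
    merge_datasets,
    rearrange,
    run_study_two,
    simulate_chromosome,
    simulate_pair,
    simulate_pair_batch,
)


class TestSimulatePair:
    def test_seeded_determinism(self):
        cfg = SimConfig(n_offspring=200, theta=0.2, d_dam=0.05, seed=7)
        a = simulate_pair(cfg)
        b = simulate_pair(cfg)
        np.testing.assert_array_equal(a.n, b.n)
        batch1 = simulate_pair_batch(5, cfg, np.random.SeedSequence(3))
        batch2 = simulate_pair_batch(5, cfg, np.random.SeedSequence(3))
        np.testing.assert_array_equal(batch1, batch2)

    def test_no_recombination_perfect_ld_is_concordant(self):
        """theta = 0 with D_dam at its maximum: only AA/AA, AB/AB, BB/BB."""
        cfg = SimConfig(n_offspring=500, theta=0.0, d_dam=0.25, p1=0.5, p2=0.5, seed=1)
        counts = simulate_pair(cfg)
        off_diag = counts.n.sum() - np.trace(counts.n)
        assert off_diag == 0
        assert counts.N == 500

    def test_invalid_ld_rejected_before_sampling(self):
        with pytest.raises(DomainError):
            simulate_pair(SimConfig(theta=0.1, d_dam=0.3, p1=0.5, p2=0.5))

    def test_cell_frequencies_match_model_probabilities(self):
        """Law of large numbers against the likelihood core (scenario II(a)
        at N = 100,000), plus a chi-square goodness-of-fit check."""
        cfg = SimConfig(n_offspring=100_000, theta=0.20, d_dam=0.05, seed=2)
        counts = simulate_pair(cfg).n
        params = LDParams.from_theta(0.20, 0.05, 0.5, 0.5)
        pi = genotype_probs(params, SirePhase.COUPLING)
        N = counts.sum()
        se = np.sqrt(pi * (1 - pi) / N)
        assert np.all(np.abs(counts / N - pi) <= 3 * se + 1e-12)
        chi2 = sps.chisquare(counts.reshape(-1), (N * pi).reshape(-1))
        assert chi2.pvalue > 0.001

    def test_batch_sampling_matches_model_probabilities(self):
        cfg = SimConfig(n_offspring=5000, theta=0.1, d_dam=0.1, p1=0.6, p2=0.4)
        batch = simulate_pair_batch(20, cfg, np.random.SeedSequence(9))
        pooled = batch.sum(axis=0)
        params = LDParams.from_theta(0.1, 0.1, 0.6, 0.4)
        pi = genotype_probs(params, SirePhase.COUPLING)
        N = pooled.sum()
        se = np.sqrt(pi * (1 - pi) / N)
        assert np.all(np.abs(pooled / N - pi) <= 4 * se + 1e-12)


class TestSimulateChromosome:
    def test_no_recombination_transmits_intact_haplotypes(self):
        # dam fixed for allele A: paternal allele = genotype - 1
        ds = simulate_chromosome(8, 50, 0.0, allele_freqs=1.0, adjacent_d=0.0, seed=4)
        pat = ds.genotypes.to_numpy() - 1
        assert set(np.unique(pat)) <= {0.0, 1.0}
        assert np.all(pat.min(axis=1) == pat.max(axis=1))  # intact haplotype

    def test_pairwise_rate_composes_over_the_map(self):
        """Markov recombination: theta(i, j) = 0.5 (1 - prod(1 - 2 theta_k)).

        Oracle: exhaustive enumeration over crossover patterns for 3 loci —
        a gamete is recombinant between loci 1 and 3 iff exactly one of the
        two interval crossovers happened:
        theta_13 = t1 (1 - t2) + t2 (1 - t1), which equals the composed form.
        """
        t1, t2 = 0.1, 0.2
        enumerated = t1 * (1 - t2) + t2 * (1 - t1)
        composed = 0.5 * (1 - (1 - 2 * t1) * (1 - 2 * t2))
        assert enumerated == pytest.approx(composed)

        ds = simulate_chromosome(
            3, 40_000, np.array([t1, t2]), allele_freqs=1.0, adjacent_d=0.0, seed=6
        )
        pat = ds.genotypes.to_numpy() - 1
        emp_13 = np.mean(pat[:, 0] != pat[:, 2])
        se = np.sqrt(composed * (1 - composed) / 40_000)
        assert abs(emp_13 - composed) <= 4 * se
        emp_12 = np.mean(pat[:, 0] != pat[:, 1])
        assert abs(emp_12 - t1) <= 4 * np.sqrt(t1 * (1 - t1) / 40_000)

    def test_dataset_structure(self):
        ds = simulate_chromosome(5, 30, 0.02, chrom="7", seed=1)
        assert ds.chromosomes == ["7"]
        assert ds.genotypes.shape == (30, 5)
        assert list(ds.snp_map["snp"]) == list(ds.genotypes.columns)
        hap = ds.sire_haplotypes["S1"]
        assert set(hap["hap1"]) == {"A"} and set(hap["hap2"]) == {"B"}

    def test_interval_theta_validation(self):
        with pytest.raises(DomainError):
            simulate_chromosome(4, 10, 0.7, seed=1)


class TestRearrange:
    def test_moves_permute_snp_to_slot_assignment(self):
        ds = simulate_chromosome(10, 20, 0.01, seed=2)
        moved = rearrange(ds, [Move("1", 9, "1", 2, 1)])
        snps = list(moved.snp_map["snp"])
        assert snps[1] == "c1s0009"
        # genotypes stay attached to their SNP
        np.testing.assert_array_equal(
            moved.genotypes["c1s0009"].to_numpy(),
            ds.genotypes["c1s0009"].to_numpy(),
        )
        # slot positions are unchanged
        np.testing.assert_array_equal(
            moved.snp_map["pos"].to_numpy(), ds.snp_map["pos"].to_numpy()
        )

    def test_cross_chromosome_move(self):
        a = simulate_chromosome(6, 20, 0.01, chrom="1", seed=3)
        b = simulate_chromosome(6, 20, 0.01, chrom="2", seed=4)
        ds = merge_datasets([a, b])
        moved = rearrange(ds, [Move("1", 3, "2", 1, 2)])
        m1 = moved.snp_map[moved.snp_map["chrom"] == "1"]
        m2 = moved.snp_map[moved.snp_map["chrom"] == "2"]
        assert len(m1) == 4 and len(m2) == 8
        assert list(m2["snp"])[:2] == ["c1s0003", "c1s0004"]

    def test_out_of_range_moves_rejected(self):
        ds = simulate_chromosome(5, 10, 0.01, seed=5)
        with pytest.raises(ValueError, match="outside"):
            rearrange(ds, [Move("1", 5, "1", 1, 3)])
        with pytest.raises(ValueError, match="outside"):
            rearrange(ds, [Move("1", 1, "1", 9, 1)])
        with pytest.raises(ValueError, match="unknown"):
            rearrange(ds, [Move("3", 1, "1", 1, 1)])


class TestStudyTwo:
    def test_boundary_truth_and_sample_size_effect(self):
        """At theta = 0 the default-start EM stays near the boundary, and
        N = 1000 curves hug the diagonal tighter than N = 100."""
        grid = np.array([0.0, 0.25])
        small = run_study_two(
            theta_grid=grid, n_replicates=150, n_offspring=100, seed=8
        )
        large = run_study_two(
            theta_grid=grid, n_replicates=150, n_offspring=1000, seed=8
        )
        t0 = small[(small.theta == 0.0) & (small.strategy == "EMT0")]
        assert t0["mean_theta_hat"].iloc[0] < 0.02
        for strat in ("EMT0", "EMT05", "EMDP"):
            es = abs(
                small[(small.theta == 0.25) & (small.strategy == strat)][
                    "mean_theta_hat"
                ].iloc[0]
                - 0.25
            )
            el = abs(
                large[(large.theta == 0.25) & (large.strategy == strat)][
                    "mean_theta_hat"
                ].iloc[0]
                - 0.25
            )
            assert el < es
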