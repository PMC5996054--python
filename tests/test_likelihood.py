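import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hsrecomb.likelihood import (
    DomainError,
    LDParams,
    LocusPairCounts,
    MaternalHaplotypeFreqs,
    SirePhase,
    ddam_bounds,
    genotype_probs,
    haplo_to_ld,
    ld_to_haplo,
    loglik,
    loglik_star,
    merge_set,
    r_squared,
)
from helpers import loglik_star_reference, random_count_table


def random_params(rng):
    p1, p2 = rng.uniform(0.05, 0.95, size=2)
    lo, hi = ddam_bounds(p1, p2)
    return LDParams(
        D_sire=rng.uniform(-0.25, 0.25),
        D_dam=rng.uniform(lo, hi),
        p1=p1,
        p2=p2,
    )


class TestGenotypeProbs:
    @pytest.mark.parametrize(
        "params, phase, cell, expected",
        [
            # pi_AA,AA = (1/4 + D_sire)(D_dam + p1 p2)
            (LDParams(0.25, 0.0, 0.5, 0.5), SirePhase.COUPLING, (0, 0), 0.125),
            # the D_sire-multiplied term of pi_AB,AB vanishes at D_sire = 0
            (LDParams(0.0, 0.15, 0.5, 0.5), SirePhase.COUPLING, (1, 1), 0.25),
            # pi_BB,BB = (1/4 + D_sire)(D_dam + (1-p1)(1-p2))
            (LDParams(0.1, 0.05, 0.4, 0.6), SirePhase.COUPLING, (2, 2), 0.35 * 0.29),
        ],
    )
    def test_printed_cells(self, params, phase, cell, expected):
        pi = genotype_probs(params, phase)
        assert pi[cell] == pytest.approx(expected, abs=1e-12)

    def test_normalization_and_nonnegativity(self, rng):
        for _ in range(300):
            params = random_params(rng)
            phase = SirePhase.COUPLING if rng.random() < 0.5 else SirePhase.REPULSION
            pi = genotype_probs(params, phase)
            assert np.all(pi >= 0)
            assert pi.sum() == pytest.approx(1.0, abs=1e-12)

    def test_repulsion_equals_negated_d_sire(self, rng):
        """Switching the phase is the theta <-> 1 - theta symmetry."""
        for _ in range(100):
            params = random_params(rng)
            flipped = LDParams(-params.D_sire, params.D_dam, params.p1, params.p2)
            np.testing.assert_allclose(
                genotype_probs(params, SirePhase.REPULSION),
                genotype_probs(flipped, SirePhase.COUPLING),
                atol=1e-14,
            )

    def test_out_of_space_raises_naming_bound(self):
        with pytest.raises(DomainError, match="D_sire"):
            genotype_probs(LDParams(0.3, 0.0, 0.5, 0.5), SirePhase.COUPLING)
        with pytest.raises(DomainError, match="D_dam"):
            genotype_probs(LDParams(0.1, 0.24, 0.8, 0.8), SirePhase.COUPLING)


class TestDdamBounds:
    @pytest.mark.parametrize(
        "p1, p2, expected",
        [
            (0.5, 0.5, (-0.25, 0.25)),
            (0.4, 0.6, (-0.24, 0.16)),
            (0.8, 0.8, (-0.04, 0.16)),
        ],
    )
    def test_values(self, p1, p2, expected):
        lo, hi = ddam_bounds(p1, p2)
        assert (lo, hi) == pytest.approx(expected)
        assert lo <= 0 <= hi

    def test_out_of_range_frequency(self):
        with pytest.raises(DomainError):
            ddam_bounds(-0.1, 0.5)


class TestHaploLdConversions:
    def test_uniform_simplex(self):
        f = MaternalHaplotypeFreqs(0.25, 0.25, 0.25, 0.25)
        assert haplo_to_ld(f) == pytest.approx((0.0, 0.5, 0.5))

    def test_known_reconstruction(self):
        f = ld_to_haplo(0.15, 0.5, 0.5)
        assert f.as_array() == pytest.approx([0.40, 0.10, 0.10, 0.40])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.tuples(*(st.floats(0.01, 1.0) for _ in range(4))))
    def test_round_trip_identity(self, raw):
        h = np.array(raw) / sum(raw)
        f = MaternalHaplotypeFreqs.from_array(h)
        d_dam, p1, p2 = haplo_to_ld(f)
        back = ld_to_haplo(d_dam, p1, p2)
        np.testing.assert_allclose(back.as_array(), h, atol=1e-12)

    def test_reconstruction_outside_space_names_haplotype(self):
        with pytest.raises(DomainError, match="p_AB"):
            ld_to_haplo(0.3, 0.5, 0.5)


class TestRSquared:
    def test_values(self):
        assert r_squared(0.15, 0.5, 0.5) == pytest.approx(0.36)
        assert r_squared(0.0, 0.3, 0.7) == 0.0
        assert r_squared(0.25, 0.5, 0.5) == pytest.approx(1.0)

    def test_monomorphic_is_missing(self):
        assert math.isnan(r_squared(0.0, 0.0, 0.5))
        assert math.isnan(r_squared(0.0, 0.5, 1.0))


class TestLoglik:
    def test_hand_computed_sum(self):
        params = LDParams(0.1, 0.05, 0.4, 0.6)
        pi = genotype_probs(params, SirePhase.COUPLING)
        counts = LocusPairCounts(np.arange(9).reshape(3, 3))
        expected = sum(
            counts.n[i, k] * math.log(pi[i, k])
            for i in range(3)
            for k in range(3)
            if counts.n[i, k] > 0
        )
        assert loglik(counts, params, SirePhase.COUPLING) == pytest.approx(expected)

    def test_empty_table_is_zero(self):
        counts = LocusPairCounts(np.zeros((3, 3)))
        assert loglik(counts, LDParams(0.1, 0.0, 0.5, 0.5), SirePhase.COUPLING) == 0.0

    def test_impossible_cell_gives_minus_inf(self):
        # at theta = 0 (D_sire = 0.25) the double-recombinant cell AA,BB is impossible
        n = np.zeros((3, 3))
        n[0, 2] = 1
        val = loglik(LocusPairCounts(n), LDParams(0.25, 0.0, 0.5, 0.5), SirePhase.COUPLING)
        assert val == -math.inf

    def test_truth_is_maximum_on_expected_counts(self, rng):
        """With expected counts the generating parameters maximize log LF."""
        true = LDParams(0.15, 0.05, 0.5, 0.5)
        pi = genotype_probs(true, SirePhase.COUPLING)
        counts = LocusPairCounts(1000 * pi)
        ll_true = loglik(counts, true, SirePhase.COUPLING)
        for _ in range(200):
            eps = rng.uniform(-0.02, 0.02, size=2)
            pert = LDParams(true.D_sire + eps[0], true.D_dam + eps[1], 0.5, 0.5)
            if not pert.in_space():
                continue
            assert loglik(counts, pert, SirePhase.COUPLING) <= ll_true + 1e-12


class TestLoglikStar:
    def test_merge_of_empty_and_minimum_cells(self):
        params = LDParams(0.1, 0.02, 0.45, 0.55)
        pi = genotype_probs(params, SirePhase.COUPLING).reshape(-1)
        n = np.zeros(9)
        n[0], n[4], n[8] = 5, 3, 2
        # J = six empty cells + the cell with count 2; merged count is 2
        J = [c for c in range(9) if n[c] == 0 or n[c] == 2]
        expected = 5 * math.log(pi[0]) + 3 * math.log(pi[4]) + 2 * math.log(pi[J].sum())
        got = loglik_star(LocusPairCounts(n.reshape(3, 3)), params, SirePhase.COUPLING)
        assert got == pytest.approx(expected)

    def test_equals_loglik_when_all_positive_unique_minimum(self):
        params = LDParams(0.05, 0.03, 0.5, 0.5)
        counts = LocusPairCounts(np.arange(1, 10).reshape(3, 3))
        assert loglik_star(counts, params, SirePhase.COUPLING) == pytest.approx(
            loglik(counts, params, SirePhase.COUPLING)
        )

    def test_against_brute_force_enumeration(self, rng):
        """Ties at the positive minimum all join the merge set."""
        for _ in range(200):
            tab, _ = random_count_table(rng, n_max=30)
            params = random_params(rng)
            pi = genotype_probs(params, SirePhase.COUPLING)
            got = loglik_star(LocusPairCounts(tab), params, SirePhase.COUPLING)
            ref = loglik_star_reference(tab, pi)
            assert got == pytest.approx(ref, abs=1e-10)

    def test_merge_set_tie_handling(self):
        n = np.array([4, 0, 2, 0, 2, 0, 0, 0, 7], dtype=float)
        J = merge_set(n)
        assert list(np.flatnonzero(J)) == [1, 2, 3, 4, 5, 6, 7]


def test_counts_invariants():
    counts = LocusPairCounts([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
    assert counts.N == 45
    np.testing.assert_array_equal(counts.locus1_marginals(), [6, 15, 24])
    np.testing.assert_array_equal(counts.locus2_marginals(), [12, 15, 18])
    with pytest.raises(ValueError):
        LocusPairCounts([[1, 2], [3, 4]])
    with pytest.raises(ValueError):
        LocusPairCounts(-np.ones((3, 3)))
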