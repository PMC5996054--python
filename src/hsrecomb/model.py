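"""Model/results front end for single locus-pair estimation.

:class:`HalfSibPairModel` is built from the data (family count tables or
raw offspring genotypes); ``fit`` runs the EM from one start and returns an
:class:`~hsrecomb.em.EMResult` carrying estimates, likelihood values and a
``summary()`` table, while ``fit_dual`` runs the dual-start procedure and
returns the :class:`~hsrecomb.duality.ProposalPair` that the decision rules
operate on.
"""

from __future__ import annotations

import numpy as np

from .decision import PairEstimate, decide_by_loglik
from .duality import ProposalPair, emdp_propose
from .em import EMResult, FamilyData, em_fit, estimate_allele_freq
from .likelihood import LocusPairCounts, SirePhase, ld_to_haplo

__all__ = ["HalfSibPairModel"]


class HalfSibPairModel:
    """Two-locus recombination/LD model for one or more half-sib families.

    Parameters
    ----------
    families : list of FamilyData
        One entry per family whose sire is heterozygous at both loci, with
        its genotype count table and sire phase.  All families share theta
        and the maternal haplotype frequencies; the paternal gamete prior
        is oriented per family phase.

    Examples
    --------
    >>> counts = [[30, 12, 2], [10, 30, 9], [1, 14, 27]]
    >>> model = HalfSibPairModel.from_counts(counts)
    >>> res = model.fit()            # EM from theta = 0, D_dam = 0
    >>> pair = model.fit_dual()      # both proposals
    >>> est = model.estimate()       # decided estimate
    """

    def __init__(self, families: list[FamilyData]):
        if not families:
            raise ValueError("at least one family is required")
        self.families = list(families)

    @classmethod
    def from_counts(
        cls,
        counts,
        phase: SirePhase = SirePhase.COUPLING,
        family: str = "F1",
    ) -> "HalfSibPairModel":
        """Build the model from a single family's 3x3 genotype count table."""
        return cls([FamilyData(LocusPairCounts(counts), phase, family)])

    @classmethod
    def from_genotypes(
        cls,
        geno1,
        geno2,
        phase: SirePhase = SirePhase.COUPLING,
        family: str = "F1",
    ) -> "HalfSibPairModel":
        """Build the model from per-offspring allele-A counts (0/1/2) at the
        two loci; offspring with a missing genotype at either locus are
        dropped."""
        g1 = np.asarray(geno1, dtype=float)
        g2 = np.asarray(geno2, dtype=float)
        keep = np.isfinite(g1) & np.isfinite(g2)
        table = np.zeros((3, 3))
        np.add.at(table, (2 - g1[keep].astype(int), 2 - g2[keep].astype(int)), 1)
        return cls.from_counts(table, phase=phase, family=family)

    def allele_freq_estimates(self) -> tuple[float, float]:
        """Pooled ML estimates (p1_hat, p2_hat) of the maternal A-allele
        frequencies, from the homozygote marginals across families."""
        pooled = sum((f.counts.n for f in self.families), np.zeros((3, 3)))
        m1 = pooled.sum(axis=1)
        m2 = pooled.sum(axis=0)
        return (
            estimate_allele_freq(m1[0], m1[1], m1[2]),
            estimate_allele_freq(m2[0], m2[1], m2[2]),
        )

    def fit(
        self,
        start_theta: float = 0.0,
        start_d_dam: float = 0.0,
        *,
        tol: float = 1e-10,
        max_iter: int = 5000,
        theta_max: float = 1.0,
        record_path: bool = False,
    ) -> EMResult:
        """Single EM run.  The default start (theta = 0, D_dam = 0) is the
        EMT0 strategy; ``start_theta=0.5`` gives EMT05."""
        p1, p2 = self.allele_freq_estimates()
        if not (np.isfinite(p1) and np.isfinite(p2)):
            raise ValueError("pair is non-estimable: undefined allele frequency")
        p1 = float(np.clip(p1, 1e-6, 1 - 1e-6))
        p2 = float(np.clip(p2, 1e-6, 1 - 1e-6))
        lo_hi = ld_to_haplo(start_d_dam, p1, p2)
        return em_fit(
            self.families,
            start_theta,
            lo_hi,
            tol=tol,
            max_iter=max_iter,
            theta_max=theta_max,
            record_path=record_path,
        )

    def fit_dual(
        self,
        *,
        tol: float = 1e-10,
        max_iter: int = 5000,
        theta_max: float = 1.0,
    ) -> ProposalPair:
        """Dual-start procedure: default start plus the complementary start
        derived from the first run (skipped when out of space)."""
        p1, p2 = self.allele_freq_estimates()
        return emdp_propose(
            self.families, p1, p2, tol=tol, max_iter=max_iter, theta_max=theta_max
        )

    def estimate(
        self,
        *,
        tol: float = 1e-10,
        max_iter: int = 5000,
        theta_max: float = 1.0,
    ) -> PairEstimate:
        """Dual-start fit followed by the likelihood decision.

        The neighborhood (spline) rule needs a map context and lives in
        :func:`hsrecomb.io.estimate_chromosome`; for an isolated pair the
        likelihood comparison is the only applicable rule.
        """
        pair = self.fit_dual(tol=tol, max_iter=max_iter, theta_max=theta_max)
        return decide_by_loglik(pair)
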