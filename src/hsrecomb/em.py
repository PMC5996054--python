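"""EM estimation of the paternal recombination rate and maternal haplotype
frequencies from two-locus half-sib genotype counts.

The latent variable per offspring is the pair (paternal gamete, maternal
gamete).  The E-step distributes each observed genotype-cell count over the
gamete combinations that can produce it, proportionally to the current
transmission probabilities; the M-step sets theta to the expected fraction
of recombinant paternal gametes and the maternal haplotype frequencies to
the expected maternal gamete counts over the total.  This is the standard
multinomial missing-data EM, so the observed-data log-likelihood is
non-decreasing across iterations — asserted in the test suite as the
correctness check of the update equations.

Several families may be fitted jointly: all share (theta, maternal
haplotype frequencies) — the dams are assumed to come from one population —
while the paternal-gamete prior is oriented by each family's sire phase.
Since families with equal phase then contribute identically, the data
reduce to two pooled count tables, one per phase.

A vectorized engine (:func:`em_fit_batch`) runs many independent fits in
parallel over replicate/pair axes; :func:`em_fit` is the single-fit wrapper
used throughout the public API.  Both share the same update code path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .likelihood import (
    CELL_OF_COMBO16,
    COMBO_TO_CELL,
    LDParams,
    LocusPairCounts,
    MaternalHaplotypeFreqs,
    SirePhase,
    haplo_to_ld,
)

__all__ = [
    "FamilyData",
    "EMResult",
    "StartValueError",
    "em_fit",
    "em_fit_batch",
    "estimate_allele_freq",
    "pool_counts_by_phase",
    "BOUNDARY_NUDGE",
]

#: starts sitting exactly on the parameter-space boundary are moved inward
#: by this amount so that no genotype cell has zero probability at iteration 1
BOUNDARY_NUDGE = 1e-6

_TINY = 1e-300

# recombinant paternal gametes per phase: in coupling the recombinants are
# A-B / B-A (gamete indices 1, 2); in repulsion they are A-A / B-B (0, 3)
_REC_GAMETES = {0: np.array([1, 2]), 1: np.array([0, 3])}
_REC_COMBO_MASK = {
    s: np.isin(np.arange(16) // 4, _REC_GAMETES[s]) for s in (0, 1)
}


class StartValueError(ValueError):
    """Raised when the likelihood is -inf at the start values.

    Every observed genotype cell is impossible under the supplied start;
    jitter the start values away from the boundary and retry.
    """


@dataclass(frozen=True)
class FamilyData:
    """Genotype counts of one half-sib family at a locus pair.

    The phase is defined only when the family's sire is heterozygous at
    both loci; families with other sire genotypes carry no information on
    theta at this pair and are excluded upstream.
    """

    counts: LocusPairCounts
    phase: SirePhase
    family: str | None = None


def estimate_allele_freq(n_AA: float, n_AB: float, n_BB: float) -> float:
    """ML estimate of the maternal A-allele frequency at one locus.

    p_hat = n_AA / (n_AA + n_BB).  Heterozygous offspring are excluded:
    the sire is heterozygous, so it contributes allele A with probability
    0.5 regardless of the maternal allele, and AB offspring carry no
    information on the maternal frequency.  Returns NaN when no homozygous
    offspring exist (the pair is then non-estimable).
    """
    denom = n_AA + n_BB
    if denom <= 0:
        return math.nan
    return n_AA / denom


def pool_counts_by_phase(families: list[FamilyData]) -> np.ndarray:
    """Pool family count tables into a (2, 3, 3) array (coupling, repulsion).

    With shared (theta, maternal haplotype frequencies) the joint likelihood
    depends on the family data only through these phase-pooled tables.
    """
    pooled = np.zeros((2, 3, 3))
    for fam in families:
        s = 0 if fam.phase is SirePhase.COUPLING else 1
        pooled[s] += fam.counts.n
    return pooled


def _paternal_priors(theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Paternal gamete priors, shape (R, 4), for coupling and repulsion."""
    par = (1.0 - theta) / 2.0
    rec = theta / 2.0
    coupling = np.stack([par, rec, rec, par], axis=-1)
    repulsion = np.stack([rec, par, par, rec], axis=-1)
    return coupling, repulsion


def batch_loglik(n2: np.ndarray, theta: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Joint log-likelihood for R fits; n2 has shape (R, 2, 9).

    Returns -inf where a positive count sits on a zero-probability cell.
    """
    out = np.zeros(theta.shape[0])
    priors = _paternal_priors(theta)
    for s in (0, 1):
        ns = n2[:, s, :]
        if not ns.any():
            continue
        w = (priors[s][:, :, None] * h[:, None, :]).reshape(-1, 16)
        pi = w @ COMBO_TO_CELL
        pos = ns > 0
        bad = np.any(pos & (pi < _TINY), axis=1)
        safe = np.maximum(pi, _TINY)
        out += np.where(pos, ns * np.log(safe), 0.0).sum(axis=1)
        out[bad] = -np.inf
    return out


def batch_loglik_star(n2: np.ndarray, theta: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Combined-cell log LF* for R fits, summed over the two phase tables.

    Each phase-pooled table gets its own merge set (empty cells plus all
    cells tied at the minimum positive count).
    """
    out = np.zeros(theta.shape[0])
    priors = _paternal_priors(theta)
    for s in (0, 1):
        ns = n2[:, s, :]
        if not ns.any():
            continue
        w = (priors[s][:, :, None] * h[:, None, :]).reshape(-1, 16)
        pi = w @ COMBO_TO_CELL
        npos = np.where(ns > 0, ns, np.inf)
        minpos = npos.min(axis=1)
        has_pos = np.isfinite(minpos)
        J = (ns == 0) | (ns == minpos[:, None])
        J[~has_pos] = False
        keep = ~J & (ns > 0)
        bad = np.any(keep & (pi < _TINY), axis=1)
        safe = np.maximum(pi, _TINY)
        ll = np.where(keep, ns * np.log(safe), 0.0).sum(axis=1)
        nJ = np.where(J, ns, 0.0).sum(axis=1)
        piJ = np.where(J, pi, 0.0).sum(axis=1)
        merged = nJ > 0
        bad |= merged & (piJ < _TINY)
        ll += np.where(merged, nJ * np.log(np.maximum(piJ, _TINY)), 0.0)
        ll[bad] = -np.inf
        out += ll
    return out


def em_fit_batch(
    counts2: np.ndarray,
    theta0: np.ndarray,
    h0: np.ndarray,
    *,
    tol: float = 1e-10,
    max_iter: int = 5000,
    theta_max: float = 1.0,
    record_path: bool = False,
) -> dict:
    """Run R independent EM fits in parallel.

    Parameters
    ----------
    counts2 : (R, 2, 3, 3) array
        Phase-pooled genotype count tables (coupling, repulsion) per fit.
    theta0, h0 : (R,) and (R, 4) arrays
        Start values; callers are responsible for keeping them off the
        boundary (see :data:`BOUNDARY_NUDGE`).
    theta_max : float
        Upper bound for theta.  The default 1.0 deliberately admits
        estimates above 0.5 (which can reflect chromatid interference or a
        mis-specified sire phase); pass 0.5 to enforce the
        interference-free parameter space.

    Returns
    -------
    dict with arrays ``theta``, ``h``, ``loglik``, ``loglik_star``,
    ``iterations``, ``converged``, ``failed`` and (optionally) ``paths``,
    a list of per-fit log-likelihood trajectories.

    Notes
    -----
    Convergence is declared when the change in the joint log-likelihood
    falls below ``tol``.  Fits that have converged are removed from the
    active set, so a few flat-surface stragglers do not dominate the cost.
    """
    counts2 = np.asarray(counts2, dtype=float)
    R = counts2.shape[0]
    n2 = counts2.reshape(R, 2, 9)
    Ntot = n2.sum(axis=(1, 2))
    if np.any(Ntot < 1):
        raise ValueError("every fit needs at least one observation")

    theta = np.asarray(theta0, dtype=float).copy()
    h = np.asarray(h0, dtype=float).copy()
    ll = np.full(R, -np.inf)
    iterations = np.zeros(R, dtype=int)
    converged = np.zeros(R, dtype=bool)
    failed = np.zeros(R, dtype=bool)
    paths: list[list[float]] | None = [[] for _ in range(R)] if record_path else None

    active = np.arange(R)
    ll_prev = np.full(R, np.nan)
    has_phase = [bool(n2[:, s, :].any()) for s in (0, 1)]

    for _ in range(max_iter):
        if active.size == 0:
            break
        th_a = theta[active]
        h_a = h[active]
        priors = _paternal_priors(th_a)
        a = active.size
        rec = np.zeros(a)
        mat = np.zeros((a, 4))
        ll_a = np.zeros(a)
        bad = np.zeros(a, dtype=bool)
        for s in (0, 1):
            if not has_phase[s]:
                continue
            ns = n2[active, s, :]
            w = (priors[s][:, :, None] * h_a[:, None, :]).reshape(a, 16)
            pi = w @ COMBO_TO_CELL
            pos = ns > 0
            bad |= np.any(pos & (pi < _TINY), axis=1)
            safe = np.maximum(pi, _TINY)
            ll_a += np.where(pos, ns * np.log(safe), 0.0).sum(axis=1)
            f = np.where(pos, ns / safe, 0.0)
            expected = w * f[:, CELL_OF_COMBO16]
            rec += expected[:, _REC_COMBO_MASK[s]].sum(axis=1)
            mat += expected.reshape(a, 4, 4).sum(axis=1)
        ll_a = np.where(bad, -np.inf, ll_a)

        # M-step
        Na = Ntot[active]
        theta_new = np.clip(rec / Na, 0.0, theta_max)
        h_new = mat / Na[:, None]
        # frequencies may hit 0 exactly; the 0*log 0 convention in the
        # E-step keeps the likelihood well defined
        h_new = np.clip(h_new, 0.0, 1.0)
        h_new /= h_new.sum(axis=1, keepdims=True)

        iterations[active] += 1
        if record_path:
            for j, idx in enumerate(active):
                paths[idx].append(ll_a[j])

        delta = np.abs(ll_a - ll_prev[active])
        done = delta < tol
        fail = ~np.isfinite(ll_a)
        done |= fail

        ll[active] = ll_a
        ll_prev[active] = ll_a
        keep_theta = np.where(fail, theta[active], theta_new)
        keep_h = np.where(fail[:, None], h[active], h_new)
        theta[active] = keep_theta
        h[active] = keep_h
        converged[active[done & ~fail]] = True
        failed[active[fail]] = True
        active = active[~done]

    result = {
        "theta": theta,
        "h": h,
        "loglik": batch_loglik(n2, theta, h),
        "loglik_star": batch_loglik_star(n2, theta, h),
        "iterations": iterations,
        "converged": converged,
        "failed": failed,
    }
    if record_path:
        result["paths"] = paths
    return result


@dataclass
class EMResult:
    """Converged EM estimates for one locus pair.

    Attributes
    ----------
    theta_hat : float
        Paternal recombination rate estimate (in [0, theta_max]).
    haplo : MaternalHaplotypeFreqs
        Estimated maternal haplotype frequencies.
    params : LDParams
        The same estimates in the LD parametrization (coupling-oriented
        D_sire = (1 - 2 theta)/4).
    loglik, loglik_star : float
        Joint log-likelihood and its combined-cell variant at the estimate.
    """

    theta_hat: float
    haplo: MaternalHaplotypeFreqs
    loglik: float
    loglik_star: float
    n_iter: int
    converged: bool
    n_offspring: float
    n_families: int
    start_theta: float
    loglik_path: np.ndarray | None = field(default=None, repr=False)

    @property
    def D_dam_hat(self) -> float:
        return haplo_to_ld(self.haplo)[0]

    @property
    def p1_hat(self) -> float:
        return haplo_to_ld(self.haplo)[1]

    @property
    def p2_hat(self) -> float:
        return haplo_to_ld(self.haplo)[2]

    @property
    def params(self) -> LDParams:
        d_dam, p1, p2 = haplo_to_ld(self.haplo)
        return LDParams.from_theta(self.theta_hat, d_dam, p1, p2)

    def summary(self) -> str:
        d_dam, p1, p2 = haplo_to_ld(self.haplo)
        lines = [
            "Two-locus half-sib EM fit",
            "=" * 41,
            f"{'offspring':<28}{self.n_offspring:>13.0f}",
            f"{'families':<28}{self.n_families:>13d}",
            f"{'iterations':<28}{self.n_iter:>13d}",
            f"{'converged':<28}{str(self.converged):>13}",
            "-" * 41,
            f"{'theta (paternal rec. rate)':<28}{self.theta_hat:>13.6f}",
            f"{'D_dam (maternal LD)':<28}{d_dam:>13.6f}",
            f"{'p1 (maternal A freq)':<28}{p1:>13.6f}",
            f"{'p2 (maternal A freq)':<28}{p2:>13.6f}",
            f"{'p(A-A), p(A-B)':<28}{self.haplo.p_AA:>6.4f}, {self.haplo.p_AB:.4f}",
            f"{'p(B-A), p(B-B)':<28}{self.haplo.p_BA:>6.4f}, {self.haplo.p_BB:.4f}",
            "-" * 41,
            f"{'log LF':<28}{self.loglik:>13.6f}",
            f"{'log LF*':<28}{self.loglik_star:>13.6f}",
        ]
        return "\n".join(lines)


def nudge_start(theta: float, h: np.ndarray, theta_max: float = 1.0) -> tuple[float, np.ndarray]:
    """Move boundary start values inward by :data:`BOUNDARY_NUDGE`.

    A start with theta = 0 (or a haplotype frequency of 0) assigns zero
    probability to some genotype cells, which would lock the EM on the
    boundary; nudging makes every cell explainable at iteration 1 while
    leaving interior starts untouched.
    """
    theta = float(np.clip(theta, BOUNDARY_NUDGE, theta_max - BOUNDARY_NUDGE))
    h = np.maximum(np.asarray(h, dtype=float), BOUNDARY_NUDGE)
    return theta, h / h.sum()


def em_fit(
    families: list[FamilyData],
    start_theta: float,
    start_haplo: MaternalHaplotypeFreqs,
    tol: float = 1e-10,
    max_iter: int = 5000,
    *,
    theta_max: float = 1.0,
    record_path: bool = False,
) -> EMResult:
    """Maximize the joint two-locus likelihood over theta and the maternal
    haplotype frequencies by EM.

    Parameters
    ----------
    families : list of FamilyData
        One entry per half-sib family with a double-heterozygous sire;
        counts are pooled by sire phase and (theta, haplotype frequencies)
        are shared across families.
    start_theta, start_haplo
        Start values; boundary values are nudged inward by 1e-6.
    tol, max_iter
        Convergence is |delta log LF| < tol (default 1e-10; the surface can
        be rather flat, hence the generous max_iter).

    Raises
    ------
    StartValueError
        If the likelihood is -inf at the (nudged) start, i.e. some observed
        genotype cell is impossible; jitter the start values and retry.
    """
    if not families:
        raise ValueError("at least one family is required")
    pooled = pool_counts_by_phase(families)
    if pooled.sum() < 1:
        raise ValueError("at least one genotype observation is required")
    theta0, h0 = nudge_start(start_theta, start_haplo.as_array(), theta_max)
    ll0 = batch_loglik(
        pooled.reshape(1, 2, 9), np.array([theta0]), h0.reshape(1, 4)
    )[0]
    if not np.isfinite(ll0):
        raise StartValueError(
            "likelihood is -inf at the start values (an observed genotype "
            "cell is impossible); jitter the start values and retry"
        )
    res = em_fit_batch(
        pooled[None, :, :, :],
        np.array([theta0]),
        h0[None, :],
        tol=tol,
        max_iter=max_iter,
        theta_max=theta_max,
        record_path=record_path,
    )
    if res["failed"][0]:
        raise StartValueError(
            "likelihood became -inf during EM; jitter the start values and retry"
        )
    return EMResult(
        theta_hat=float(res["theta"][0]),
        haplo=MaternalHaplotypeFreqs.from_array(res["h"][0]),
        loglik=float(res["loglik"][0]),
        loglik_star=float(res["loglik_star"][0]),
        n_iter=int(res["iterations"][0]),
        converged=bool(res["converged"][0]),
        n_offspring=float(pooled.sum()),
        n_families=len(families),
        start_theta=float(start_theta),
        loglik_path=np.array(res["paths"][0]) if record_path else None,
    )
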