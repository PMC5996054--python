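"""Dual-start strategy exploiting the two modes of the two-locus likelihood.

The likelihood surface over (D_sire, D_dam) can have two local maxima whose
heights depend on the maternal allele frequencies.  The two modes are
linked through the covariances between additively and dominance-coded
genotypes at the two loci,

    cov_add = D_sire + D_dam
    cov_dom = 16 D_sire D_dam + 4 D_sire (1 - 2 p1)(1 - 2 p2),

a system with two solutions for (D_sire, D_dam).  Given one solution the
other is

    D_sire' = D_dam + c,   D_dam' = D_sire - c,   c = (1 - 2 p1)(1 - 2 p2)/4,

an involution; at p1 = p2 = 0.5 it simply swaps paternal and maternal LD.

The dual-start procedure runs the EM once from the default start
(theta = 0, D_dam = 0), maps the converged estimates through the
complementary relationship, and — when the complementary point lies inside
the parameter space — runs the EM a second time from there.  A
complementary start outside the space indicates a unimodal surface and the
second run is skipped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .likelihood import (
    DomainError,
    LDParams,
    ddam_bounds,
    ld_to_haplo,
)
from .em import (
    BOUNDARY_NUDGE,
    EMResult,
    FamilyData,
    em_fit,
    em_fit_batch,
    nudge_start,
)

__all__ = [
    "ProposalPair",
    "cov_system",
    "complementary_params",
    "complementary_start_in_space",
    "emdp_propose",
    "emdp_batch",
]

#: proposals closer than this in log LF* and in parameters are considered
#: the same mode and the pair is collapsed to a unimodal result
COLLAPSE_LL_TOL = 1e-9
COLLAPSE_PARAM_TOL = 1e-6


def cov_system(params: LDParams) -> tuple[float, float]:
    """Covariances (cov_add, cov_dom) of additively / dominance coded
    genotypes implied by the LD parameters.

    Both solutions of the two-mode system reproduce the same pair, which is
    what ties the modes together.
    """
    cov_add = params.D_sire + params.D_dam
    cov_dom = 16.0 * params.D_sire * params.D_dam + 4.0 * params.D_sire * (
        1.0 - 2.0 * params.p1
    ) * (1.0 - 2.0 * params.p2)
    return cov_add, cov_dom


def complementary_params(params: LDParams) -> LDParams:
    """The second solution of the covariance system, given the first.

    With c = (1 - 2 p1)(1 - 2 p2)/4:  D_sire' = D_dam + c and
    D_dam' = D_sire - c, at unchanged allele frequencies.  Applying the map
    twice returns the input.  The result is *not* validated — it may lie
    outside the parameter space, which the caller interprets as evidence of
    a unimodal likelihood.
    """
    c = (1.0 - 2.0 * params.p1) * (1.0 - 2.0 * params.p2) / 4.0
    return LDParams(
        D_sire=params.D_dam + c,
        D_dam=params.D_sire - c,
        p1=params.p1,
        p2=params.p2,
    )


def complementary_start_in_space(params: LDParams) -> bool:
    """Whether a complementary start point is usable for a second EM run.

    Checked on both LD bounds (|D_sire| <= 0.25, D_dam within the
    frequency-dependent bounds) and on the reconstructed maternal haplotype
    simplex.
    """
    if abs(params.D_sire) > 0.25:
        return False
    try:
        lo, hi = ddam_bounds(params.p1, params.p2)
    except DomainError:
        return False
    if not (lo - 1e-12 <= params.D_dam <= hi + 1e-12):
        return False
    try:
        ld_to_haplo(params.D_dam, params.p1, params.p2)
    except DomainError:
        return False
    return True


@dataclass
class ProposalPair:
    """The one or two EM proposals produced by the dual-start procedure.

    ``second`` is absent when the complementary start fell outside the
    parameter space (unimodal surface) or when the second run converged
    back to the first mode.
    """

    first: EMResult
    second: EMResult | None
    complementary_start: LDParams
    complementary_in_space: bool

    @property
    def unimodal(self) -> bool:
        return self.second is None


def _same_mode(a: EMResult, b: EMResult) -> bool:
    if abs(a.loglik_star - b.loglik_star) >= COLLAPSE_LL_TOL:
        return False
    da = np.array([a.theta_hat, *a.haplo.as_array()])
    db = np.array([b.theta_hat, *b.haplo.as_array()])
    return bool(np.max(np.abs(da - db)) < COLLAPSE_PARAM_TOL)


def emdp_propose(
    families: list[FamilyData],
    p1_hat: float,
    p2_hat: float,
    *,
    tol: float = 1e-10,
    max_iter: int = 5000,
    theta_max: float = 1.0,
) -> ProposalPair:
    """Run the EM from the default start and, if admissible, from the
    complementary start derived from the first run's estimates.

    Parameters
    ----------
    families : list of FamilyData
        Phase-oriented count tables; see :func:`hsrecomb.em.em_fit`.
    p1_hat, p2_hat : float
        Maternal allele-frequency estimates used to build the haplotype
        start (D_dam = 0) for the first run.

    Returns
    -------
    ProposalPair
        First proposal always present; second present only for a bimodal
        surface with an in-space complementary start that converged to a
        distinct mode.
    """
    if not (np.isfinite(p1_hat) and np.isfinite(p2_hat)):
        raise ValueError("pair is non-estimable: undefined allele frequency")
    p1c = float(np.clip(p1_hat, BOUNDARY_NUDGE, 1 - BOUNDARY_NUDGE))
    p2c = float(np.clip(p2_hat, BOUNDARY_NUDGE, 1 - BOUNDARY_NUDGE))
    start_haplo = ld_to_haplo(0.0, p1c, p2c)
    first = em_fit(
        families, 0.0, start_haplo, tol=tol, max_iter=max_iter, theta_max=theta_max
    )
    # Eq.-2 map applied to the run-1 LD estimates at the marginal
    # allele-frequency estimates (the same p-hat that seeds run 1); the
    # reported mode-selection frequencies pin this choice down
    comp = complementary_params(
        LDParams(
            D_sire=first.params.D_sire,
            D_dam=first.D_dam_hat,
            p1=p1c,
            p2=p2c,
        )
    )
    in_space = complementary_start_in_space(comp)
    if theta_max < comp.theta:
        in_space = False
    second: EMResult | None = None
    if in_space:
        h2 = ld_to_haplo(comp.D_dam, comp.p1, comp.p2)
        second = em_fit(
            families,
            comp.theta,
            h2,
            tol=tol,
            max_iter=max_iter,
            theta_max=theta_max,
        )
        if _same_mode(first, second):
            second = None
    return ProposalPair(
        first=first,
        second=second,
        complementary_start=comp,
        complementary_in_space=in_space,
    )


def emdp_batch(
    counts2: np.ndarray,
    p1_hat: np.ndarray,
    p2_hat: np.ndarray,
    *,
    tol: float = 1e-10,
    max_iter: int = 5000,
    theta_max: float = 1.0,
) -> dict:
    """Vectorized dual-start procedure over R independent locus pairs.

    Mirrors :func:`emdp_propose` on arrays: run 1 from (theta = 0,
    D_dam = 0), complementary starts from the run-1 estimates, run 2 on the
    subset with in-space complements.  Returns a dict of arrays with both
    runs' estimates, their log LF* values and bookkeeping masks
    (``second_present``, ``collapsed``).
    """
    counts2 = np.asarray(counts2, dtype=float)
    R = counts2.shape[0]
    n2 = counts2.reshape(R, 2, 9)

    p1c = np.clip(p1_hat, BOUNDARY_NUDGE, 1 - BOUNDARY_NUDGE)
    p2c = np.clip(p2_hat, BOUNDARY_NUDGE, 1 - BOUNDARY_NUDGE)
    h0 = np.stack(
        [p1c * p2c, p1c * (1 - p2c), (1 - p1c) * p2c, (1 - p1c) * (1 - p2c)],
        axis=1,
    )
    theta0 = np.zeros(R)
    th0, _ = nudge_start(0.0, np.ones(4), theta_max)
    theta0[:] = th0
    h0 = np.maximum(h0, BOUNDARY_NUDGE)
    h0 /= h0.sum(axis=1, keepdims=True)

    run1 = em_fit_batch(
        counts2, theta0, h0, tol=tol, max_iter=max_iter, theta_max=theta_max
    )

    # complementary starts: Eq.-2 map of the run-1 LD estimates, evaluated
    # at the marginal allele-frequency estimates p-hat
    h1 = run1["h"]
    p1e = h1[:, 0] + h1[:, 1]
    p2e = h1[:, 0] + h1[:, 2]
    d_dam1 = h1[:, 0] - p1e * p2e
    d_sire1 = (1.0 - 2.0 * run1["theta"]) / 4.0
    c = (1.0 - 2.0 * p1c) * (1.0 - 2.0 * p2c) / 4.0
    d_sire2 = d_dam1 + c
    d_dam2 = d_sire1 - c

    lo = np.maximum(-p1c * p2c, -(1 - p1c) * (1 - p2c))
    hi = np.minimum(p1c * (1 - p2c), (1 - p1c) * p2c)
    theta2 = (1.0 - 4.0 * d_sire2) / 2.0
    in_space = (
        (np.abs(d_sire2) <= 0.25)
        & (d_dam2 >= lo - 1e-12)
        & (d_dam2 <= hi + 1e-12)
        & (theta2 <= theta_max)
        & ~run1["failed"]
    )

    theta_b = np.full(R, np.nan)
    h_b = np.full((R, 4), np.nan)
    ll_b = np.full(R, -np.inf)
    lls_b = np.full(R, -np.inf)
    iters_b = np.zeros(R, dtype=int)
    conv_b = np.zeros(R, dtype=bool)

    idx = np.flatnonzero(in_space)
    if idx.size:
        d2 = np.clip(d_dam2[idx], lo[idx], hi[idx])
        p1s, p2s = p1c[idx], p2c[idx]
        h20 = np.stack(
            [
                p1s * p2s + d2,
                p1s * (1 - p2s) - d2,
                (1 - p1s) * p2s - d2,
                (1 - p1s) * (1 - p2s) + d2,
            ],
            axis=1,
        )
        h20 = np.maximum(h20, BOUNDARY_NUDGE)
        h20 /= h20.sum(axis=1, keepdims=True)
        th20 = np.clip(theta2[idx], BOUNDARY_NUDGE, theta_max - BOUNDARY_NUDGE)
        run2 = em_fit_batch(
            counts2[idx],
            th20,
            h20,
            tol=tol,
            max_iter=max_iter,
            theta_max=theta_max,
        )
        theta_b[idx] = run2["theta"]
        h_b[idx] = run2["h"]
        ll_b[idx] = run2["loglik"]
        lls_b[idx] = run2["loglik_star"]
        iters_b[idx] = run2["iterations"]
        conv_b[idx] = run2["converged"]

    same_ll = np.abs(lls_b - run1["loglik_star"]) < COLLAPSE_LL_TOL
    same_par = (
        np.abs(theta_b - run1["theta"]) < COLLAPSE_PARAM_TOL
    ) & np.all(np.abs(h_b - run1["h"]) < COLLAPSE_PARAM_TOL, axis=1)
    collapsed = in_space & same_ll & same_par
    second_present = in_space & ~collapsed

    return {
        "theta1": run1["theta"],
        "h1": run1["h"],
        "loglik1": run1["loglik"],
        "loglik_star1": run1["loglik_star"],
        "iterations1": run1["iterations"],
        "converged1": run1["converged"],
        "failed1": run1["failed"],
        "theta2": theta_b,
        "h2": h_b,
        "loglik2": ll_b,
        "loglik_star2": lls_b,
        "iterations2": iters_b,
        "converged2": conv_b,
        "complementary_in_space": in_space,
        "second_present": second_present,
        "collapsed": collapsed,
        "d_sire_comp": d_sire2,
        "d_dam_comp": d_dam2,
    }
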