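"""Choosing the final estimate from the pair of EM proposals.

For locus pairs whose maternal allele-frequency estimates lie outside the
critical range [0.48, 0.52] the two likelihood modes differ clearly in
height and the proposal with the larger combined-cell log-likelihood
(log LF*) wins.  Inside the critical range the modes are nearly equal and
the likelihood cannot discriminate; there the decision borrows strength
from the neighborhood: a cubic smoothing spline (five effective degrees of
freedom) is fitted to the already-decided recombination-rate estimates of
one locus against the relative physical positions of its mates, and the
proposal closer to the curve at the mate's position is selected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.linalg import cho_factor, cho_solve, eigh
from scipy.optimize import brentq

from .duality import ProposalPair
from .em import EMResult
from .likelihood import haplo_to_ld, r_squared

__all__ = [
    "CRITICAL_RANGE",
    "PairEstimate",
    "SplineCurve",
    "is_critical",
    "decide_by_loglik",
    "fit_smoothing_curve",
    "decide_by_spline",
]

#: maternal allele-frequency interval (closed) in which the two likelihood
#: modes are expected to have near-equal height
CRITICAL_RANGE = (0.48, 0.52)

#: minimum number of neighborhood points needed to support a 5-df spline
MIN_SPLINE_POINTS = 10

_LL_TIE_TOL = 1e-12


def is_critical(
    p1_hat: float, p2_hat: float, critical_range: tuple[float, float] = CRITICAL_RANGE
) -> bool:
    """True iff *both* allele-frequency estimates fall in the critical range.

    The interval is closed; a pair is non-critical as soon as one frequency
    leaves the range, because one clearly off-centre frequency already
    separates the mode heights.
    """
    lo, hi = critical_range
    return (lo <= p1_hat <= hi) and (lo <= p2_hat <= hi)


@dataclass
class PairEstimate:
    """Final decided estimate for a locus pair, with decision provenance.

    The estimate is always bit-identical to one of the proposals —
    the decision selects, it never averages or re-fits.
    """

    i: int
    k: int
    theta_hat: float
    D_dam_hat: float
    p1_hat: float
    p2_hat: float
    r2_hat: float
    loglik_star: float
    decision: str  # 'loglik' | 'spline' | 'unimodal'
    mode: str  # 'first' | 'second'
    n_families: int
    n_offspring: float


def _estimate_from(result: EMResult, i: int, k: int, decision: str, mode: str) -> PairEstimate:
    d_dam, p1, p2 = haplo_to_ld(result.haplo)
    return PairEstimate(
        i=i,
        k=k,
        theta_hat=result.theta_hat,
        D_dam_hat=d_dam,
        p1_hat=p1,
        p2_hat=p2,
        r2_hat=r_squared(d_dam, p1, p2),
        loglik_star=result.loglik_star,
        decision=decision,
        mode=mode,
        n_families=result.n_families,
        n_offspring=result.n_offspring,
    )


def decide_by_loglik(pair: ProposalPair, i: int = 0, k: int = 1) -> PairEstimate:
    """Select the proposal with the larger combined-cell log-likelihood.

    A single proposal (unimodal surface) is returned as-is with decision
    'unimodal'.  An exact tie falls to the first proposal with a warning —
    outside the critical range ties are not expected, so they deserve a
    look.
    """
    if pair.second is None:
        return _estimate_from(pair.first, i, k, "unimodal", "first")
    d = pair.first.loglik_star - pair.second.loglik_star
    if abs(d) < _LL_TIE_TOL:
        warnings.warn(
            f"log LF* tie ({pair.first.loglik_star:.12g}) at pair ({i}, {k}); "
            "keeping the first (default-start) proposal",
            stacklevel=2,
        )
        return _estimate_from(pair.first, i, k, "loglik", "first")
    if d >= 0:
        return _estimate_from(pair.first, i, k, "loglik", "first")
    return _estimate_from(pair.second, i, k, "loglik", "second")


def _penalty_matrix(x: np.ndarray) -> np.ndarray:
    """Natural-cubic-spline roughness penalty K with integral g''^2 = g'Kg.

    Standard construction from the second-difference map Q and the
    tridiagonal Gram matrix R of the natural spline basis: K = Q R^{-1} Q^T.
    """
    n = x.size
    hdif = np.diff(x)
    Q = np.zeros((n, n - 2))
    Rm = np.zeros((n - 2, n - 2))
    for j in range(1, n - 1):
        Q[j - 1, j - 1] = 1.0 / hdif[j - 1]
        Q[j, j - 1] = -1.0 / hdif[j - 1] - 1.0 / hdif[j]
        Q[j + 1, j - 1] = 1.0 / hdif[j]
        Rm[j - 1, j - 1] = (hdif[j - 1] + hdif[j]) / 3.0
        if j < n - 2:
            Rm[j - 1, j] = hdif[j] / 6.0
            Rm[j, j - 1] = hdif[j] / 6.0
    cf = cho_factor(Rm)
    return Q @ cho_solve(cf, Q.T)


class SplineCurve:
    """Cubic smoothing spline with a prescribed effective df, evaluable on [0, 1].

    The fit minimizes sum_i w_i (y_i - g(x_i))^2 + lam * integral g''^2 over
    natural cubic splines; lam is chosen so that the trace of the smoother
    matrix equals ``df``.  Duplicate abscissae are collapsed to their
    (weighted) mean with summed weights, matching common smoothing-spline
    practice.  Evaluation outside the data range extends the curve
    linearly, as a natural spline does.
    """

    def __init__(self, x: np.ndarray, y: np.ndarray, df: float = 5.0, w=None):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if w is None:
            w = np.ones_like(x)
        w = np.asarray(w, dtype=float)

        order = np.argsort(x, kind="stable")
        x, y, w = x[order], y[order], w[order]
        xu, inv = np.unique(x, return_inverse=True)
        wu = np.bincount(inv, weights=w)
        yu = np.bincount(inv, weights=w * y) / wu
        if xu.size < 4:
            raise ValueError(
                f"need at least 4 distinct positions for a cubic smoothing "
                f"spline, got {xu.size}"
            )
        if df >= xu.size:
            raise ValueError(
                f"df={df} is not attainable with {xu.size} distinct positions"
            )
        # scale positions to [0, 1]; df is invariant, lam stays well-scaled
        span = xu[-1] - xu[0]
        xs = (xu - xu[0]) / span
        K = _penalty_matrix(xs)
        sw = np.sqrt(wu)
        B = K / np.outer(sw, sw)
        evals = np.clip(eigh(B, eigvals_only=True), 0.0, None)

        def df_of(log_lam: float) -> float:
            return float(np.sum(1.0 / (1.0 + 10.0**log_lam * evals)))

        # df(lam) falls monotonically from n to 2; bracket then root-find
        lo, hi = -18.0, 18.0
        if df_of(lo) < df or df_of(hi) > df:
            raise ValueError(f"cannot reach df={df} for this configuration")
        log_lam = brentq(lambda t: df_of(t) - df, lo, hi, xtol=1e-10)
        lam = 10.0**log_lam

        A = lam * K + np.diag(wu)
        g = np.linalg.solve(A, wu * yu)

        self.df = float(df)
        self.lam_scaled = float(lam)
        self.x_ = xu
        self.fitted_ = g
        self.weights_ = wu
        self._spline = CubicSpline(xu, g, bc_type="natural")
        # linear extension beyond the data range
        d = self._spline.derivative()
        self._left = (xu[0], g[0], float(d(xu[0])))
        self._right = (xu[-1], g[-1], float(d(xu[-1])))

    def __call__(self, pos) -> np.ndarray | float:
        pos = np.asarray(pos, dtype=float)
        scalar = pos.ndim == 0
        pos = np.atleast_1d(pos)
        out = self._spline(pos)
        x0, y0, s0 = self._left
        x1, y1, s1 = self._right
        out = np.where(pos < x0, y0 + s0 * (pos - x0), out)
        out = np.where(pos > x1, y1 + s1 * (pos - x1), out)
        return float(out[0]) if scalar else out


def fit_smoothing_curve(
    positions,
    theta_hats,
    df: float = 5.0,
    *,
    min_points: int = MIN_SPLINE_POINTS,
) -> SplineCurve:
    """Fit the neighborhood smoothing curve theta-hat vs relative position.

    Parameters
    ----------
    positions : array-like
        Relative physical positions in [0, 1] (bp scaled by chromosome
        length) of the mates of the locus under consideration.
    theta_hats : array-like
        Final (already decided) recombination-rate estimates to those mates.
    df : float
        Effective degrees of freedom of the smoother (default 5).

    Raises
    ------
    ValueError
        With fewer than ``min_points`` points; callers fall back to the
        likelihood comparison in that case.
    """
    positions = np.asarray(positions, dtype=float)
    theta_hats = np.asarray(theta_hats, dtype=float)
    keep = np.isfinite(positions) & np.isfinite(theta_hats)
    positions, theta_hats = positions[keep], theta_hats[keep]
    if positions.size < min_points:
        raise ValueError(
            f"only {positions.size} usable neighborhood estimates; "
            f"at least {min_points} are required for a {df}-df spline"
        )
    return SplineCurve(positions, theta_hats, df=df)


def decide_by_spline(
    pair: ProposalPair,
    curve: SplineCurve,
    position_k: float,
    i: int = 0,
    k: int = 1,
) -> PairEstimate:
    """Select the proposal whose theta-hat is closer to the smoothing curve.

    The curve is evaluated at the relative physical position of the mate
    SNP; the proposal minimizing the squared deviation wins.  Equal
    deviations fall to the first proposal with a warning.
    """
    if pair.second is None:
        return _estimate_from(pair.first, i, k, "unimodal", "first")
    target = float(curve(position_k))
    d1 = (pair.first.theta_hat - target) ** 2
    d2 = (pair.second.theta_hat - target) ** 2
    if d1 == d2:
        warnings.warn(
            f"equal spline deviations at pair ({i}, {k}); keeping the first proposal",
            stacklevel=2,
        )
        return _estimate_from(pair.first, i, k, "spline", "first")
    if d1 < d2:
        return _estimate_from(pair.first, i, k, "spline", "first")
    return _estimate_from(pair.second, i, k, "spline", "second")
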