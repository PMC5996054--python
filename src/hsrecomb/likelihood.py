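"""Two-locus genotype likelihood for paternal half-sib families.

A sire that is heterozygous at two biallelic SNPs transmits, per offspring,
one of four gametes: the two parental haplotypes each with probability
(1 - theta)/2 and the two recombinant haplotypes each with probability
theta/2, where theta is the paternal recombination rate.  The maternal
gamete is drawn from a dam population with haplotype frequencies
(p_AA, p_AB, p_BA, p_BB).  The offspring's unordered two-locus genotype is
the allele-wise sum of the two gametes, so the nine genotype-cell
probabilities are sums of paternal-gamete x maternal-gamete products.

The model is reparametrized in terms of linkage disequilibria:

    D_sire = +-(1 - 2 theta)/4   (positive sign: coupling phase)
    D_dam  = p_AA - p1 * p2

with p1, p2 the maternal A-allele frequencies at the two loci.  The
log-likelihood of a 3x3 table of offspring genotype counts n_{i,k} is the
multinomial sum n_{i,k} log pi_{i,k} (additive constant omitted).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SirePhase",
    "MaternalHaplotypeFreqs",
    "LDParams",
    "LocusPairCounts",
    "DomainError",
    "GENOTYPES",
    "HAPLOTYPES",
    "genotype_probs",
    "loglik",
    "loglik_star",
    "ddam_bounds",
    "haplo_to_ld",
    "ld_to_haplo",
    "r_squared",
]

#: genotype labels indexing rows/columns of every 3x3 table (A-allele count 2,1,0)
GENOTYPES = ("AA", "AB", "BB")

#: gamete labels; first symbol is the allele at locus 1
HAPLOTYPES = ("A-A", "A-B", "B-A", "B-B")

# allele (1 = A) carried by each gamete at locus 1 / locus 2
_GAMETE_L1 = np.array([1, 1, 0, 0])
_GAMETE_L2 = np.array([1, 0, 1, 0])

# cell index of the genotype produced by paternal gamete g and maternal
# gamete m: row = 2 - (#A at locus 1), col = 2 - (#A at locus 2)
_CELL_OF_COMBO = np.empty((4, 4), dtype=int)
for _g in range(4):
    for _m in range(4):
        _row = 2 - (_GAMETE_L1[_g] + _GAMETE_L1[_m])
        _col = 2 - (_GAMETE_L2[_g] + _GAMETE_L2[_m])
        _CELL_OF_COMBO[_g, _m] = 3 * _row + _col

#: (16,) cell index for each flattened (paternal, maternal) gamete combination
CELL_OF_COMBO16 = _CELL_OF_COMBO.reshape(-1)

#: (16, 9) 0/1 aggregation matrix: combo -> genotype cell
COMBO_TO_CELL = np.zeros((16, 9))
COMBO_TO_CELL[np.arange(16), CELL_OF_COMBO16] = 1.0

# probabilities below this floor are treated as impossible when a positive
# count sits on the cell (mode comparison then sees -inf, no exception)
_PROB_FLOOR = 1e-300


class DomainError(ValueError):
    """Parameter outside the admissible space; the message names the bound."""


class SirePhase(str, enum.Enum):
    """Arrangement of a double-heterozygous sire's alleles on its haplotypes.

    Coupling: haplotypes A-A / B-B.  Repulsion: A-B / B-A.  Switching the
    phase is equivalent to replacing theta by 1 - theta (i.e. negating
    D_sire).
    """

    COUPLING = "coupling"
    REPULSION = "repulsion"


@dataclass(frozen=True)
class MaternalHaplotypeFreqs:
    """Dam-gamete haplotype frequencies (p_AA, p_AB, p_BA, p_BB).

    The first allele symbol refers to locus 1, e.g. ``p_AB`` is the
    frequency of maternal gametes carrying A at locus 1 and B at locus 2.
    """

    p_AA: float
    p_AB: float
    p_BA: float
    p_BB: float

    def __post_init__(self) -> None:
        for name in ("p_AA", "p_AB", "p_BA", "p_BB"):
            v = getattr(self, name)
            if not (-1e-12 <= v <= 1 + 1e-12):
                raise DomainError(f"haplotype frequency {name}={v} outside [0, 1]")
        if abs(sum(self.as_array()) - 1.0) > 1e-12:
            raise DomainError(
                f"haplotype frequencies sum to {sum(self.as_array())}, expected 1"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.p_AA, self.p_AB, self.p_BA, self.p_BB])

    @classmethod
    def from_array(cls, h: np.ndarray) -> "MaternalHaplotypeFreqs":
        return cls(float(h[0]), float(h[1]), float(h[2]), float(h[3]))


@dataclass(frozen=True)
class LDParams:
    """LD parametrization (D_sire, D_dam, p1, p2) of the two-locus model.

    ``theta`` is derived from ``D_sire`` via the coupling-phase convention
    theta = (1 - 4 D_sire)/2; D_sire in [-0.25, 0.25] maps onto
    theta in [0, 1].  Construction does not validate, so that
    out-of-space candidates (e.g. complementary start values) can be
    represented; call :meth:`validate` or :meth:`in_space` explicitly.
    """

    D_sire: float
    D_dam: float
    p1: float
    p2: float

    @property
    def theta(self) -> float:
        return (1.0 - 4.0 * self.D_sire) / 2.0

    @classmethod
    def from_theta(cls, theta: float, D_dam: float, p1: float, p2: float) -> "LDParams":
        return cls((1.0 - 2.0 * theta) / 4.0, D_dam, p1, p2)

    def validate(self) -> "LDParams":
        if not (0.0 <= self.p1 <= 1.0):
            raise DomainError(f"p1={self.p1} outside [0, 1]")
        if not (0.0 <= self.p2 <= 1.0):
            raise DomainError(f"p2={self.p2} outside [0, 1]")
        if abs(self.D_sire) > 0.25 + 1e-12:
            raise DomainError(f"D_sire={self.D_sire} outside [-0.25, 0.25]")
        lo, hi = ddam_bounds(self.p1, self.p2)
        if not (lo - 1e-12 <= self.D_dam <= hi + 1e-12):
            raise DomainError(
                f"D_dam={self.D_dam} outside [{lo}, {hi}] for p1={self.p1}, p2={self.p2}"
            )
        return self

    def in_space(self) -> bool:
        try:
            self.validate()
        except DomainError:
            return False
        return True


class LocusPairCounts:
    """3x3 table of two-locus offspring genotype counts.

    Rows index the genotype at locus 1 and columns at locus 2, in the order
    AA, AB, BB.  Entry ``n[0, 2]`` is therefore the number of offspring with
    genotype AA at locus 1 and BB at locus 2.
    """

    def __init__(self, n):
        arr = np.asarray(n, dtype=float)
        if arr.shape != (3, 3):
            raise ValueError(f"expected a 3x3 count table, got shape {arr.shape}")
        if np.any(arr < 0):
            raise ValueError("genotype counts must be non-negative")
        self.n = arr

    @property
    def N(self) -> float:
        return float(self.n.sum())

    def locus1_marginals(self) -> np.ndarray:
        """Counts (n_AA, n_AB, n_BB) at locus 1."""
        return self.n.sum(axis=1)

    def locus2_marginals(self) -> np.ndarray:
        return self.n.sum(axis=0)

    def __add__(self, other: "LocusPairCounts") -> "LocusPairCounts":
        return LocusPairCounts(self.n + other.n)

    def __repr__(self) -> str:  # pragma: no cover
        return f"LocusPairCounts(N={self.N:g})"


def ddam_bounds(p1: float, p2: float) -> tuple[float, float]:
    """Admissible range [L1, L2] of the maternal LD given allele frequencies.

    L1 = max{-p1 p2, -(1-p1)(1-p2)} and L2 = min{p1(1-p2), (1-p1) p2};
    the classical bounds keeping all four haplotype frequencies in [0, 1].
    """
    if not (0.0 <= p1 <= 1.0):
        raise DomainError(f"p1={p1} outside [0, 1]")
    if not (0.0 <= p2 <= 1.0):
        raise DomainError(f"p2={p2} outside [0, 1]")
    L1 = max(-p1 * p2, -(1.0 - p1) * (1.0 - p2))
    L2 = min(p1 * (1.0 - p2), (1.0 - p1) * p2)
    return L1, L2


def haplo_to_ld(freqs: MaternalHaplotypeFreqs) -> tuple[float, float, float]:
    """Map haplotype frequencies to (D_dam, p1, p2)."""
    p1 = freqs.p_AA + freqs.p_AB
    p2 = freqs.p_AA + freqs.p_BA
    return freqs.p_AA - p1 * p2, p1, p2


def ld_to_haplo(D_dam: float, p1: float, p2: float) -> MaternalHaplotypeFreqs:
    """Reconstruct the maternal haplotype simplex from (D_dam, p1, p2)."""
    vals = {
        "p_AA": p1 * p2 + D_dam,
        "p_AB": p1 * (1.0 - p2) - D_dam,
        "p_BA": (1.0 - p1) * p2 - D_dam,
        "p_BB": (1.0 - p1) * (1.0 - p2) + D_dam,
    }
    for name, v in vals.items():
        if not (-1e-12 <= v <= 1 + 1e-12):
            raise DomainError(
                f"D_dam={D_dam} with p1={p1}, p2={p2} puts haplotype "
                f"{name}={v} outside [0, 1]"
            )
    return MaternalHaplotypeFreqs(**{k: min(max(v, 0.0), 1.0) for k, v in vals.items()})


def r_squared(D_dam: float, p1: float, p2: float) -> float:
    """Standardized LD r^2 = D_dam^2 / (p1 (1-p1) p2 (1-p2)).

    Undefined (NaN) when either locus is monomorphic among maternal gametes.
    """
    denom = p1 * (1.0 - p1) * p2 * (1.0 - p2)
    if denom <= 0.0:
        return math.nan
    return D_dam * D_dam / denom


def paternal_gamete_probs(theta: float, phase: SirePhase) -> np.ndarray:
    """Transmission probabilities of the four paternal gametes.

    Order A-A, A-B, B-A, B-B.  In coupling phase A-A/B-B are parental
    (probability (1-theta)/2 each); in repulsion they are the recombinants.
    """
    if phase is SirePhase.COUPLING:
        par, rec = (1.0 - theta) / 2.0, theta / 2.0
    else:
        par, rec = theta / 2.0, (1.0 - theta) / 2.0
    return np.array([par, rec, rec, par])


def genotype_probs(params: LDParams, phase: SirePhase) -> np.ndarray:
    """Nine two-locus genotype probabilities as a 3x3 array.

    Built from the gamete decomposition: pi_{i,k} = sum over paternal x
    maternal gamete pairs producing genotype (i, k) of the product of
    transmission probabilities.  E.g. in coupling phase
    pi_{AA,AA} = (1/4 + D_sire)(D_dam + p1 p2).
    """
    params.validate()
    pat = paternal_gamete_probs(params.theta, phase)
    mat = ld_to_haplo(params.D_dam, params.p1, params.p2).as_array()
    w = np.outer(pat, mat).reshape(-1)
    pi = (w @ COMBO_TO_CELL).reshape(3, 3)
    # clip tiny negative round-off
    return np.clip(pi, 0.0, None)


def loglik(counts: LocusPairCounts, params: LDParams, phase: SirePhase) -> float:
    """Multinomial log-likelihood sum n_{i,k} log pi_{i,k} (constant omitted).

    Cells with zero counts contribute nothing; a zero-probability cell
    carrying a positive count makes the configuration impossible and the
    function returns -inf rather than raising.
    """
    pi = genotype_probs(params, phase).reshape(-1)
    n = counts.n.reshape(-1)
    pos = n > 0
    if np.any(pi[pos] < _PROB_FLOOR):
        return -math.inf
    return float(np.sum(n[pos] * np.log(pi[pos])))


def merge_set(n: np.ndarray) -> np.ndarray:
    """Boolean mask of cells merged in the combined-cell likelihood.

    The merge set J joins the empty cells J0 with every cell attaining the
    minimum positive count (the argmin is set-valued; ties are all
    included, which keeps the rule deterministic and order-independent).
    Empty tables yield an all-False mask.
    """
    n = np.asarray(n, dtype=float).reshape(-1)
    mask = n == 0
    pos = n[n > 0]
    if pos.size:
        mask |= n == pos.min()
    else:
        mask[:] = False
    return mask


def loglik_star(counts: LocusPairCounts, params: LDParams, phase: SirePhase) -> float:
    """Combined-cell log-likelihood log LF*.

    Unobserved genotype cells and the least-observed cell(s) are pooled
    into a single multinomial cell, which damps the influence of
    near-zero haplotype frequencies in small families.  Outside the merge
    set the terms coincide with the plain log-likelihood.
    """
    if counts.N < 1:
        raise ValueError("loglik_star requires at least one observation")
    pi = genotype_probs(params, phase).reshape(-1)
    n = counts.n.reshape(-1)
    J = merge_set(n)
    out = ~J
    pos = out & (n > 0)
    if np.any(pi[pos] < _PROB_FLOOR):
        return -math.inf
    total = float(np.sum(n[pos] * np.log(pi[pos])))
    nJ = float(n[J].sum())
    if nJ > 0:
        piJ = float(pi[J].sum())
        if piJ < _PROB_FLOOR:
            return -math.inf
        total += nJ * math.log(piJ)
    return total
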