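"""Test helpers: independent oracles kept free of the code paths they check."""

from __future__ import annotations

import numpy as np

from hsrecomb.likelihood import (
    CELL_OF_COMBO16,
    COMBO_TO_CELL,
    SirePhase,
    ddam_bounds,
    ld_to_haplo,
    paternal_gamete_probs,
)


def grid_loglik(n9: np.ndarray, p1: float, p2: float, n_theta: int = 401, n_d: int = 401):
    """Dense log-likelihood surface over (theta, D_dam) at fixed (p1, p2).

    Independent of the EM path: probabilities are built directly from the
    gamete products on a lattice.  Returns (theta grid, D_dam grid, ll).
    """
    thetas = np.linspace(0.0, 1.0, n_theta)
    lo, hi = ddam_bounds(p1, p2)
    dds = np.linspace(lo, hi, n_d)
    pat = np.stack([(1 - thetas) / 2, thetas / 2, thetas / 2, (1 - thetas) / 2], axis=1)
    H = np.stack(
        [p1 * p2 + dds, p1 * (1 - p2) - dds, (1 - p1) * p2 - dds, (1 - p1) * (1 - p2) + dds],
        axis=1,
    )
    H = np.clip(H, 0.0, 1.0)
    W = np.einsum("tg,dm->tdgm", pat, H).reshape(n_theta, n_d, 16)
    pi = W @ COMBO_TO_CELL
    pos = n9 > 0
    ll = np.where(pos, n9 * np.log(np.maximum(pi, 1e-300)), 0.0).sum(axis=2)
    ll[np.any(pos & (pi < 1e-300), axis=2)] = -np.inf
    return thetas, dds, ll


def grid_local_maxima(ll: np.ndarray) -> np.ndarray:
    """Indices (t, d) of lattice points >= all eight neighbors."""
    p = np.pad(ll, 1, constant_values=-np.inf)
    c = p[1:-1, 1:-1]
    mask = np.ones_like(c, dtype=bool)
    for di in (-1, 0, 1):
        for dk in (-1, 0, 1):
            if di == 0 and dk == 0:
                continue
            mask &= c >= p[1 + di : p.shape[0] - 1 + di, 1 + dk : p.shape[1] - 1 + dk]
    return np.argwhere(mask & np.isfinite(c))


def random_count_table(rng: np.random.Generator, n_max: int = 50) -> tuple[np.ndarray, dict]:
    """Random small genotype table drawn from random valid parameters.

    Resamples until both loci have at least one homozygote (so the
    allele-frequency estimates are defined).  Returns the 3x3 table and the
    generating parameters.
    """
    while True:
        theta = rng.uniform(0.0, 1.0)
        p1, p2 = rng.uniform(0.1, 0.9, size=2)
        lo, hi = ddam_bounds(p1, p2)
        d_dam = rng.uniform(lo, hi)
        N = int(rng.integers(10, n_max + 1))
        pat = paternal_gamete_probs(theta, SirePhase.COUPLING)
        mat = ld_to_haplo(d_dam, p1, p2).as_array()
        c16 = rng.multinomial(N, np.outer(pat, mat).reshape(-1))
        t9 = np.zeros(9)
        np.add.at(t9, CELL_OF_COMBO16, c16)
        tab = t9.reshape(3, 3)
        m1, m2 = tab.sum(axis=1), tab.sum(axis=0)
        if m1[0] + m1[2] > 0 and m2[0] + m2[2] > 0:
            return tab, {"theta": theta, "d_dam": d_dam, "p1": p1, "p2": p2, "N": N}


def loglik_star_reference(n9: np.ndarray, pi9: np.ndarray) -> float:
    """Brute-force combined-cell log-likelihood from first principles.

    Enumerates the merge set literally (all zero-count cells plus every
    cell attaining the minimum positive count) without sharing code with
    the implementation under test.
    """
    n9 = np.asarray(n9, dtype=float).reshape(-1)
    pi9 = np.asarray(pi9, dtype=float).reshape(-1)
    positive = [c for c in range(9) if n9[c] > 0]
    if not positive:
        return 0.0
    mn = min(n9[c] for c in positive)
    J = [c for c in range(9) if n9[c] == 0 or n9[c] == mn]
    total = 0.0
    for c in range(9):
        if c not in J and n9[c] > 0:
            total += n9[c] * np.log(pi9[c])
    nJ = sum(n9[c] for c in J)
    if nJ > 0:
        total += nJ * np.log(sum(pi9[c] for c in J))
    return float(total)
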