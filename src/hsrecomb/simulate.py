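"""Synthetic half-sib genotype generation.

Two levels of machinery:

* Two-locus sampling (:func:`simulate_pair`) for validating the estimator —
  a double-heterozygous sire in known phase transmits gametes with
  recombination probability theta, the dam population contributes gametes
  with given allele frequencies and LD, and the two simulation studies
  (:func:`run_study_one`, :func:`run_study_two`) wrap it with the
  start-value strategies EMT0, EMT05 and EMDP.

* Multi-locus chromosomes (:func:`simulate_chromosome`) for exercising the
  misplacement scan end to end — paternal gametes follow a Markov
  recombination process over map intervals (no interference), dam gametes a
  first-order Markov chain with specified adjacent-pair LD whose
  between-pair LD decays multiplicatively with distance, and
  :func:`rearrange` plants misplacements by permuting the SNP-to-position
  assignment while the genotypes keep following the true order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .duality import emdp_batch
from .em import BOUNDARY_NUDGE, em_fit_batch
from .io import Dataset
from .likelihood import (
    CELL_OF_COMBO16,
    DomainError,
    LocusPairCounts,
    SirePhase,
    ddam_bounds,
    ld_to_haplo,
    paternal_gamete_probs,
)

__all__ = [
    "SimConfig",
    "SCENARIOS",
    "FREQ_SETTINGS",
    "simulate_pair",
    "simulate_pair_batch",
    "fit_strategies",
    "run_study_one",
    "run_study_two",
    "simulate_chromosome",
    "Move",
    "rearrange",
]

#: the three two-locus LD scenarios of the validation study
SCENARIOS = {
    "I": {"theta": 0.01, "d_dam": 0.05},  # small theta (D_sire = 0.245)
    "II": {"theta": 0.20, "d_dam": 0.05},  # medium theta (D_sire = 0.15)
    "III": {"theta": 0.40, "d_dam": 0.15},  # large theta (D_sire = 0.05)
}

#: maternal allele-frequency settings crossed with each scenario
FREQ_SETTINGS = {
    "a": (0.5, 0.5),
    "b": (0.4, 0.4),
    "c": (0.4, 0.6),
    "d": (0.8, 0.8),
}

STRATEGIES = ("EMT0", "EMT05", "EMDP")


@dataclass(frozen=True)
class SimConfig:
    """Two-locus simulation settings for one half-sib family."""

    n_offspring: int = 100
    theta: float = 0.01
    d_dam: float = 0.05
    p1: float = 0.5
    p2: float = 0.5
    phase: SirePhase = SirePhase.COUPLING
    n_replicates: int = 1
    seed: int | None = None

    def validate(self) -> "SimConfig":
        if not (0.0 <= self.theta <= 1.0):
            raise DomainError(f"theta={self.theta} outside [0, 1]")
        lo, hi = ddam_bounds(self.p1, self.p2)
        if not (lo <= self.d_dam <= hi):
            raise DomainError(
                f"D_dam={self.d_dam} outside [{lo}, {hi}] for "
                f"p1={self.p1}, p2={self.p2}"
            )
        return self


def simulate_pair(config: SimConfig, rng: np.random.Generator | None = None) -> LocusPairCounts:
    """Simulate one family's two-locus genotype counts, offspring by offspring.

    Each offspring receives a paternal gamete — one of the sire's two
    haplotypes at random, with the locus-2 allele swapped to the other
    haplotype with probability theta — and a maternal gamete drawn from the
    dam haplotype distribution.  Genotypes are the unordered allele pairs
    per locus.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    N = config.n_offspring
    if config.phase is SirePhase.COUPLING:
        hap_l1 = np.array([1, 0])  # haplotypes A-A / B-B (1 = allele A)
        hap_l2 = np.array([1, 0])
    else:
        hap_l1 = np.array([1, 0])  # haplotypes A-B / B-A
        hap_l2 = np.array([0, 1])
    strand = rng.integers(0, 2, size=N)
    recomb = rng.random(N) < config.theta
    pat1 = hap_l1[strand]
    pat2 = np.where(recomb, hap_l2[1 - strand], hap_l2[strand])
    mat_freqs = ld_to_haplo(config.d_dam, config.p1, config.p2).as_array()
    mat = rng.choice(4, size=N, p=mat_freqs)
    mat1 = np.array([1, 1, 0, 0])[mat]
    mat2 = np.array([1, 0, 1, 0])[mat]
    g1 = pat1 + mat1  # allele-A count at locus 1
    g2 = pat2 + mat2
    table = np.zeros((3, 3))
    np.add.at(table, (2 - g1, 2 - g2), 1)
    return LocusPairCounts(table)


def simulate_pair_batch(
    n_replicates: int,
    config: SimConfig,
    seed_seq: np.random.SeedSequence,
) -> np.ndarray:
    """Count tables for many replicates, shape (R, 3, 3).

    Each replicate uses its own generator spawned from ``seed_seq`` so that
    any single replicate can be reproduced independently.  Sampling draws
    the offspring total directly from the multinomial over the 16 paternal x
    maternal gamete combinations — distributionally identical to the
    per-offspring mechanics of :func:`simulate_pair`.
    """
    config.validate()
    pat = paternal_gamete_probs(config.theta, config.phase)
    mat = ld_to_haplo(config.d_dam, config.p1, config.p2).as_array()
    probs16 = np.outer(pat, mat).reshape(-1)
    out = np.zeros((n_replicates, 3, 3))
    for r, child in enumerate(seed_seq.spawn(n_replicates)):
        rng = np.random.default_rng(child)
        c16 = rng.multinomial(config.n_offspring, probs16)
        table = np.zeros(9)
        np.add.at(table, CELL_OF_COMBO16, c16)
        out[r] = table.reshape(3, 3)
    return out


def fit_strategies(
    counts: np.ndarray,
    p1_start: np.ndarray,
    p2_start: np.ndarray,
    *,
    strategies,
    tol: float,
    max_iter: int,
) -> dict[str, dict[str, np.ndarray]]:
    """Run the requested start-value strategies on a batch of count tables.

    EMT0 starts at (theta = 0, D_dam = 0); EMT05 at (theta = 0.5,
    D_dam = 0); EMDP runs the dual-start procedure and decides by the
    combined-cell log-likelihood only (the neighborhood rule needs a map,
    which a single simulated pair does not have).  EMT0 and the first EMDP
    run share their start, so the EMDP reuses that fit.
    """
    R = counts.shape[0]
    counts2 = np.zeros((R, 2, 3, 3))
    counts2[:, 0] = counts
    p1c = np.clip(p1_start, BOUNDARY_NUDGE, 1 - BOUNDARY_NUDGE)
    p2c = np.clip(p2_start, BOUNDARY_NUDGE, 1 - BOUNDARY_NUDGE)
    h0 = np.stack(
        [p1c * p2c, p1c * (1 - p2c), (1 - p1c) * p2c, (1 - p1c) * (1 - p2c)], axis=1
    )
    h0 = np.maximum(h0, BOUNDARY_NUDGE)
    h0 /= h0.sum(axis=1, keepdims=True)

    results: dict[str, dict[str, np.ndarray]] = {}
    need_dual = "EMDP" in strategies
    if "EMT0" in strategies or need_dual:
        if need_dual:
            dual = emdp_batch(counts2, p1_start, p2_start, tol=tol, max_iter=max_iter)
            emt0 = {
                "theta": dual["theta1"],
                "h": dual["h1"],
                "loglik_star": dual["loglik_star1"],
            }
        else:
            fit = em_fit_batch(
                counts2, np.full(R, BOUNDARY_NUDGE), h0, tol=tol, max_iter=max_iter
            )
            emt0 = {
                "theta": fit["theta"],
                "h": fit["h"],
                "loglik_star": fit["loglik_star"],
            }
        if "EMT0" in strategies:
            results["EMT0"] = emt0
        if need_dual:
            first_wins = ~dual["second_present"] | (
                dual["loglik_star1"] >= dual["loglik_star2"]
            )
            results["EMDP"] = {
                "theta": np.where(first_wins, dual["theta1"], dual["theta2"]),
                "h": np.where(first_wins[:, None], dual["h1"], dual["h2"]),
                "loglik_star": np.where(
                    first_wins, dual["loglik_star1"], dual["loglik_star2"]
                ),
                "first_wins": first_wins,
                "second_present": dual["second_present"],
            }
    if "EMT05" in strategies:
        fit = em_fit_batch(counts2, np.full(R, 0.5), h0, tol=tol, max_iter=max_iter)
        results["EMT05"] = {
            "theta": fit["theta"],
            "h": fit["h"],
            "loglik_star": fit["loglik_star"],
        }
    return results


def _summarize(res: dict[str, np.ndarray], theta_true: float, d_dam_true: float) -> dict:
    theta_hat = res["theta"]
    h = res["h"]
    p1e = h[:, 0] + h[:, 1]
    p2e = h[:, 0] + h[:, 2]
    d_hat = h[:, 0] - p1e * p2e
    err_t = theta_hat - theta_true
    err_d = d_hat - d_dam_true
    R = theta_hat.size
    out = {
        "bias_theta": float(err_t.mean()),
        "bias_ddam": float(err_d.mean()),
        "mse_theta": float((err_t**2).mean()),
        "mse_ddam": float((err_d**2).mean()),
        "se_bias_theta": float(err_t.std(ddof=1) / math.sqrt(R)),
        "se_bias_ddam": float(err_d.std(ddof=1) / math.sqrt(R)),
        "se_mse_theta": float((err_t**2).std(ddof=1) / math.sqrt(R)),
        "se_mse_ddam": float((err_d**2).std(ddof=1) / math.sqrt(R)),
    }
    if "first_wins" in res:
        out["frac_first_mode"] = float(res["first_wins"].mean())
    return out


def run_study_one(
    scenarios=("I", "II", "III"),
    freq_settings=("a", "b", "c", "d"),
    strategies=STRATEGIES,
    *,
    n_offspring: int = 100,
    n_replicates: int = 10_000,
    seed: int = 0,
    tol: float = 1e-10,
    max_iter: int = 5000,
) -> pd.DataFrame:
    """Bias/MSE study across LD scenarios, frequencies and start strategies.

    For every scenario x frequency cell, the same simulated replicates are
    analyzed with each strategy.  Returns one row per (scenario, frequency,
    strategy) with bias, MSE and their Monte-Carlo standard errors; EMDP
    rows also carry the fraction of replicates decided for the first
    (default-start) mode.
    """
    root = np.random.SeedSequence(seed)
    rows = []
    for scen in scenarios:
        pars = SCENARIOS[scen]
        for fl in freq_settings:
            p1, p2 = FREQ_SETTINGS[fl]
            cfg = SimConfig(
                n_offspring=n_offspring,
                theta=pars["theta"],
                d_dam=pars["d_dam"],
                p1=p1,
                p2=p2,
            )
            cell_seq = np.random.SeedSequence(
                entropy=root.entropy,
                spawn_key=(ord(scen[-1]), ord(fl), n_offspring),
            )
            counts = simulate_pair_batch(n_replicates, cfg, cell_seq)
            marg1 = counts.sum(axis=2)
            marg2 = counts.sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                p1_hat = marg1[:, 0] / (marg1[:, 0] + marg1[:, 2])
                p2_hat = marg2[:, 0] / (marg2[:, 0] + marg2[:, 2])
            p1_hat = np.where(np.isfinite(p1_hat), p1_hat, 0.5)
            p2_hat = np.where(np.isfinite(p2_hat), p2_hat, 0.5)
            fits = fit_strategies(
                counts,
                p1_hat,
                p2_hat,
                strategies=strategies,
                tol=tol,
                max_iter=max_iter,
            )
            for strat in strategies:
                row = {
                    "scenario": scen,
                    "freq": fl,
                    "p1": p1,
                    "p2": p2,
                    "theta": pars["theta"],
                    "d_dam": pars["d_dam"],
                    "strategy": strat,
                    "n_offspring": n_offspring,
                    "n_replicates": n_replicates,
                }
                row.update(_summarize(fits[strat], pars["theta"], pars["d_dam"]))
                rows.append(row)
    return pd.DataFrame(rows)


def run_study_two(
    *,
    d_dam: float = 0.05,
    p1: float = 0.5,
    n_offspring: int = 100,
    n_replicates: int = 1000,
    theta_grid=None,
    strategies=STRATEGIES,
    seed: int = 0,
    tol: float = 1e-10,
    max_iter: int = 5000,
) -> pd.DataFrame:
    """Mean estimate vs true theta over a fine grid (estimated-vs-simulated
    curves).

    theta runs from 0 to 0.5 in steps of 0.005; for each replicate p2 is
    drawn uniformly on [0.3, 0.7] and redrawn if (D_dam, p1, p2) would
    violate the LD bounds.  Returns one row per (theta, strategy) with the
    mean estimates across replicates.
    """
    if theta_grid is None:
        theta_grid = np.round(np.arange(0.0, 0.5 + 1e-9, 0.005), 3)
    root = np.random.SeedSequence(seed)
    rows = []
    for theta in theta_grid:
        grid_seq = np.random.SeedSequence(
            entropy=root.entropy, spawn_key=(int(round(theta * 1000)),)
        )
        rng = np.random.default_rng(grid_seq)
        counts = np.zeros((n_replicates, 3, 3))
        pat = paternal_gamete_probs(float(theta), SirePhase.COUPLING)
        for r in range(n_replicates):
            while True:
                p2 = rng.uniform(0.3, 0.7)
                lo, hi = ddam_bounds(p1, p2)
                if lo <= d_dam <= hi:
                    break
            mat = ld_to_haplo(d_dam, p1, p2).as_array()
            c16 = rng.multinomial(n_offspring, np.outer(pat, mat).reshape(-1))
            table = np.zeros(9)
            np.add.at(table, CELL_OF_COMBO16, c16)
            counts[r] = table.reshape(3, 3)
        marg1 = counts.sum(axis=2)
        marg2 = counts.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            p1_hat = marg1[:, 0] / (marg1[:, 0] + marg1[:, 2])
            p2_hat = marg2[:, 0] / (marg2[:, 0] + marg2[:, 2])
        p1_hat = np.where(np.isfinite(p1_hat), p1_hat, 0.5)
        p2_hat = np.where(np.isfinite(p2_hat), p2_hat, 0.5)
        fits = fit_strategies(
            counts, p1_hat, p2_hat, strategies=strategies, tol=tol, max_iter=max_iter
        )
        for strat in strategies:
            rows.append(
                {
                    "theta": float(theta),
                    "strategy": strat,
                    "mean_theta_hat": float(fits[strat]["theta"].mean()),
                    "mean_ddam_hat": float(
                        (
                            fits[strat]["h"][:, 0]
                            - (fits[strat]["h"][:, 0] + fits[strat]["h"][:, 1])
                            * (fits[strat]["h"][:, 0] + fits[strat]["h"][:, 2])
                        ).mean()
                    ),
                    "n_offspring": n_offspring,
                    "n_replicates": n_replicates,
                }
            )
    return pd.DataFrame(rows)


def _dam_gametes(
    rng: np.random.Generator,
    n: int,
    freqs: np.ndarray,
    adjacent_d: np.ndarray,
) -> np.ndarray:
    """First-order Markov dam gametes; (n, m) 0/1 allele matrix (1 = A).

    Adjacent loci k, k+1 have haplotype LD ``adjacent_d[k]``; LD between
    non-adjacent loci decays as the product of the adjacent correlations,
    which emulates the distance decay of LD in a random-mating population.
    """
    m = freqs.size
    for k in range(m - 1):
        lo, hi = ddam_bounds(freqs[k], freqs[k + 1])
        if not (lo <= adjacent_d[k] <= hi):
            raise DomainError(
                f"adjacent D_dam={adjacent_d[k]} between loci {k} and {k + 1} "
                f"outside [{lo}, {hi}]"
            )
    X = np.zeros((n, m), dtype=np.int8)
    X[:, 0] = rng.random(n) < freqs[0]
    for k in range(m - 1):
        pA = freqs[k + 1] + adjacent_d[k] / max(freqs[k], 1e-12)
        pB = freqs[k + 1] - adjacent_d[k] / max(1 - freqs[k], 1e-12)
        pnext = np.where(X[:, k] == 1, pA, pB)
        X[:, k + 1] = rng.random(n) < pnext
    return X


def simulate_chromosome(
    m: int,
    n_offspring: int,
    interval_theta,
    *,
    chrom: str = "1",
    allele_freqs=None,
    adjacent_d: float | np.ndarray = 0.05,
    sire: str = "S1",
    start_bp: int = 100_000,
    spacing_bp: int = 100_000,
    offspring_prefix: str = "O",
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> Dataset:
    """Simulate a half-sib family genotyped along one chromosome.

    Parameters
    ----------
    m, n_offspring : int
        Number of SNPs and offspring.
    interval_theta : float or (m-1,) array
        Recombination rate of each adjacent map interval.  Paternal gametes
        follow a Markov process over intervals (crossovers independent
        between intervals — no interference), so the pairwise rate between
        loci i < j composes as 0.5 (1 - prod_k (1 - 2 theta_k)).
    allele_freqs : None, float, (m,) array or ("uniform", lo, hi)
        Maternal A-allele frequencies; the tuple form draws them uniformly.
    adjacent_d : float or (m-1,) array
        Maternal LD between adjacent loci (see :func:`_dam_gametes`).
    sire
        The sire is double-heterozygous in coupling phase at every locus
        (haplotypes all-A / all-B), so every pair is informative.

    Returns a :class:`Dataset` whose map positions are evenly spaced.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    theta_iv = np.broadcast_to(np.asarray(interval_theta, dtype=float), (m - 1,)).copy()
    if np.any((theta_iv < 0) | (theta_iv > 0.5)):
        raise DomainError("interval theta values must lie in [0, 0.5]")
    if allele_freqs is None:
        freqs = np.full(m, 0.5)
    elif isinstance(allele_freqs, tuple) and allele_freqs[0] == "uniform":
        freqs = rng.uniform(allele_freqs[1], allele_freqs[2], size=m)
    else:
        freqs = np.broadcast_to(np.asarray(allele_freqs, dtype=float), (m,)).copy()
    adj = np.broadcast_to(np.asarray(adjacent_d, dtype=float), (m - 1,)).copy()
    # clip adjacent LD into the admissible range implied by the frequencies
    for k in range(m - 1):
        lo, hi = ddam_bounds(freqs[k], freqs[k + 1])
        adj[k] = min(max(adj[k], lo * 0.999), hi * 0.999)

    # paternal gametes: strand Markov chain over intervals
    strand = np.zeros((n_offspring, m), dtype=np.int8)
    strand[:, 0] = rng.integers(0, 2, size=n_offspring)
    cross = rng.random((n_offspring, m - 1)) < theta_iv
    strand[:, 1:] = strand[:, [0]] ^ np.cumsum(cross, axis=1) % 2
    pat = 1 - strand  # strand 0 = all-A haplotype

    mat = _dam_gametes(rng, n_offspring, freqs, adj)
    G = (pat + mat).astype(float)

    snps = [f"c{chrom}s{j + 1:04d}" for j in range(m)]
    pos = start_bp + spacing_bp * np.arange(m)
    offspring = [f"{offspring_prefix}{j + 1:04d}" for j in range(n_offspring)]
    genotypes = pd.DataFrame(G, index=offspring, columns=snps)
    snp_map = pd.DataFrame({"snp": snps, "chrom": chrom, "pos": pos})
    pedigree = pd.Series(sire, index=pd.Index(offspring, name="offspring"), name="sire")
    hap = pd.DataFrame({"hap1": "A", "hap2": "B"}, index=pd.Index(snps, name="snp"))
    return Dataset(genotypes, snp_map, pedigree, {sire: hap}).validate()


def merge_datasets(datasets: list[Dataset]) -> Dataset:
    """Concatenate per-chromosome datasets of the same offspring panel."""
    genotypes = pd.concat([d.genotypes for d in datasets], axis=1)
    snp_map = pd.concat([d.snp_map for d in datasets], ignore_index=True)
    pedigree = datasets[0].pedigree
    haps: dict[str, pd.DataFrame] = {}
    for d in datasets:
        for sire, hap in d.sire_haplotypes.items():
            haps[sire] = pd.concat([haps.get(sire, pd.DataFrame()), hap])
    return Dataset(genotypes, snp_map, pedigree, haps).validate()


@dataclass(frozen=True)
class Move:
    """Relocation of a block of SNPs in the map (misplacement planting).

    Indices are 1-based map positions within a chromosome, as in assembly
    tables.  The block of ``length`` SNPs starting at ``from_index`` on
    ``from_chrom`` is re-assigned to the slots starting at ``to_index`` on
    ``to_chrom``.  Genotypes stay attached to the SNPs; only the claimed
    positions change, which is exactly what an assembly error does.
    """

    from_chrom: str
    from_index: int
    to_chrom: str
    to_index: int
    length: int = 1


def rearrange(ds: Dataset, moves: list[Move]) -> Dataset:
    """Plant misplacements by permuting the SNP-to-slot assignment.

    The chromosome slot structure (chromosome labels and bp positions) is
    kept fixed; moves permute which SNP occupies which slot.  Returns a new
    Dataset whose genotype columns follow the new map order.
    """
    order: dict[str, list[str]] = {
        chrom: list(grp["snp"])
        for chrom, grp in ds.snp_map.groupby("chrom", sort=False)
    }
    slots: dict[str, np.ndarray] = {
        chrom: grp["pos"].to_numpy()
        for chrom, grp in ds.snp_map.groupby("chrom", sort=False)
    }
    for mv in moves:
        if mv.from_chrom not in order or mv.to_chrom not in order:
            raise ValueError(f"unknown chromosome in move {mv}")
        src = order[mv.from_chrom]
        if not (1 <= mv.from_index and mv.from_index + mv.length - 1 <= len(src)):
            raise ValueError(
                f"move source {mv.from_index}..{mv.from_index + mv.length - 1} "
                f"outside 1..{len(src)} on chromosome {mv.from_chrom}"
            )
        block = src[mv.from_index - 1 : mv.from_index - 1 + mv.length]
        del src[mv.from_index - 1 : mv.from_index - 1 + mv.length]
        dst = order[mv.to_chrom]
        if not (1 <= mv.to_index <= len(dst) + 1):
            raise ValueError(
                f"move target {mv.to_index} outside 1..{len(dst) + 1} "
                f"on chromosome {mv.to_chrom}"
            )
        dst[mv.to_index - 1 : mv.to_index - 1] = block

    rows = []
    for chrom, snps in order.items():
        npos = slots[chrom]
        if len(snps) != npos.size:
            # cross-chromosome moves change per-chromosome SNP counts;
            # re-space the slots evenly preserving the original span
            npos = np.linspace(npos.min(), npos.max(), len(snps)).round()
        for snp, p in zip(snps, npos):
            rows.append((snp, chrom, int(p)))
    snp_map = pd.DataFrame(rows, columns=["snp", "chrom", "pos"])
    genotypes = ds.genotypes[list(snp_map["snp"])]
    haps = {
        sire: hap.loc[list(snp_map["snp"])]
        for sire, hap in ds.sire_haplotypes.items()
    }
    return Dataset(genotypes, snp_map, ds.pedigree, haps).validate()
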