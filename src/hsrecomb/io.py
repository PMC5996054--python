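"""Dataset container, readers/writers and per-chromosome orchestration.

The native format is deliberately plain: four UTF-8 TSV files with '.'
decimal separator and "NA" for missing values.

``genotypes.tsv``
    offspring x SNP matrix of allele-A counts (0 = BB, 1 = AB, 2 = AA);
    first column ``id`` holds the offspring identifier.
``map.tsv``
    columns ``snp``, ``chrom``, ``pos`` (1-based base pairs), sorted by
    (chromosome, position); row order defines the map order.
``pedigree.tsv``
    columns ``offspring``, ``sire``.
``haplotypes.tsv``
    columns ``sire``, ``snp``, ``hap1``, ``hap2`` with alleles 'A'/'B';
    the two phased haplotypes of each sire (phasing is an input here, not
    something this package does).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .decision import (
    CRITICAL_RANGE,
    MIN_SPLINE_POINTS,
    fit_smoothing_curve,
)
from .duality import emdp_batch
from .likelihood import SirePhase
from .scan import ThetaMatrix

logger = logging.getLogger("hsrecomb")

__all__ = [
    "Dataset",
    "EstimateConfig",
    "load_dataset",
    "write_dataset",
    "informative_pairs",
    "estimate_chromosome",
    "write_pairs",
    "read_pairs",
    "write_matrix",
    "read_matrix",
]


@dataclass
class Dataset:
    """In-memory half-sib dataset.

    Attributes
    ----------
    genotypes : DataFrame (offspring x SNPs)
        Allele-A counts 0/1/2, NaN for missing; columns follow map order.
    snp_map : DataFrame
        Columns snp, chrom, pos; row order is the map order.
    pedigree : Series
        offspring id -> sire id.
    sire_haplotypes : dict
        sire id -> DataFrame indexed by snp with columns hap1, hap2
        ('A'/'B'), aligned with the map.
    """

    genotypes: pd.DataFrame
    snp_map: pd.DataFrame
    pedigree: pd.Series
    sire_haplotypes: dict[str, pd.DataFrame]

    def validate(self) -> "Dataset":
        snps = list(self.snp_map["snp"])
        ncol, nmap = len(self.genotypes.columns), len(snps)
        if ncol != nmap:
            raise ValueError(
                f"genotype matrix has {ncol} columns but the map lists {nmap} SNPs"
            )
        if list(self.genotypes.columns) != snps:
            raise ValueError("genotype columns are not aligned with the map order")
        for chrom, grp in self.snp_map.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) < 0):
                bad = int(np.flatnonzero(np.diff(pos) < 0)[0])
                raise ValueError(
                    f"map is not sorted by position on chromosome {chrom} "
                    f"(row {grp.index[bad + 1]})"
                )
        for off in self.genotypes.index:
            if off not in self.pedigree.index:
                raise ValueError(f"offspring {off!r} missing from the pedigree")
        for off, sire in self.pedigree.items():
            if off in self.genotypes.index and sire not in self.sire_haplotypes:
                raise ValueError(f"unknown sire {sire!r} for offspring {off!r}")
        for sire, hap in self.sire_haplotypes.items():
            missing = set(snps) - set(hap.index)
            if missing:
                raise ValueError(
                    f"sire {sire!r} haplotypes lack {len(missing)} mapped SNPs "
                    f"(e.g. {sorted(missing)[:3]})"
                )
        return self

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.snp_map["chrom"]))

    def families(self) -> dict[str, list[str]]:
        """sire id -> list of genotyped offspring ids."""
        fams: dict[str, list[str]] = {}
        for off in self.genotypes.index:
            fams.setdefault(self.pedigree[off], []).append(off)
        return fams


def write_dataset(ds: Dataset, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    g = ds.genotypes.copy()
    g.insert(0, "id", g.index)
    g.to_csv(d / "genotypes.tsv", sep="\t", index=False, na_rep="NA")
    ds.snp_map.to_csv(d / "map.tsv", sep="\t", index=False)
    ped = ds.pedigree.rename_axis("offspring").rename("sire").reset_index()
    ped.to_csv(d / "pedigree.tsv", sep="\t", index=False)
    rows = []
    for sire, hap in ds.sire_haplotypes.items():
        for snp, r in hap.iterrows():
            rows.append((sire, snp, r["hap1"], r["hap2"]))
    pd.DataFrame(rows, columns=["sire", "snp", "hap1", "hap2"]).to_csv(
        d / "haplotypes.tsv", sep="\t", index=False
    )


def load_dataset(directory, min_family_size: int = 30) -> Dataset:
    """Read and validate a dataset directory.

    Families with fewer than ``min_family_size`` genotyped offspring are
    dropped with a logged notice (small families cannot be phased reliably
    and contribute little information).
    """
    d = Path(directory)
    geno = pd.read_csv(d / "genotypes.tsv", sep="\t", na_values="NA")
    geno = geno.set_index("id")
    geno.index = geno.index.astype(str).rename(None)
    geno = geno.astype(float)
    snp_map = pd.read_csv(d / "map.tsv", sep="\t", dtype={"snp": str, "chrom": str})
    ped_df = pd.read_csv(d / "pedigree.tsv", sep="\t", dtype=str)
    pedigree = ped_df.set_index("offspring")["sire"]
    hap_df = pd.read_csv(d / "haplotypes.tsv", sep="\t", dtype=str)
    sire_haplotypes = {
        sire: grp.set_index("snp")[["hap1", "hap2"]]
        for sire, grp in hap_df.groupby("sire", sort=False)
    }

    ds = Dataset(geno, snp_map, pedigree, sire_haplotypes).validate()

    sizes = ds.genotypes.groupby(ds.pedigree.reindex(ds.genotypes.index)).size()
    small = sizes[sizes < min_family_size]
    if len(small):
        drop_off = [
            off
            for off in ds.genotypes.index
            if ds.pedigree[off] in set(small.index)
        ]
        logger.info(
            "dropping %d famil%s below the minimum size of %d: %s",
            len(small),
            "y" if len(small) == 1 else "ies",
            min_family_size,
            ", ".join(f"{s} (n={n})" for s, n in small.items()),
        )
        ds.genotypes = ds.genotypes.drop(index=drop_off)
    return ds


def _chrom_arrays(ds: Dataset, chrom: str):
    """Per-chromosome views: SNP ids, positions, genotype matrix, sire
    haplotype allele arrays (1 = A)."""
    sel = ds.snp_map[ds.snp_map["chrom"] == chrom]
    if sel.empty:
        raise ValueError(f"chromosome {chrom!r} not present in the map")
    snps = list(sel["snp"])
    pos = sel["pos"].to_numpy(dtype=float)
    G = ds.genotypes[snps].to_numpy(dtype=float)
    haps = {}
    for sire, hap in ds.sire_haplotypes.items():
        sub = hap.loc[snps]
        a1 = (sub["hap1"].to_numpy() == "A").astype(int)
        a2 = (sub["hap2"].to_numpy() == "A").astype(int)
        haps[sire] = (a1, a2)
    return snps, pos, G, haps


def informative_pairs(ds: Dataset, chrom: str):
    """Iterate over informative locus pairs of one chromosome.

    Yields (i, k, phases) with i < k map indices (0-based) and ``phases`` a
    dict sire -> SirePhase covering every family whose sire is heterozygous
    at *both* loci.  Pairs without any such family are not yielded: with no
    double-heterozygous sire, recombination between the loci is unobservable.
    """
    snps, _, _, haps = _chrom_arrays(ds, chrom)
    fams = ds.families()
    m = len(snps)
    sires = list(fams)
    het = {s: haps[s][0] != haps[s][1] for s in sires}
    for i in range(m):
        for k in range(i + 1, m):
            phases = {}
            for s in sires:
                if het[s][i] and het[s][k]:
                    a1, _ = haps[s]
                    phases[s] = (
                        SirePhase.COUPLING if a1[i] == a1[k] else SirePhase.REPULSION
                    )
            if phases:
                yield i, k, phases


@dataclass
class EstimateConfig:
    """Tuning knobs for chromosome-wide pair estimation."""

    tol: float = 1e-10
    max_iter: int = 5000
    theta_max: float = 1.0
    critical_range: tuple[float, float] = CRITICAL_RANGE
    spline_df: float = 5.0
    min_spline_points: int = MIN_SPLINE_POINTS
    chunk_size: int = 50_000


def _pair_count_blocks(G: np.ndarray) -> np.ndarray:
    """All-pairs 3x3 genotype count tables via a one-hot cross product.

    Returns C of shape (3m, 3m) where the (i, k) pair table is
    ``C[3i:3i+3, 3k:3k+3]`` with rows/cols ordered AA, AB, BB.  Offspring
    missing a genotype at either locus drop out of that pair only.
    """
    N, m = G.shape
    E = np.zeros((N, m, 3))
    valid = np.isfinite(G)
    rows = np.repeat(np.arange(N), m)[valid.ravel()]
    cols = np.tile(np.arange(m), N)[valid.ravel()]
    cells = (2 - G[valid]).astype(int)
    E[rows, cols, cells] = 1.0
    T = E.reshape(N, 3 * m)
    return T.T @ T


def estimate_chromosome(
    ds: Dataset, chrom: str, config: EstimateConfig | None = None
) -> tuple[pd.DataFrame, ThetaMatrix]:
    """Estimate (theta, D_dam) for every informative pair of a chromosome.

    For each pair, family counts are pooled by sire phase, maternal allele
    frequencies are estimated from the pooled homozygote marginals, the
    dual-start EM produces one or two proposals, and the decision process
    picks the final estimate — likelihood comparison first, then the
    smoothing-spline rule for pairs with both frequencies in the critical
    range (those are decided in a second pass so every spline is built from
    already-final estimates).

    Returns the pair table (one row per informative pair; non-estimable
    pairs keep NaN estimates) and the symmetric theta matrix.
    """
    cfg = config or EstimateConfig()
    snps, pos, G, haps = _chrom_arrays(ds, chrom)
    m = len(snps)
    fams = ds.families()
    sires = list(fams)

    # per-family all-pairs count blocks
    blocks = {}
    for s in sires:
        idx = [off for off in fams[s]]
        blocks[s] = _pair_count_blocks(ds.genotypes.loc[idx, snps].to_numpy(float))
    het = {s: haps[s][0] != haps[s][1] for s in sires}

    pair_i, pair_k, counts_list, nfam_list = [], [], [], []
    for i in range(m):
        for k in range(i + 1, m):
            c2 = None
            nf = 0
            for s in sires:
                if not (het[s][i] and het[s][k]):
                    continue
                if c2 is None:
                    c2 = np.zeros((2, 3, 3))
                a1, _ = haps[s]
                phase = 0 if a1[i] == a1[k] else 1
                c2[phase] += blocks[s][3 * i : 3 * i + 3, 3 * k : 3 * k + 3]
                nf += 1
            if c2 is not None:
                pair_i.append(i)
                pair_k.append(k)
                counts_list.append(c2)
                nfam_list.append(nf)

    if not counts_list:
        warnings.warn(f"no informative pairs on chromosome {chrom}", stacklevel=2)
        empty = pd.DataFrame(
            columns=[
                "chrom", "snp_i", "snp_k", "bp_i", "bp_k", "theta_hat",
                "D_dam_hat", "p1_hat", "p2_hat", "r2", "loglik_star",
                "decision", "mode", "n_families", "N",
            ]
        )
        return empty, ThetaMatrix.empty(chrom, snps, pos)

    counts2 = np.stack(counts_list)
    pair_i = np.array(pair_i)
    pair_k = np.array(pair_k)
    n_families = np.array(nfam_list)
    R = counts2.shape[0]

    # pooled maternal allele-frequency estimates from homozygote marginals
    marg1 = counts2.sum(axis=(1, 3))  # (R, 3) locus-1 genotype counts
    marg2 = counts2.sum(axis=(1, 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        p1_hat = marg1[:, 0] / (marg1[:, 0] + marg1[:, 2])
        p2_hat = marg2[:, 0] / (marg2[:, 0] + marg2[:, 2])
    estimable = np.isfinite(p1_hat) & np.isfinite(p2_hat) & (counts2.sum(axis=(1, 2, 3)) >= 1)
    n_skipped = int(R - estimable.sum())
    if n_skipped:
        logger.info(
            "chromosome %s: %d pairs skipped (undefined allele frequency)",
            chrom,
            n_skipped,
        )

    theta_fin = np.full(R, np.nan)
    ddam_fin = np.full(R, np.nan)
    lls_fin = np.full(R, np.nan)
    mode_fin = np.full(R, "", dtype=object)
    decision_fin = np.full(R, "non_estimable", dtype=object)
    p1_fin = np.full(R, np.nan)
    p2_fin = np.full(R, np.nan)

    est_idx = np.flatnonzero(estimable)
    res: dict[str, np.ndarray] = {}
    for start in range(0, est_idx.size, cfg.chunk_size):
        sub = est_idx[start : start + cfg.chunk_size]
        out = emdp_batch(
            counts2[sub],
            p1_hat[sub],
            p2_hat[sub],
            tol=cfg.tol,
            max_iter=cfg.max_iter,
            theta_max=cfg.theta_max,
        )
        for key, val in out.items():
            res.setdefault(key, []).append(val)
    res = {k: np.concatenate(v) for k, v in res.items()}

    def _mode_fields(j_local: np.ndarray, second: np.ndarray):
        """Final estimate fields for local rows, given which mode wins."""
        th = np.where(second, res["theta2"][j_local], res["theta1"][j_local])
        h = np.where(
            second[:, None], res["h2"][j_local], res["h1"][j_local]
        )
        lls = np.where(
            second, res["loglik_star2"][j_local], res["loglik_star1"][j_local]
        )
        p1e = h[:, 0] + h[:, 1]
        p2e = h[:, 0] + h[:, 2]
        dd = h[:, 0] - p1e * p2e
        return th, dd, lls, p1e, p2e

    crit_lo, crit_hi = cfg.critical_range
    critical = (
        (p1_hat[est_idx] >= crit_lo)
        & (p1_hat[est_idx] <= crit_hi)
        & (p2_hat[est_idx] >= crit_lo)
        & (p2_hat[est_idx] <= crit_hi)
    )
    second_present = res["second_present"]

    # pass 1: likelihood decision for non-critical pairs (and pairs where
    # only one proposal exists, which need no decision at all)
    pass1 = ~critical | ~second_present
    loc1 = np.flatnonzero(pass1)
    second_wins = second_present[loc1] & (
        res["loglik_star2"][loc1] > res["loglik_star1"][loc1]
    )
    th, dd, lls, p1e, p2e = _mode_fields(loc1, second_wins)
    g = est_idx[loc1]
    theta_fin[g] = th
    ddam_fin[g] = dd
    lls_fin[g] = lls
    p1_fin[g] = p1e
    p2_fin[g] = p2e
    mode_fin[g] = np.where(second_wins, "second", "first")
    decision_fin[g] = np.where(second_present[loc1], "loglik", "unimodal")

    tm = ThetaMatrix.empty(chrom, snps, pos)
    mat = tm.matrix
    mat[pair_i[g], pair_k[g]] = th
    mat[pair_k[g], pair_i[g]] = th

    # pass 2: spline decision for critical pairs, built from decided mates
    loc2 = np.flatnonzero(critical & second_present)
    rel_pos = pos / pos.max()
    curves: dict[int, object] = {}
    n_spline = 0
    for j in loc2:
        gj = est_idx[j]
        i, k = int(pair_i[gj]), int(pair_k[gj])
        curve = curves.get(i, None)
        if i not in curves:
            mates = np.isfinite(mat[i])
            try:
                curve = fit_smoothing_curve(
                    rel_pos[mates],
                    mat[i][mates],
                    df=cfg.spline_df,
                    min_points=cfg.min_spline_points,
                )
            except ValueError:
                curve = None
            curves[i] = curve
        curve = curves[i]
        if curve is None:
            warnings.warn(
                f"too few decided mates of SNP index {i} on {chrom} for a "
                f"spline; falling back to the likelihood comparison",
                stacklevel=2,
            )
            second = bool(res["loglik_star2"][j] > res["loglik_star1"][j])
            decision_fin[gj] = "loglik"
        else:
            target = float(curve(rel_pos[k]))
            d1 = (res["theta1"][j] - target) ** 2
            d2 = (res["theta2"][j] - target) ** 2
            second = bool(d2 < d1)
            decision_fin[gj] = "spline"
            n_spline += 1
        sec = np.array([second])
        th, dd, lls, p1e, p2e = _mode_fields(np.array([j]), sec)
        theta_fin[gj] = th[0]
        ddam_fin[gj] = dd[0]
        lls_fin[gj] = lls[0]
        p1_fin[gj] = p1e[0]
        p2_fin[gj] = p2e[0]
        mode_fin[gj] = "second" if second else "first"
        mat[i, k] = mat[k, i] = th[0]

    if loc2.size:
        logger.info(
            "chromosome %s: %d critical pairs, %d decided by spline",
            chrom,
            loc2.size,
            n_spline,
        )

    with np.errstate(invalid="ignore", divide="ignore"):
        denom = p1_fin * (1 - p1_fin) * p2_fin * (1 - p2_fin)
        r2 = np.where(denom > 0, ddam_fin**2 / np.where(denom > 0, denom, 1.0), np.nan)

    pairs = pd.DataFrame(
        {
            "chrom": chrom,
            "snp_i": [snps[i] for i in pair_i],
            "snp_k": [snps[k] for k in pair_k],
            "bp_i": pos[pair_i],
            "bp_k": pos[pair_k],
            "theta_hat": theta_fin,
            "D_dam_hat": ddam_fin,
            "p1_hat": p1_fin,
            "p2_hat": p2_fin,
            "r2": r2,
            "loglik_star": lls_fin,
            "decision": decision_fin,
            "mode": mode_fin,
            "n_families": n_families,
            "N": counts2.sum(axis=(1, 2, 3)),
        }
    )
    return pairs, tm


def write_pairs(pairs: pd.DataFrame, path) -> None:
    pairs.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_pairs(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values="NA", dtype={"chrom": str})


def write_matrix(tm: ThetaMatrix, path) -> None:
    df = pd.DataFrame(tm.matrix, index=tm.snp_ids, columns=tm.snp_ids)
    df.insert(0, "pos", tm.positions)
    df.rename_axis("snp").to_csv(path, sep="\t", na_rep="NA")


def read_matrix(path, chrom: str) -> ThetaMatrix:
    df = pd.read_csv(path, sep="\t", na_values="NA", index_col="snp")
    pos = df.pop("pos").to_numpy(dtype=float)
    snps = [str(s) for s in df.index]
    return ThetaMatrix(chrom, snps, pos, df.to_numpy(dtype=float))
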