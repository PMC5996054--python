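"""Window statistics over the pairwise recombination-rate matrix and
flagging of putatively misplaced SNPs.

A SNP that truly belongs elsewhere shows unusually *high* recombination
estimates to the markers around its assigned position and can show
unusually *low* estimates to markers at the chromosome end most distant
from it.  Two per-SNP window means capture this: theta_H averages the
estimates to the s nearest markers (ahead of the SNP, or behind it near the
chromosome end) and theta_L averages the estimates to the s markers at the
far chromosome end.  Genome-wide quantiles of the two statistics (99% for
theta_H, 1% for theta_L) serve as thresholds; SNPs beyond a threshold are
candidates, consecutive candidates form clusters, and non-informative SNPs
enclosed in a cluster are declared candidates as well.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ThetaMatrix",
    "theta_H",
    "theta_L",
    "window_stats",
    "genome_thresholds",
    "flag_candidates",
    "DEFAULT_WINDOW",
]

#: number of markers per window; 30 keeps the window local enough to catch
#: within-chromosome moves (very large windows only see cross-chromosome ones)
DEFAULT_WINDOW = 30


@dataclass
class ThetaMatrix:
    """Per-chromosome symmetric store of pairwise theta estimates.

    ``matrix[i, j]`` is the estimate between the i-th and j-th SNP in map
    order (0-based), NaN where the pair was non-informative; the diagonal
    is NaN by construction.
    """

    chrom: str
    snp_ids: list[str]
    positions: np.ndarray
    matrix: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        m = len(self.snp_ids)
        if self.matrix.shape != (m, m):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match {m} SNPs"
            )

    @property
    def m(self) -> int:
        return len(self.snp_ids)

    @classmethod
    def empty(cls, chrom: str, snp_ids, positions) -> "ThetaMatrix":
        m = len(snp_ids)
        mat = np.full((m, m), np.nan)
        return cls(chrom, list(snp_ids), np.asarray(positions, dtype=float), mat)

    def set_pair(self, i: int, k: int, value: float) -> None:
        self.matrix[i, k] = value
        self.matrix[k, i] = value


def _window_mean(values: np.ndarray, min_avail: int) -> float:
    avail = np.isfinite(values)
    if avail.sum() < min_avail:
        return math.nan
    return float(values[avail].mean())


def theta_H(matrix: np.ndarray, i: int, s: int, min_avail: int | None = None) -> float:
    """Mean recombination estimate from SNP ``i`` to its s nearest markers.

    ``i`` is 0-based.  With 1-based index I = i + 1 the window is
    J = I+1 .. I+s when I < m - s and J = I-s .. I-1 otherwise, clipped to
    the chromosome.  Non-informative (missing) pairs are excluded from the
    mean; if fewer than ``min_avail`` (default ceil(s/2)) entries are
    available the statistic is undefined (NaN).
    """
    m = matrix.shape[0]
    if not (0 <= i < m):
        raise IndexError(f"SNP index {i} outside 0..{m - 1}")
    if s < 1:
        raise ValueError("window size s must be >= 1")
    if min_avail is None:
        min_avail = math.ceil(s / 2)
    if i + 1 < m - s:  # 1-based: I < m - s
        j = np.arange(i + 1, min(i + s, m - 1) + 1)
    else:
        j = np.arange(max(i - s, 0), i)
    if j.size == 0:
        return math.nan
    return _window_mean(matrix[i, j], min_avail)


def theta_L(matrix: np.ndarray, i: int, s: int, min_avail: int | None = None) -> float:
    """Mean recombination estimate from SNP ``i`` to the far chromosome end.

    With 1-based index I = i + 1: the window is the last s markers when
    I < m/2 and the first s markers when I >= m/2.  The SNP itself is
    excluded if the window overlaps it.  Missing pairs are excluded; fewer
    than ``min_avail`` available entries give NaN.
    """
    m = matrix.shape[0]
    if not (0 <= i < m):
        raise IndexError(f"SNP index {i} outside 0..{m - 1}")
    if s < 1:
        raise ValueError("window size s must be >= 1")
    if min_avail is None:
        min_avail = math.ceil(s / 2)
    if i + 1 < m / 2:  # 1-based: I < m/2
        j = np.arange(max(m - s, 0), m)
    else:
        j = np.arange(0, min(s, m))
    j = j[j != i]
    if j.size == 0:
        return math.nan
    return _window_mean(matrix[i, j], min_avail)


def window_stats(
    tm: ThetaMatrix, s: int = DEFAULT_WINDOW, min_avail: int | None = None
) -> pd.DataFrame:
    """Both window statistics for every SNP of one chromosome.

    Returns a DataFrame with columns snp, chrom, index (0-based map index),
    pos, theta_H, theta_L, n_H, n_L, informative.  A SNP is informative if
    it has at least one finite pairwise estimate.
    """
    m = tm.m
    if min_avail is None:
        min_avail = math.ceil(s / 2)
    rows = []
    for i in range(m):
        row = tm.matrix[i]
        rows.append(
            {
                "snp": tm.snp_ids[i],
                "chrom": tm.chrom,
                "index": i,
                "pos": tm.positions[i],
                "theta_H": theta_H(tm.matrix, i, s, min_avail),
                "theta_L": theta_L(tm.matrix, i, s, min_avail),
                "informative": bool(np.isfinite(row).any()),
            }
        )
    return pd.DataFrame(rows)


def genome_thresholds(
    stats: pd.DataFrame, q_high: float = 0.99, q_low: float = 0.01
) -> tuple[float, float]:
    """Genome-wide thresholds (tH, tL) from the pooled window statistics.

    tH is the ``q_high`` quantile of all theta_H values and tL the
    ``q_low`` quantile of all theta_L values, with linear interpolation
    between order statistics (pinned so results are reproducible across
    environments).
    """
    th = stats["theta_H"].to_numpy(dtype=float)
    tl = stats["theta_L"].to_numpy(dtype=float)
    if not np.isfinite(th).any() or not np.isfinite(tl).any():
        raise ValueError("no defined window statistics to take quantiles of")
    tH = float(np.nanquantile(th, q_high, method="linear"))
    tL = float(np.nanquantile(tl, q_low, method="linear"))
    return tH, tL


def flag_candidates(
    stats: pd.DataFrame, thresholds: tuple[float, float]
) -> pd.DataFrame:
    """Flag misplacement candidates and group them into clusters.

    A SNP is a candidate iff its theta_H lies strictly above tH or its
    theta_L strictly below tL.  Within each chromosome, maximal runs of
    consecutive map indices are merged into clusters; non-informative SNPs
    lying strictly inside a flagged run are declared candidates too (reason
    'enclosed').  Returns the candidate table with columns of ``stats``
    plus ``reason`` and ``cluster``.
    """
    tH, tL = thresholds
    out_frames = []
    cluster_id = 0
    for chrom, grp in stats.groupby("chrom", sort=False):
        grp = grp.sort_values("index")
        high = grp["theta_H"].to_numpy() > tH
        low = grp["theta_L"].to_numpy() < tL
        flagged = high | low
        informative = grp["informative"].to_numpy(dtype=bool)
        idx = grp["index"].to_numpy()

        # enclose non-informative SNPs sitting strictly inside a flagged run
        enclosed = np.zeros(len(grp), dtype=bool)
        fl = np.flatnonzero(flagged)
        for a, b in zip(fl[:-1], fl[1:]):
            if b - a > 1 and idx[b] - idx[a] == b - a:
                gap = slice(a + 1, b)
                if np.all(~informative[gap]):
                    enclosed[gap] = True

        member = flagged | enclosed
        if not member.any():
            continue
        sel = grp.loc[member].copy()
        reasons = []
        for hi_f, lo_f, en_f in zip(high[member], low[member], enclosed[member]):
            if en_f:
                reasons.append("enclosed")
            elif hi_f and lo_f:
                reasons.append("high_H+low_L")
            elif hi_f:
                reasons.append("high_H")
            else:
                reasons.append("low_L")
        sel["reason"] = reasons

        # maximal runs of consecutive map indices -> clusters
        sel_idx = sel["index"].to_numpy()
        breaks = np.flatnonzero(np.diff(sel_idx) > 1)
        labels = np.zeros(len(sel), dtype=int)
        for b in breaks:
            labels[b + 1 :] += 1
        sel["cluster"] = labels + cluster_id
        cluster_id += labels.max() + 1 if len(labels) else 0
        out_frames.append(sel)

    if not out_frames:
        cols = list(stats.columns) + ["reason", "cluster"]
        return pd.DataFrame(columns=cols)
    return pd.concat(out_frames, ignore_index=True)
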