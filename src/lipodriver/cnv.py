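"""Somatic copy-number estimation from paired tumor/normal binned depth.

The estimator anchors absolute copies at diploid autosomes by median
normalization of both profiles (no purity/ploidy correction; sex
chromosomes are excluded from the medians):

    copies_i = 2 * (t_i / median(t)) / (n_i / median(n))

Segmentation is recursive binary splitting: at each node the split
maximizing the absolute mean difference between flanks is accepted when a
permutation test on that statistic is significant and both flanks hold at
least ``min_bins`` bins. Focal amplifications are segments whose copies
exceed diploid by more than a threshold and whose length stays below a
focality cap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

SEX_CHROMS = {"chrX", "chrY", "X", "Y"}


def _check_grids(tumor: pd.DataFrame, normal: pd.DataFrame) -> None:
    if len(tumor) != len(normal):
        raise ValueError(f"bin grids differ in length: {len(tumor)} vs {len(normal)}")
    for col in ("chrom", "start", "end"):
        neq = tumor[col].to_numpy() != normal[col].to_numpy()
        if neq.any():
            i = int(np.argmax(neq))
            raise ValueError(
                "tumor/normal bin grids disagree at bin "
                f"{i}: {tumor.iloc[i][['chrom', 'start', 'end']].tolist()} vs "
                f"{normal.iloc[i][['chrom', 'start', 'end']].tolist()}")


def coverage_to_copy(tumor: pd.DataFrame, normal: pd.DataFrame) -> pd.DataFrame:
    """Per-bin absolute copy estimates (diploid = 2) from paired depths.

    Bins with zero normal depth are masked (``copies`` = NaN), not zeroed.
    Scale-invariant in each profile's overall depth.
    """
    _check_grids(tumor, normal)
    auto = ~tumor["chrom"].isin(SEX_CHROMS).to_numpy()
    t = tumor["depth"].to_numpy(dtype=float)
    n = normal["depth"].to_numpy(dtype=float)
    med_t = np.median(t[auto])
    med_n = np.median(n[auto])
    if med_n <= 0:
        raise ValueError("normal median depth is zero; profile unusable")
    if med_t <= 0:
        raise ValueError("tumor median depth is zero; profile unusable")
    with np.errstate(divide="ignore", invalid="ignore"):
        copies = 2.0 * (t / med_t) / (n / med_n)
    copies[n == 0] = np.nan
    out = tumor[["chrom", "start", "end"]].copy()
    out["copies"] = copies
    return out


def _window_lengths(n: int, min_bins: int, ratio: float = 1.2) -> list[int]:
    """Geometric grid of candidate window lengths in [min_bins, n - min_bins].

    The same grid is used for the observed scan and for every
    permutation, so the permutation test stays valid; the grid merely
    coarsens which change-point pairs are considered in one pass (the
    recursion refines boundaries afterwards). Lengths up to 20 bins are
    enumerated exhaustively — a focal event whose width misses the grid
    gets truncated by one or two bins, and the stray outlier bins then
    contaminate the permutation null of the child nodes — with a
    geometric tail (ratio 1.2) beyond.
    """
    lengths = list(range(min_bins, min(20, n - min_bins) + 1))
    length = lengths[-1] if lengths else min_bins
    while True:
        length = max(length + 1, int(round(length * ratio)))
        if length > n - min_bins:
            break
        lengths.append(length)
    return lengths


def _window_scan(cs: np.ndarray, n: int, min_bins: int,
                 lengths: list[int]) -> tuple[tuple[int, int], float] | tuple[None, float]:
    """Best window [i, j) of a single profile given its 0-prefixed cumsum.

    Statistic: |mean_in − mean_out| · sqrt(L·(n−L)/n) maximized over the
    length grid and all placements whose arms are empty or >= min_bins.
    Ties break on the leftmost, shortest window.
    """
    best_stat = -1.0
    best = None
    total = cs[-1]
    for L in lengths:
        i = np.arange(0, n - L + 1)
        left_ok = (i == 0) | (i >= min_bins)
        right = n - L - i
        right_ok = (right == 0) | (right >= min_bins)
        valid = left_ok & right_ok
        if not valid.any():
            continue
        win = cs[i + L] - cs[i]
        stat = np.abs(win / L - (total - win) / (n - L)) * np.sqrt(L * (n - L) / n)
        stat[~valid] = -np.inf
        k = int(np.argmax(stat))
        if stat[k] > best_stat:
            best_stat = float(stat[k])
            best = (int(i[k]), int(i[k]) + L)
    return best, best_stat


def _perm_pvalue(x: np.ndarray, observed: float, min_bins: int,
                 lengths: list[int], n_perm: int, alpha: float,
                 rng: np.random.Generator) -> float:
    """Permutation p-value of the max-window statistic, with early rejection.

    Permutations run in chunks; once the exceedance count alone already
    forces p >= alpha the remaining chunks cannot change the accept/reject
    decision and are skipped (the returned p is then a conservative
    partial estimate, used only for its comparison against alpha).
    """
    n = len(x)
    count = 0
    done = 0
    chunk = 250
    reject_at = alpha * (n_perm + 1) - 1  # count > this => p >= alpha
    while done < n_perm:
        m = min(chunk, n_perm - done)
        perm = rng.permuted(np.tile(x, (m, 1)), axis=1)
        cs = np.concatenate([np.zeros((m, 1)), np.cumsum(perm, axis=1)], axis=1)
        total = cs[:, -1:]
        max_stat = np.full(m, -np.inf)
        for L in lengths:
            i = np.arange(0, n - L + 1)
            valid = ((i == 0) | (i >= min_bins)) & \
                    ((n - L - i == 0) | (n - L - i >= min_bins))
            if not valid.any():
                continue
            idx = i[valid]
            win = cs[:, idx + L] - cs[:, idx]
            stat = np.abs(win / L - (total - win) / (n - L)) * np.sqrt(L * (n - L) / n)
            np.maximum(max_stat, stat.max(axis=1), out=max_stat)
        count += int(np.sum(max_stat >= observed))
        done += m
        if count > reject_at:
            return (count + 1) / (done + 1)
    return (count + 1) / (n_perm + 1)


def segment_copy_number(copies: pd.DataFrame, p_thresh: float = 0.01,
                        n_perm: int = 1000, min_bins: int = 3,
                        seed: int = 0) -> pd.DataFrame:
    """Segment per-bin copy estimates chromosome by chromosome.

    Recursive change-point search: each node is scanned for the window
    [i, j) maximizing the standardized mean-difference statistic
    |mean_in − mean_out|·sqrt(L(n−L)/n) — a two-change-point (circular)
    scan, which keeps power for focal events that a single binary split
    dilutes — and the window is accepted when a permutation test on the
    same statistic gives p < ``p_thresh`` with every resulting piece
    empty or at least ``min_bins`` bins. The scan runs on log2 copies
    (variance stabilization against amplified outliers); reported segment
    means are plain means of the member bins on the copy scale.

    Masked bins (NaN copies) are dropped before segmentation and excluded
    from segment means.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5E9]))
    segs: list[tuple] = []
    for chrom in copies["chrom"].unique():
        sub = copies[(copies["chrom"] == chrom) & copies["copies"].notna()]
        if sub.empty:
            logger.warning("chromosome %s has no unmasked bins; skipped", chrom)
            continue
        x = sub["copies"].to_numpy()
        lx = np.log2(np.maximum(x, 1e-3))
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()

        stack = [(0, len(x))]
        found: list[tuple[int, int]] = []
        while stack:
            a, b = stack.pop()
            n = b - a
            if n < 2 * min_bins:
                found.append((a, b))
                continue
            node = lx[a:b]
            lengths = _window_lengths(n, min_bins)
            cs = np.concatenate([[0.0], np.cumsum(node)])
            window, obs = _window_scan(cs, n, min_bins, lengths)
            if window is None or obs <= 0.0:
                found.append((a, b))
                continue
            p = _perm_pvalue(node, obs, min_bins, lengths, n_perm, p_thresh, rng)
            if p < p_thresh:
                i, j = window
                for lo, hi in ((a, a + i), (a + i, a + j), (a + j, b)):
                    if hi > lo:
                        stack.append((lo, hi))
            else:
                found.append((a, b))
        for a, b in sorted(found):
            segs.append((chrom, int(starts[a]), int(ends[b - 1]),
                         float(np.mean(x[a:b])), b - a))
    return pd.DataFrame(segs, columns=["chrom", "start", "end", "copies", "n_bins"])


def call_focal_amplifications(segments: pd.DataFrame,
                              extra_copy_threshold: float = 2.0,
                              max_len: float = 20e6) -> pd.DataFrame:
    """Flag focal amplifications: extra copies above threshold AND short.

    Returns every segment with ``extra_copies`` and a boolean ``passes``.
    """
    out = segments.copy()
    out["extra_copies"] = out["copies"] - 2.0
    length = out["end"] - out["start"]
    out["passes"] = (out["extra_copies"] > extra_copy_threshold) & (length <= max_len)
    return out


def scna_burden(segments: pd.DataFrame, min_dev: float = 1.0, min_bins: int = 3) -> int:
    """Number of segments deviating from diploid by at least ``min_dev``
    copies over at least ``min_bins`` bins."""
    dev = (segments["copies"] - 2.0).abs() >= min_dev
    return int((dev & (segments["n_bins"] >= min_bins)).sum())


@dataclass
class IntervalCorrelation:
    r: float
    p: float
    n_genes: int


def _gene_copy_estimate(segments: pd.DataFrame, chrom: str, start: int, end: int) -> float:
    """Mean copies over segments overlapping a gene interval; NaN if none."""
    sub = segments[(segments["chrom"] == chrom)
                   & (segments["start"] < end) & (segments["end"] > start)]
    if sub.empty:
        return float("nan")
    return float(sub["copies"].mean())


def expression_cn_correlation(segments: dict[str, pd.DataFrame],
                              expression: pd.DataFrame,
                              annotation: pd.DataFrame,
                              interval: tuple[str, int, int],
                              samples: list[str] | None = None) -> IntervalCorrelation:
    """Gene-level Pearson correlation between copy number and expression
    inside a genomic interval.

    Per gene: mean copy estimate over overlapping segments, averaged over
    the sample group, against the mean log2(normalized + 1) expression.
    """
    chrom, lo, hi = interval
    if samples is None:
        samples = list(segments)
    in_interval = annotation[(annotation["chrom"] == chrom)
                             & (annotation["start"] < hi) & (annotation["end"] > lo)]
    in_interval = in_interval[in_interval["gene_id"].isin(expression.index)]
    cn_vals, expr_vals = [], []
    for rec in in_interval.itertuples():
        per_sample = [_gene_copy_estimate(segments[s], rec.chrom, rec.start, rec.end)
                      for s in samples]
        cn = np.nanmean(per_sample)
        if np.isnan(cn):
            continue
        cn_vals.append(cn)
        expr_vals.append(np.log2(expression.loc[rec.gene_id, samples] + 1).mean())
    if len(cn_vals) < 3:
        raise ValueError(f"only {len(cn_vals)} genes with both copy number and "
                         f"expression in {chrom}:{lo}-{hi}; need >= 3")
    cn_arr, ex_arr = np.asarray(cn_vals), np.asarray(expr_vals)
    if np.all(cn_arr == cn_arr[0]) or np.all(ex_arr == ex_arr[0]):
        raise ValueError("zero-variance vector in CN-expression correlation")
    r, p = stats.pearsonr(cn_arr, ex_arr)
    return IntervalCorrelation(r=float(r), p=float(p), n_genes=len(cn_vals))
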