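"""Weir-Cockerham F_ST, sliding-window averaging and outlier regions.

The per-locus statistic is the unbiased two-population variance-component
estimator: theta = a / (a + b + c), where a, b, c estimate the
among-population, among-individual-within-population and within-individual
allele-frequency variance components.  Per-locus values (which may be
negative) are averaged across sliding windows of an odd number of
consecutive SNPs, the empirical upper tail of window means is taken as
differentiated, and tail windows within 1 Mb of each other are merged into
regions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix
from .pedigree import Pedigree


def wc_fst_per_locus(gm: GenotypeMatrix, group_labels) -> pd.DataFrame:
    """Per-SNP Weir-Cockerham theta between two labelled groups.

    ``group_labels`` is a per-sample array with exactly two distinct
    values.  Missing genotypes are excluded per locus per group.  Loci
    that are monomorphic across both groups, or with a group entirely
    missing, are flagged undefined (theta = nan).

    Returns a frame with the variance components a, b, c, theta, and the
    per-group sample sizes and allele frequencies.
    """
    labels = np.asarray(group_labels)
    if labels.size != gm.n_samples:
        raise ValueError("one group label per sample required")
    groups = np.unique(labels)
    if groups.size != 2:
        raise ValueError(f"exactly two groups required, got {groups.size}")

    dos = gm.dosages
    called = dos != MISSING
    het = dos == 1

    n = np.empty((2, gm.n_snps))
    p = np.empty((2, gm.n_snps))
    h = np.empty((2, gm.n_snps))
    for k, gval in enumerate(groups):
        rows = labels == gval
        nk = called[rows].sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p[k] = np.where(called[rows], dos[rows], 0).sum(axis=0) / (2.0 * nk)
            h[k] = het[rows].sum(axis=0) / nk
        n[k] = nk

    r = 2.0
    nbar = n.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n ** 2).sum(axis=0) / (r * nbar)) / (r - 1.0)
        pbar = (n * p).sum(axis=0) / (r * nbar)
        s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1.0) * nbar)
        hbar = (n * h).sum(axis=0) / (r * nbar)
        inner = pbar * (1.0 - pbar) - ((r - 1.0) / r) * s2 - hbar / 4.0
        a = (nbar / nc) * (s2 - inner / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1.0 - pbar) - ((r - 1.0) / r) * s2 - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar
        )
        c = hbar / 2.0
        denom = a + b + c
        theta = a / denom

    defined = (
        (n > 0).all(axis=0)
        & (nbar > 1.0)
        & np.isfinite(denom)
        & (np.abs(denom) > 0)
        & ~((pbar == 0.0) | (pbar == 1.0))
    )
    theta = np.where(defined, theta, np.nan)

    return pd.DataFrame(
        {
            "snp_id": gm.map.snp_id,
            "chrom": gm.map.chrom,
            "bp": gm.map.bp,
            "n1": n[0],
            "n2": n[1],
            "p1": p[0],
            "p2": p[1],
            "a": np.where(defined, a, np.nan),
            "b": np.where(defined, b, np.nan),
            "c": np.where(defined, c, np.nan),
            "theta": theta,
            "defined": defined,
        }
    )


def window_fst(loci: pd.DataFrame, k: int) -> pd.DataFrame:
    """Sliding-window mean of per-locus theta, keyed by the central SNP.

    ``k`` must be odd; windows cover k consecutive defined-theta loci of
    one chromosome (loci with undefined theta are dropped before
    windowing), so every window has (k-1)/2 neighbours on each side of its
    central SNP.  Chromosomes with fewer than k usable loci yield none.
    """
    if k % 2 != 1 or k < 1:
        raise ValueError("window size k must be a positive odd integer")
    usable = loci[loci["defined"]]
    half = k // 2
    frames = []
    for chrom, grp in usable.groupby("chrom", sort=False):
        t = grp["theta"].to_numpy()
        if t.size < k:
            continue
        means = np.convolve(t, np.ones(k) / k, mode="valid")
        centers = grp.iloc[half:half + means.size]
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "center_snp": centers["snp_id"].to_numpy(),
                    "center_bp": centers["bp"].to_numpy(),
                    "k": k,
                    "mean_theta": means,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["chrom", "center_snp", "center_bp", "k", "mean_theta"])
    return pd.concat(frames, ignore_index=True)


def window_fst_ratio_of_sums(loci: pd.DataFrame, k: int) -> pd.DataFrame:
    """Alternative window statistic: sum(a) / sum(a+b+c) over the window."""
    if k % 2 != 1 or k < 1:
        raise ValueError("window size k must be a positive odd integer")
    usable = loci[loci["defined"]]
    half = k // 2
    frames = []
    kern = np.ones(k)
    for chrom, grp in usable.groupby("chrom", sort=False):
        if len(grp) < k:
            continue
        num = np.convolve(grp["a"].to_numpy(), kern, mode="valid")
        den = np.convolve((grp["a"] + grp["b"] + grp["c"]).to_numpy(), kern, mode="valid")
        with np.errstate(invalid="ignore", divide="ignore"):
            means = num / den
        centers = grp.iloc[half:half + means.size]
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "center_snp": centers["snp_id"].to_numpy(),
                    "center_bp": centers["bp"].to_numpy(),
                    "k": k,
                    "mean_theta": means,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["chrom", "center_snp", "center_bp", "k", "mean_theta"])
    return pd.concat(frames, ignore_index=True)


@dataclass
class Region:
    chrom: int
    start_bp: int
    end_bp: int
    windows: pd.DataFrame  # contributing tail windows (all sizes)
    max_theta_by_k: dict = field(default_factory=dict)  # k -> max, absent if none


def top_windows(windows: pd.DataFrame, tail_fraction: float = 0.0005,
                top_n: int | None = None) -> pd.DataFrame:
    """The empirical upper tail of one window-size's mean-theta values.

    The tail holds ceil(tail_fraction * N) windows (or ``top_n`` when an
    absolute count is requested); ties at the cutoff are all included.
    """
    n = len(windows)
    if n == 0:
        return windows
    size = top_n if top_n is not None else max(1, math.ceil(tail_fraction * n))
    size = min(size, n)
    vals = np.sort(windows["mean_theta"].to_numpy())[::-1]
    cutoff = vals[size - 1]
    return windows[windows["mean_theta"] >= cutoff]


def top_windows_and_regions(
    windows_by_k: dict,
    tail_fraction: float = 0.0005,
    merge_distance_bp: int = 1_000_000,
    top_n: int | None = None,
) -> list:
    """Merge the per-size empirical tails into differentiated regions.

    The union of each window size's tail is taken; central SNPs within
    ``merge_distance_bp`` of each other (same chromosome) are chained into
    a region.  Each region reports the maximum window value per window
    size, with sizes absent from the region omitted from the mapping.
    """
    tails = [top_windows(w, tail_fraction, top_n) for w in windows_by_k.values()]
    tails = [t for t in tails if len(t)]
    if not tails:
        return []
    allw = pd.concat(tails, ignore_index=True).sort_values(["chrom", "center_bp"])
    regions: list = []
    cur: list = []
    for row in allw.itertuples(index=False):
        if cur and (row.chrom != cur[-1].chrom
                    or row.center_bp - cur[-1].center_bp > merge_distance_bp):
            regions.append(_make_region(cur))
            cur = []
        cur.append(row)
    if cur:
        regions.append(_make_region(cur))
    return regions


def _make_region(rows: list) -> Region:
    df = pd.DataFrame(rows)
    maxima = df.groupby("k")["mean_theta"].max().to_dict()
    return Region(
        chrom=int(df["chrom"].iloc[0]),
        start_bp=int(df["center_bp"].min()),
        end_bp=int(df["center_bp"].max()),
        windows=df,
        max_theta_by_k={int(k): float(v) for k, v in maxima.items()},
    )


@dataclass
class CohortSelection:
    cluster1_ids: list
    cluster2_ids: list
    threshold: float
    n_per_cluster: int
    shortfall: dict = field(default_factory=dict)  # cluster -> missing count


def select_cohorts(
    membership: dict,
    ped: Pedigree | None = None,
    threshold: float = 0.90,
    n_per_cluster: int = 27,
    labels: dict | None = None,
    allowed_labels: dict | None = None,
) -> CohortSelection:
    """Pick maximally assigned, mutually non-half-sib cohorts per cluster.

    ``membership`` maps id -> coefficient for cluster 1 (cluster 2 uses the
    complement).  Candidates above ``threshold`` are taken greedily in
    decreasing membership order, skipping any candidate that shares a known
    sire or dam with an already selected member of the same cohort.
    ``labels``/``allowed_labels`` optionally restrict candidates to given
    categories (e.g. role).  If a cohort cannot be filled the shortfall is
    reported, not raised.
    """
    out = {}
    shortfall = {}
    for cluster in (1, 2):
        q = {i: (v if cluster == 1 else 1.0 - v) for i, v in membership.items()}
        cands = [i for i, v in q.items() if v > threshold]
        if labels is not None and allowed_labels is not None and cluster in allowed_labels:
            cands = [i for i in cands if labels.get(i) in allowed_labels[cluster]]
        cands.sort(key=lambda i: (-q[i], str(i)))
        chosen: list = []
        used_parents: set = set()
        for i in cands:
            if len(chosen) >= n_per_cluster:
                break
            parents = set()
            if ped is not None and i in ped:
                parents = {p for p in ped.parents(i) if p is not None}
            if parents & used_parents:
                continue
            chosen.append(i)
            used_parents |= parents
        if len(chosen) < n_per_cluster:
            shortfall[cluster] = n_per_cluster - len(chosen)
        out[cluster] = chosen
    return CohortSelection(
        cluster1_ids=out[1],
        cluster2_ids=out[2],
        threshold=threshold,
        n_per_cluster=n_per_cluster,
        shortfall=shortfall,
    )


def window_scheme_dispersion(
    mmap,
    k_list=(9, 13, 17),
    size_list_bp=(250_000, 500_000, 1_000_000),
) -> dict:
    """Dispersion diagnostic for fixed-SNP vs fixed-size window schemes.

    For each window size k (SNPs), the distribution of physical spans of
    k-SNP windows; for each physical size, the distribution of SNP counts
    in tiling windows of that size.  The coefficient of variation of each
    distribution summarises how uneven the scheme is on the given map.
    """
    report: dict = {"fixed_snp": {}, "fixed_bp": {}}
    chroms = mmap.chromosomes()
    for k in k_list:
        spans = []
        for c in chroms:
            pos = mmap.bp[mmap.chrom_indices(c)]
            if pos.size >= k:
                spans.append(pos[k - 1:] - pos[:pos.size - k + 1])
        spans = np.concatenate(spans) if spans else np.array([])
        report["fixed_snp"][int(k)] = _dispersion(spans.astype(float))
    for size in size_list_bp:
        counts = []
        for c in chroms:
            pos = mmap.bp[mmap.chrom_indices(c)]
            if pos.size == 0:
                continue
            edges = np.arange(1, pos.max() + size + 1, size)
            counts.append(np.histogram(pos, bins=edges)[0])
        counts = np.concatenate(counts) if counts else np.array([])
        report["fixed_bp"][int(size)] = _dispersion(counts.astype(float))
    return report


def _dispersion(x: np.ndarray) -> dict:
    if x.size == 0 or x.mean() == 0:
        return {"n": int(x.size), "mean": float("nan"), "sd": float("nan"),
                "cv": float("nan")}
    return {
        "n": int(x.size),
        "mean": float(x.mean()),
        "sd": float(x.std(ddof=1)) if x.size > 1 else 0.0,
        "cv": float(x.std(ddof=1) / x.mean()) if x.size > 1 else 0.0,
    }
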