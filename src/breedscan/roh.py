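"""Runs of homozygosity: scanning-window detection, F_ROH, segment pools.

The detector follows the classic SNP-array scanning algorithm: windows of a
fixed number of SNPs slide along each chromosome of each individual; a
window "hits" when it contains at most a small number of heterozygous and
missing calls; each SNP's hit proportion is the fraction of windows
covering it that hit, and SNPs whose proportion exceeds a threshold are
eligible.  Maximal stretches of consecutive eligible SNPs that are long
enough (both in SNP count and physical span) are reported as ROH.

F_ROH is the total ROH length divided by the physical extent of the
genotyping panel's genome coverage (default: the 2,198,710,490 bp covered
by the high-density canine array on the CanFam2.0 assembly).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .core import MISSING, GenotypeMatrix


@dataclass
class ROHParams:
    scan_window_snps: int = 50
    window_hit_proportion: float = 0.05
    max_het_per_window: int = 1
    max_missing_per_window: int = 5
    min_snps_in_roh: int = 100
    min_length_bp: int = 1_000_000
    genome_denominator_bp: int = 2_198_710_490

    def __post_init__(self) -> None:
        if not (0.0 < self.window_hit_proportion <= 1.0):
            raise ValueError("window_hit_proportion must be in (0, 1]")
        for name in ("scan_window_snps", "min_snps_in_roh", "min_length_bp",
                     "genome_denominator_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class ROHSegment:
    individual: str
    chrom: int
    start_bp: int
    end_bp: int  # 1-based inclusive
    n_snps: int
    n_het_inside: int
    n_missing_inside: int
    start_idx: int = -1  # global marker-map indices of the run's ends
    end_idx: int = -1

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


@dataclass
class ROHPool:
    pool_id: int
    segments: list
    chrom: int
    consensus_start_idx: int
    consensus_end_idx: int
    consensus_start_bp: int
    consensus_end_bp: int
    # allelic subgroups: genotype-signature over the consensus interval
    subgroups: list = field(default_factory=list)  # list of lists of segments


def detect_roh(gm: GenotypeMatrix, params: ROHParams | None = None) -> list:
    """Scan every individual's genome for runs of homozygosity."""
    p = params or ROHParams()
    w = p.scan_window_snps
    segments: list = []
    for c in gm.map.chromosomes():
        idx = gm.map.chrom_indices(c)
        m = idx.size
        if m < w:
            continue  # no windows fit: no calls on this chromosome
        pos = gm.map.bp[idx]
        n_starts = m - w + 1
        for i, iid in enumerate(gm.sample_ids):
            g = gm.dosages[i, idx]
            het = (g == 1).astype(np.int32)
            mis = (g == MISSING).astype(np.int32)
            het_win = _window_sums(het, w)
            mis_win = _window_sums(mis, w)
            hit = (het_win <= p.max_het_per_window) & (mis_win <= p.max_missing_per_window)
            # per-SNP covering-window tallies
            cover_hits = _coverage_sums(hit.astype(np.int32), m, w)
            cover_all = _coverage_sums(np.ones(n_starts, dtype=np.int32), m, w)
            eligible = cover_hits > p.window_hit_proportion * cover_all
            for s, e in _runs(eligible):
                n_snps = e - s + 1
                length = int(pos[e] - pos[s]) + 1
                if n_snps >= p.min_snps_in_roh and length >= p.min_length_bp:
                    segments.append(
                        ROHSegment(
                            individual=iid,
                            chrom=int(c),
                            start_bp=int(pos[s]),
                            end_bp=int(pos[e]),
                            n_snps=n_snps,
                            n_het_inside=int(het[s:e + 1].sum()),
                            n_missing_inside=int(mis[s:e + 1].sum()),
                            start_idx=int(idx[s]),
                            end_idx=int(idx[e]),
                        )
                    )
    return segments


def _window_sums(x: np.ndarray, w: int) -> np.ndarray:
    cs = np.concatenate([[0], np.cumsum(x)])
    return cs[w:] - cs[:-w]


def _coverage_sums(per_start: np.ndarray, m: int, w: int) -> np.ndarray:
    """Sum of ``per_start`` over the window starts covering each SNP.

    SNP s is covered by starts in [max(0, s-w+1), min(s, m-w)]; near
    chromosome ends fewer windows cover a SNP and the actual count is used.
    """
    n_starts = m - w + 1
    cs = np.concatenate([[0], np.cumsum(per_start)])
    s = np.arange(m)
    lo = np.maximum(0, s - w + 1)
    hi = np.minimum(s, n_starts - 1)
    return cs[hi + 1] - cs[lo]


def _runs(mask: np.ndarray):
    """(start, end) inclusive index pairs of maximal True runs."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1)
    if mask[0]:
        starts = np.concatenate([[0], starts])
    if mask[-1]:
        ends = np.concatenate([ends, [mask.size - 1]])
    return list(zip(starts.tolist(), ends.tolist()))


def f_roh(segments: list, params: ROHParams | None = None,
          sample_ids=None) -> dict:
    """Genomic inbreeding coefficient per individual.

    Total ROH length (bp, inclusive ends) over the genome denominator;
    ``sample_ids`` lets individuals without any segment appear with 0.
    """
    p = params or ROHParams()
    out = {sid: 0.0 for sid in (sample_ids or [])}
    for seg in segments:
        out[seg.individual] = out.get(seg.individual, 0.0) + seg.length_bp
    return {k: v / p.genome_denominator_bp for k, v in out.items()}


def segments_to_frame(segments: list) -> pd.DataFrame:
    """Tabular view of segments in the conventional .hom-style layout."""
    return pd.DataFrame(
        [
            {
                "IID": s.individual,
                "CHR": s.chrom,
                "POS1": s.start_bp,
                "POS2": s.end_bp,
                "KB": s.length_bp / 1000.0,
                "NSNP": s.n_snps,
                "NHET": s.n_het_inside,
                "NMISS": s.n_missing_inside,
            }
            for s in segments
        ]
    )


def pool_overlapping_segments(segments: list, gm: GenotypeMatrix,
                              min_overlap_snps: int = 3) -> list:
    """Group segments that overlap by more than two SNPs into pools.

    Overlap is transitive (connected components of the pairwise-overlap
    graph); only pools with segments from at least two individuals are
    reported.  Within a pool, allelic subgroups collect segments whose
    carriers have identical genotype states over the pool's consensus
    (shared-by-all) interval.
    """
    n = len(segments)
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    by_chrom: dict = {}
    for i, s in enumerate(segments):
        by_chrom.setdefault(s.chrom, []).append(i)
    for idxs in by_chrom.values():
        idxs = sorted(idxs, key=lambda i: segments[i].start_idx)
        for a_pos, i in enumerate(idxs):
            for j in idxs[a_pos + 1:]:
                si, sj = segments[i], segments[j]
                if sj.start_idx > si.end_idx - (min_overlap_snps - 1):
                    break
                shared = min(si.end_idx, sj.end_idx) - max(si.start_idx, sj.start_idx) + 1
                if shared >= min_overlap_snps:
                    parent[find(i)] = find(j)

    comps: dict = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)

    pools = []
    pid = 0
    for members in comps.values():
        segs = [segments[i] for i in members]
        if len(segs) < 2 or len({s.individual for s in segs}) < 2:
            continue
        lo = max(s.start_idx for s in segs)
        hi = min(s.end_idx for s in segs)
        if hi - lo + 1 < min_overlap_snps:
            # transitive chain with no common core: keep pool, one subgroup
            lo, hi = -1, -2
        groups: dict = {}
        for s in segs:
            if lo <= hi:
                row = gm.dosages[gm.sample_index(s.individual), lo:hi + 1]
                key = tuple(int(v) for v in row)
            else:
                key = ()
            groups.setdefault(key, []).append(s)
        pools.append(
            ROHPool(
                pool_id=pid,
                segments=segs,
                chrom=segs[0].chrom,
                consensus_start_idx=lo,
                consensus_end_idx=hi,
                consensus_start_bp=int(gm.map.bp[lo]) if lo <= hi else -1,
                consensus_end_bp=int(gm.map.bp[hi]) if lo <= hi else -1,
                subgroups=list(groups.values()),
            )
        )
        pid += 1
    return pools


@dataclass
class PoolAssociation:
    chi2: float
    p_value: float
    dof: int
    table: np.ndarray
    defined: bool = True


def cluster_roh_association(pool: ROHPool, membership: dict,
                            low_high_cut: float = 0.5) -> PoolAssociation:
    """Pearson chi-square of cluster stratum vs allelic subgroup.

    ``membership`` maps individual id to its coefficient for cluster 1;
    "low" means coefficient <= ``low_high_cut``.  A zero row or column
    margin makes the statistic undefined (flagged).
    """
    k = len(pool.subgroups)
    table = np.zeros((2, k), dtype=np.int64)
    for g, segs in enumerate(pool.subgroups):
        for s in segs:
            q = membership[s.individual]
            table[0 if q <= low_high_cut else 1, g] += 1
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any() or k < 2:
        return PoolAssociation(float("nan"), float("nan"),
                               dof=(2 - 1) * (max(k, 1) - 1),
                               table=table, defined=False)
    chi2, p, dof, _ = chi2_contingency(table, correction=False)
    return PoolAssociation(float(chi2), float(p), int(dof), table)
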