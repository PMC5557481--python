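"""Pairwise linkage disequilibrium, distance-binned decay and LD-based Ne.

r² is the squared Pearson correlation between unphased dosage vectors
(composite LD), computed for syntenic marker pairs over the samples called
at both loci.  Binned mean r² as a function of distance feeds the drift
expectation E(r²) = 1/(alpha + 4 Ne c), where c is the recombination
fraction in Morgans (physical distance converted at a constant cM/Mb) and
alpha is 1 ignoring mutation or 2 accounting for it; each distance bin
then yields an estimate of Ne roughly 1/(2c) generations in the past.
A finite-sample correction subtracts 1/(2n) from mean r² before inversion
when requested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix

#: Genetic map density assumed when converting bp to Morgans (canine average).
DEFAULT_CM_PER_MB = 0.97

#: Genetic span (cM) whose bins inform Ne about one generation in the past.
RECENT_SPAN_CM = (33.0, 100.0)


@dataclass
class LDBinSummary:
    lo_bp: float
    hi_bp: float
    mean_dist_bp: float
    mean_r2: float
    mean_r2_adjusted: float  # mean_r2 - 1/(2n); nan if n unknown
    n_pairs: int
    r2_pct2_5: float
    r2_pct97_5: float


def pairwise_r2(
    gm: GenotypeMatrix,
    maf_min: float = 0.0,
    max_distance_bp: int | None = None,
) -> pd.DataFrame:
    """Squared dosage correlation for all syntenic marker pairs.

    Loci with minor allele frequency <= ``maf_min`` are excluded, as are
    pairs whose pairwise-complete dosage vectors have zero variance.
    Returns a frame with columns chrom, snp_i, snp_j, dist_bp, r2.
    """
    maf = gm.maf()
    usable = np.flatnonzero(np.nan_to_num(maf, nan=0.0) > maf_min)
    has_missing = bool((gm.dosages == MISSING).any())

    rows_chrom, rows_i, rows_j, rows_d, rows_r2 = [], [], [], [], []
    for c in gm.map.chromosomes():
        idx = np.intersect1d(gm.map.chrom_indices(c), usable)
        if idx.size < 2:
            continue
        pos = gm.map.bp[idx]
        X = gm.dosages[:, idx].astype(float)
        if not has_missing:
            std = X.std(axis=0)
            ok = std > 0
            Z = np.zeros_like(X)
            Z[:, ok] = (X[:, ok] - X[:, ok].mean(axis=0)) / std[ok]
            n = X.shape[0]
        for a in range(idx.size - 1):
            if max_distance_bp is None:
                hi = idx.size
            else:
                hi = int(np.searchsorted(pos, pos[a] + max_distance_bp, side="right"))
            if hi <= a + 1:
                continue
            js = np.arange(a + 1, hi)
            if not has_missing:
                if not ok[a]:
                    continue
                r = (Z[:, js].T @ Z[:, a]) / n
                keep = ok[js]
                r2 = r[keep] ** 2
                js = js[keep]
            else:
                r2_list, keep_js = [], []
                xa = X[:, a]
                ma = xa != MISSING
                for b in js:
                    xb = X[:, b]
                    m = ma & (xb != MISSING)
                    if m.sum() < 2:
                        continue
                    va, vb = xa[m], xb[m]
                    if va.std() == 0 or vb.std() == 0:
                        continue
                    r = np.corrcoef(va, vb)[0, 1]
                    r2_list.append(r * r)
                    keep_js.append(b)
                r2 = np.array(r2_list)
                js = np.array(keep_js, dtype=int)
            if js.size == 0:
                continue
            rows_chrom.append(np.full(js.size, c))
            rows_i.append(np.full(js.size, idx[a]))
            rows_j.append(idx[js])
            rows_d.append(pos[js] - pos[a])
            rows_r2.append(r2)

    if not rows_chrom:
        return pd.DataFrame(columns=["chrom", "snp_i", "snp_j", "dist_bp", "r2"])
    chrom = np.concatenate(rows_chrom)
    i_idx = np.concatenate(rows_i)
    j_idx = np.concatenate(rows_j)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "snp_i": gm.map.snp_id[i_idx],
            "snp_j": gm.map.snp_id[j_idx],
            "dist_bp": np.concatenate(rows_d).astype(np.int64),
            "r2": np.concatenate(rows_r2),
        }
    )


def bin_ld(pairs: pd.DataFrame, bin_edges_bp, n_samples: int | None = None) -> list:
    """Average r² within half-open distance bins [lo, hi).

    A pair exactly at an edge goes to the bin whose lower edge it equals.
    Empty bins are omitted.  ``n_samples`` enables the 1/(2n) adjusted mean.
    """
    edges = np.asarray(bin_edges_bp, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or not np.all(np.diff(edges) > 0):
        raise ValueError("bin edges must be a sorted 1-D array of length >= 2")
    if pairs.empty:
        return []
    d = pairs["dist_bp"].to_numpy()
    r2 = pairs["r2"].to_numpy()
    which = np.digitize(d, edges) - 1  # [lo, hi) with the convention above
    out = []
    for b in range(edges.size - 1):
        m = which == b
        if not m.any():
            continue
        vals = r2[m]
        mean = float(vals.mean())
        out.append(
            LDBinSummary(
                lo_bp=float(edges[b]),
                hi_bp=float(edges[b + 1]),
                mean_dist_bp=float(d[m].mean()),
                mean_r2=mean,
                mean_r2_adjusted=(mean - 1.0 / (2 * n_samples)) if n_samples else float("nan"),
                n_pairs=int(m.sum()),
                r2_pct2_5=float(np.percentile(vals, 2.5)),
                r2_pct97_5=float(np.percentile(vals, 97.5)),
            )
        )
    return out


def default_bin_edges(lo_bp: float = 1_000, hi_bp: float = 50_000_000,
                      n_bins: int = 25) -> np.ndarray:
    """Geometric distance-bin edges from 1 kb to 50 Mb."""
    return np.geomspace(lo_bp, hi_bp, n_bins + 1)


def cm_span_to_bp(lo_cm: float, hi_cm: float, cm_per_mb: float = DEFAULT_CM_PER_MB):
    """Convert a genetic-distance span to physical bp at constant cM/Mb."""
    return lo_cm / cm_per_mb * 1e6, hi_cm / cm_per_mb * 1e6


def estimate_ne_from_ld(
    bins: list,
    cm_per_mb: float = DEFAULT_CM_PER_MB,
    n_samples: int | None = None,
    alpha: int = 1,
    use_adjusted: bool = False,
) -> pd.DataFrame:
    """Per-bin Ne from E(r²) = 1/(alpha + 4 Ne c).

    c is the bin's mean physical distance converted to Morgans at
    ``cm_per_mb``; Ne = (1/r - alpha) / (4c) with r the (optionally
    1/(2n)-adjusted) mean r²; the bin dates to 1/(2c) generations ago.
    Bins where the inversion is impossible (r <= 0 after adjustment, or
    1/r <= alpha) carry ``defined=False`` with Ne = nan.
    """
    if alpha not in (1, 2):
        raise ValueError("alpha must be 1 or 2")
    rows = []
    for b in bins:
        c = b.mean_dist_bp * (cm_per_mb / 100.0) / 1e6  # Morgans
        if use_adjusted:
            if n_samples is None and np.isnan(b.mean_r2_adjusted):
                raise ValueError("adjusted r2 requires n_samples")
            r = b.mean_r2_adjusted if not np.isnan(b.mean_r2_adjusted) else (
                b.mean_r2 - 1.0 / (2 * n_samples)
            )
        else:
            r = b.mean_r2
        defined = r > 0 and (1.0 / r) > alpha and c > 0
        ne = (1.0 / r - alpha) / (4.0 * c) if defined else float("nan")
        rows.append(
            {
                "lo_bp": b.lo_bp,
                "hi_bp": b.hi_bp,
                "c_morgans": c,
                "generations_ago": 1.0 / (2.0 * c) if c > 0 else float("inf"),
                "n_pairs": b.n_pairs,
                "mean_r2": b.mean_r2,
                "r2_used": r,
                "alpha": alpha,
                "adjusted": use_adjusted,
                "ne": ne,
                "defined": defined,
            }
        )
    return pd.DataFrame(rows)
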