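"""Support computations for model-based clustering analyses.

The clustering itself (admixture-model MCMC) is treated as an external
step whose log-likelihood table and membership coefficients are inputs;
this module provides the delta-K statistic used to choose the number of
clusters and the deterministic every-nth marker thinning used to build a
reduced-LD subset.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def delta_k(table: pd.DataFrame) -> pd.DataFrame:
    """Second-difference (delta-K) statistic of a log-likelihood profile.

    ``table`` has columns K, replicate, lnp with >= 2 replicates at each of
    >= 3 consecutive K values.  For each interior K,

        delta_K = mean_r |lnp_r(K+1) - 2 lnp_r(K) + lnp_r(K-1)| / sd_r(lnp(K))

    with the mean of per-replicate absolute second differences in the
    numerator and the standard deviation of lnp across replicates at K in
    the denominator (undefined, flagged, when that sd is 0).
    """
    req = {"K", "replicate", "lnp"}
    if not req.issubset(table.columns):
        raise ValueError(f"likelihood table needs columns {sorted(req)}")
    ks = np.sort(table["K"].unique())
    if ks.size < 3 or not np.all(np.diff(ks) == 1):
        raise ValueError("need at least three consecutive K values")
    wide = table.pivot(index="replicate", columns="K", values="lnp")
    if wide.isna().any().any():
        raise ValueError("every replicate needs a value at every K")
    if len(wide) < 2:
        raise ValueError("need at least two replicates per K")
    rows = []
    for k in ks[1:-1]:
        second = wide[k + 1] - 2 * wide[k] + wide[k - 1]
        sd = wide[k].std(ddof=1)
        defined = sd > 0
        rows.append(
            {
                "K": int(k),
                "delta_k": float(second.abs().mean() / sd) if defined else float("nan"),
                "sd_lnp": float(sd),
                "defined": bool(defined),
            }
        )
    return pd.DataFrame(rows)


def thin_markers(mmap, stride: int = 3) -> np.ndarray:
    """Indices of every ``stride``-th marker in genome-wide map order.

    The first marker is always kept, so ceil(m / stride) markers survive
    (e.g. 117,971 markers at stride 3 leave 39,324).  Map order, and hence
    chromosome assignment, is preserved.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    return np.arange(0, mmap.n_snps, stride)
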