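"""Independent reference implementations used only as test oracles.

Each function here deliberately uses a different algorithm from the package
code it checks: path counting instead of the kinship recurrence, the
tabular relationship matrix instead of memoised recursion, exact rational
enumeration instead of log-gamma arithmetic, literal step-by-step formula
transcription instead of vectorised components, and an explicit
window-enumeration ROH scan instead of cumulative sums.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb

import numpy as np

from breedscan.core import MISSING


# ---------------------------------------------------------------------------
# pedigree oracles
# ---------------------------------------------------------------------------

def wright_path_inbreeding(ped, iid) -> float:
    """Wright's path-counting inbreeding coefficient.

    F(x) = sum over common ancestors A of sire and dam, over pairs of
    ancestor paths meeting only at A, of (1/2)^(n1+n2+1) (1 + F(A)).
    """
    sire, dam = ped.parents(iid)
    if sire is None or dam is None:
        return 0.0
    return _path_kinship(ped, sire, dam)


def _paths_up(ped, start):
    """All ancestor paths [start, ..., ancestor] (including trivial)."""
    out = [[start]]
    s, d = ped.parents(start)
    for p in (s, d):
        if p is not None:
            out.extend([[start] + rest for rest in _paths_up(ped, p)])
    return out


def _path_kinship(ped, a, b) -> float:
    total = 0.0
    for pa in _paths_up(ped, a):
        for pb in _paths_up(ped, b):
            if pa[-1] != pb[-1]:
                continue
            # paths must share only the terminal common ancestor
            if set(pa[:-1]) & set(pb):
                continue
            if set(pb[:-1]) & set(pa):
                continue
            anc = pa[-1]
            n1, n2 = len(pa) - 1, len(pb) - 1
            total += 0.5 ** (n1 + n2 + 1) * (1.0 + wright_path_inbreeding(ped, anc))
    return total


def tabular_relationship_matrix(ped):
    """Additive relationship matrix by the tabular method.

    Returns (ids, A) with individuals in topological (parents-first) order;
    kinship(i, j) = A[i, j] / 2.
    """
    ids = _topological(ped)
    index = {x: i for i, x in enumerate(ids)}
    n = len(ids)
    A = np.zeros((n, n))
    for i, x in enumerate(ids):
        s, d = ped.parents(x)
        si = index[s] if s is not None else None
        di = index[d] if d is not None else None
        A[i, i] = 1.0 + (0.5 * A[si, di] if (si is not None and di is not None) else 0.0)
        for j in range(i):
            val = 0.0
            if si is not None:
                val += 0.5 * A[j, si]
            if di is not None:
                val += 0.5 * A[j, di]
            A[i, j] = A[j, i] = val
    return ids, A


def _topological(ped):
    order, seen = [], set()

    def visit(x):
        if x in seen:
            return
        seen.add(x)
        for p in ped.parents(x):
            if p is not None:
                visit(p)
        order.append(x)

    for x in ped.sire:
        visit(x)
    return order


def enumerate_ancestors(ped, iid, depth=0, out=None):
    """(ancestor, generation) pairs over all known ancestor slots."""
    if out is None:
        out = []
    for p in ped.parents(iid):
        if p is not None:
            out.append((p, depth + 1))
            enumerate_ancestors(ped, p, depth + 1, out)
    return out


# ---------------------------------------------------------------------------
# HWE exact test by full rational enumeration
# ---------------------------------------------------------------------------

def hwe_exact_enumeration(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Exact HWE p-value via enumeration with rational arithmetic."""
    n = n_hom1 + n_het + n_hom2
    na = 2 * n_hom1 + n_het  # copies of allele 1
    if na == 0 or na == 2 * n:
        return 1.0

    def weight(het: int) -> int:
        hom1 = (na - het) // 2
        hom2 = n - hom1 - het
        if hom1 < 0 or hom2 < 0:
            return 0
        # multinomial genotype arrangements x 2^het phase assignments
        return comb(n, hom1) * comb(n - hom1, het) * (2 ** het)

    hets = [h for h in range(na % 2, min(na, 2 * n - na) + 1, 2)]
    weights = {h: weight(h) for h in hets}
    total = sum(weights.values())
    w_obs = weights[n_het]
    # integer weight comparison == exact probability comparison
    return float(Fraction(sum(w for w in weights.values() if w <= w_obs), total))


# ---------------------------------------------------------------------------
# Weir-Cockerham theta: literal two-group transcription
# ---------------------------------------------------------------------------

def wc_theta_transcription(geno1, geno2):
    """Step-by-step scalar evaluation of the two-population components.

    ``geno1``/``geno2`` are dosage lists for one locus (missing excluded by
    the caller).  Returns (a, b, c, theta); theta is nan when undefined.
    """
    g1 = [g for g in geno1 if g != MISSING]
    g2 = [g for g in geno2 if g != MISSING]
    n1, n2 = len(g1), len(g2)
    if n1 == 0 or n2 == 0:
        return float("nan"), float("nan"), float("nan"), float("nan")
    r = 2
    p1 = sum(g1) / (2 * n1)
    p2 = sum(g2) / (2 * n2)
    h1 = sum(1 for g in g1 if g == 1) / n1
    h2 = sum(1 for g in g2 if g == 1) / n2
    nbar = (n1 + n2) / r
    if nbar <= 1:
        return float("nan"), float("nan"), float("nan"), float("nan")
    nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    if pbar in (0.0, 1.0):
        return float("nan"), float("nan"), float("nan"), float("nan")
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (1 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2
    denom = a + b + c
    theta = a / denom if denom != 0 else float("nan")
    return a, b, c, theta


# ---------------------------------------------------------------------------
# naive ROH scanner
# ---------------------------------------------------------------------------

def naive_roh_scan(genotypes, positions, params):
    """Direct window-enumeration ROH scan for one individual/chromosome.

    ``genotypes``: 1-D dosage array; ``positions``: matching bp positions.
    Returns (start_index, end_index) pairs of segments passing the filters.
    """
    g = np.asarray(genotypes)
    m = g.size
    w = params.scan_window_snps
    if m < w:
        return []
    hits = []
    for s in range(m - w + 1):
        window = g[s:s + w]
        n_het = int(np.sum(window == 1))
        n_mis = int(np.sum(window == MISSING))
        hits.append(n_het <= params.max_het_per_window
                    and n_mis <= params.max_missing_per_window)
    eligible = []
    for snp in range(m):
        lo = max(0, snp - w + 1)
        hi = min(snp, m - w)
        covering = hits[lo:hi + 1]
        eligible.append(sum(covering) > params.window_hit_proportion * len(covering))
    segments = []
    i = 0
    while i < m:
        if eligible[i]:
            j = i
            while j + 1 < m and eligible[j + 1]:
                j += 1
            n_snps = j - i + 1
            length = int(positions[j] - positions[i]) + 1
            if n_snps >= params.min_snps_in_roh and length >= params.min_length_bp:
                segments.append((i, j))
            i = j + 1
        else:
            i += 1
    return segments


# ---------------------------------------------------------------------------
# chi-square
# ---------------------------------------------------------------------------

def pearson_chi2(table):
    """Textbook Pearson chi-square for a contingency table."""
    t = np.asarray(table, dtype=float)
    rows = t.sum(axis=1, keepdims=True)
    cols = t.sum(axis=0, keepdims=True)
    expected = rows @ cols / t.sum()
    return float(((t - expected) ** 2 / expected).sum())


# ---------------------------------------------------------------------------
# random pedigree generator (layered, so path enumeration stays tractable)
# ---------------------------------------------------------------------------

def random_layered_pedigree(rng, n_founders=8, n_generations=4, per_generation=10):
    """Random pedigree records with parents drawn from the previous layer."""
    from breedscan.pedigree import Pedigree

    records = [(f"F{i}", None, None) for i in range(n_founders)]
    prev = [r[0] for r in records]
    for g in range(1, n_generations + 1):
        layer = []
        for i in range(per_generation):
            iid = f"G{g}_{i}"
            sire = prev[rng.integers(len(prev))]
            dam = prev[rng.integers(len(prev))]
            if sire == dam:  # one unknown parent rather than selfing
                dam = None
            records.append((iid, sire, dam))
            layer.append(iid)
        prev = layer
    return Pedigree(records)
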