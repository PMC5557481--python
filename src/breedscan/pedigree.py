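"""Pedigree-based inbreeding, kinship, completeness and effective size.

The inbreeding coefficient F of an individual is the kinship of its parents;
kinship is computed by the standard recurrence on ordered pairs with
memoisation, so sparse queries do not require building the full additive
relationship matrix.  An individual with an unknown parent contributes no
identity-by-descent through that parent, so founders and half-known
individuals have F = 0.

The inbreeding (rate-of-heterozygosity-loss) effective population size is
estimated as Ne = 1 / (2 dF L), where dF is the annual rate of inbreeding
obtained from the slope of an ordinary least-squares regression of
ln(1 - F) on birthdate (in years), and L is the mean generation interval
in years, so that dF * L is the per-generation rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class PedigreeCycleError(ValueError):
    """Raised when an individual is its own ancestor."""


DAYS_PER_YEAR = 365.25


@dataclass
class CompletenessMetrics:
    """Depth-of-knowledge summary of one individual's ancestry.

    ``max_generations`` is the generation distance to the furthest known
    ancestor; ``complete_generations`` the deepest generation g at which all
    2^g ancestor slots are filled; ``equivalent_generations`` the sum of
    (1/2)^n over all known ancestor slots n generations back.
    """

    max_generations: int
    complete_generations: int
    equivalent_generations: float


@dataclass
class NeEstimate:
    ne: float
    delta_f_per_generation: float
    slope: float  # d ln(1-F) / d year
    generation_interval_years: float
    n_individuals_used: int
    defined: bool = True


class Pedigree:
    """Directed acyclic id -> (sire, dam, birthdate) table.

    Unknown parents are ``None``; birthdates are optional
    ``pandas.Timestamp`` values.  Parent ids referenced but never listed as
    individuals are added implicitly as founders.
    """

    def __init__(self, records):
        """``records``: iterable of (id, sire, dam[, birthdate]) tuples."""
        self.sire: dict = {}
        self.dam: dict = {}
        self.birthdate: dict = {}
        for rec in records:
            iid, sire, dam = rec[0], rec[1], rec[2]
            bd = rec[3] if len(rec) > 3 else None
            if iid in self.sire:
                raise ValueError(f"duplicate pedigree id {iid!r}")
            self.sire[iid] = sire if not _is_unknown(sire) else None
            self.dam[iid] = dam if not _is_unknown(dam) else None
            self.birthdate[iid] = bd if bd is not None and not pd.isna(bd) else None
        # implicit founders for referenced-but-unlisted parents
        for iid in list(self.sire):
            for p in (self.sire[iid], self.dam[iid]):
                if p is not None and p not in self.sire:
                    self.sire[p] = None
                    self.dam[p] = None
                    self.birthdate[p] = None
        self._check_acyclic()
        self._kin_cache: dict = {}
        self._f_cache: dict = {}
        self._rank_cache: dict = {}

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Pedigree":
        recs = []
        has_bd = "birthdate" in df.columns
        for row in df.itertuples(index=False):
            bd = getattr(row, "birthdate") if has_bd else None
            recs.append((row.id, row.sire, row.dam, bd))
        return cls(recs)

    def to_frame(self) -> pd.DataFrame:
        ids = list(self.sire)
        return pd.DataFrame(
            {
                "id": ids,
                "sire": [self.sire[i] for i in ids],
                "dam": [self.dam[i] for i in ids],
                "birthdate": [self.birthdate[i] for i in ids],
            }
        )

    def __len__(self) -> int:
        return len(self.sire)

    def __contains__(self, iid) -> bool:
        return iid in self.sire

    def parents(self, iid):
        return self.sire[iid], self.dam[iid]

    def _check_acyclic(self) -> None:
        WHITE, GREY, BLACK = 0, 1, 2
        color = {i: WHITE for i in self.sire}
        for start in self.sire:
            if color[start] != WHITE:
                continue
            stack = [(start, iter(self._known_parents(start)))]
            color[start] = GREY
            path = [start]
            while stack:
                node, it = stack[-1]
                advanced = False
                for p in it:
                    if color[p] == GREY:
                        cycle = path[path.index(p):] + [p]
                        raise PedigreeCycleError(
                            "pedigree cycle: " + " -> ".join(map(str, cycle))
                        )
                    if color[p] == WHITE:
                        color[p] = GREY
                        path.append(p)
                        stack.append((p, iter(self._known_parents(p))))
                        advanced = True
                        break
                if not advanced:
                    color[node] = BLACK
                    path.pop()
                    stack.pop()

    def _known_parents(self, iid):
        return [p for p in (self.sire[iid], self.dam[iid]) if p is not None]

    # -- generation rank used to orient the kinship recurrence -------------
    def _rank(self, iid) -> int:
        if iid in self._rank_cache:
            return self._rank_cache[iid]
        # iterative post-order: rank = 1 + max(parent ranks), founders 0
        stack = [iid]
        while stack:
            node = stack[-1]
            if node in self._rank_cache:
                stack.pop()
                continue
            pending = [p for p in self._known_parents(node) if p not in self._rank_cache]
            if pending:
                stack.extend(pending)
            else:
                ps = self._known_parents(node)
                self._rank_cache[node] = 1 + max((self._rank_cache[p] for p in ps), default=-1)
                stack.pop()
        return self._rank_cache[iid]

    # -- kinship and inbreeding --------------------------------------------
    def kinship(self, a, b) -> float:
        """Kinship (coancestry) coefficient of two individuals.

        Probability that alleles drawn at random from each are identical by
        descent; half the additive relationship; kinship(x, x) = (1+F_x)/2.
        """
        for i in (a, b):
            if i not in self.sire:
                raise KeyError(f"unknown pedigree id {i!r}")
        return self._kin(a, b)

    def _kin(self, a, b) -> float:
        if a is None or b is None:
            return 0.0
        key = (a, b) if (self._rank(a), str(a)) >= (self._rank(b), str(b)) else (b, a)
        hit = self._kin_cache.get(key)
        if hit is not None:
            return hit
        x, y = key  # x is the "younger" (recursion descends through x)
        if x == y:
            val = 0.5 * (1.0 + self._kin(self.sire[x], self.dam[x]))
        else:
            val = 0.5 * (self._kin(self.sire[x], y) + self._kin(self.dam[x], y))
        self._kin_cache[key] = val
        return val

    def inbreeding(self, iid) -> float:
        """F = kinship of the individual's parents (0 if either unknown)."""
        if iid not in self.sire:
            raise KeyError(f"unknown pedigree id {iid!r}")
        hit = self._f_cache.get(iid)
        if hit is None:
            s, d = self.sire[iid], self.dam[iid]
            hit = self._kin(s, d) if (s is not None and d is not None) else 0.0
            self._f_cache[iid] = hit
        return hit

    def inbreeding_coefficients(self) -> dict:
        """F for every individual, keyed by id."""
        return {i: self.inbreeding(i) for i in self.sire}

    # -- completeness --------------------------------------------------------
    def completeness(self, iid) -> CompletenessMetrics:
        if iid not in self.sire:
            raise KeyError(f"unknown pedigree id {iid!r}")
        maxg: dict = {}
        compg: dict = {}
        eqg: dict = {}

        order = self._ancestor_postorder(iid)
        for node in order:
            ps = [self.sire[node], self.dam[node]]
            known = [p for p in ps if p is not None]
            maxg[node] = 1 + max((maxg[p] for p in known), default=-1)
            compg[node] = (1 + min(compg[p] for p in known)) if len(known) == 2 else 0
            eqg[node] = sum(0.5 * (1.0 + eqg[p]) for p in known)
        return CompletenessMetrics(
            max_generations=maxg[iid],
            complete_generations=compg[iid],
            equivalent_generations=eqg[iid],
        )

    def _ancestor_postorder(self, iid) -> list:
        seen = set()
        order = []
        stack = [(iid, False)]
        while stack:
            node, done = stack.pop()
            if done:
                order.append(node)
                continue
            if node in seen:
                continue
            seen.add(node)
            stack.append((node, True))
            for p in self._known_parents(node):
                stack.append((p, False))
        return order


def _is_unknown(parent) -> bool:
    if parent is None:
        return True
    if isinstance(parent, float) and math.isnan(parent):
        return True
    return str(parent) in ("", "0", "nan", "NA")


def inbreeding_coefficients(ped: Pedigree) -> dict:
    return ped.inbreeding_coefficients()


def kinship(ped: Pedigree, a, b) -> float:
    return ped.kinship(a, b)


def completeness(ped: Pedigree, iid) -> CompletenessMetrics:
    return ped.completeness(iid)


def ne_from_inbreeding_trend(
    ped: Pedigree,
    generation_interval_years: float = 4.5,
    min_birthdate=None,
    drop_zero_f: bool = False,
) -> NeEstimate:
    """Inbreeding effective population size from the ln(1-F) trend.

    Regresses ln(1 - F) on birthdate in years; the negated slope is the
    annual inbreeding rate dF, multiplied by the generation interval L to
    give the per-generation rate, and Ne = 1/(2 dF L).  ``min_birthdate``
    drops older individuals; ``drop_zero_f`` drops F = 0 individuals
    (typically those with too little pedigree depth for F to be estimable).

    A non-negative slope yields ``defined=False`` with ``ne = nan``.
    """
    xs, ys = [], []
    for iid in ped.sire:
        bd = ped.birthdate[iid]
        if bd is None:
            continue
        bd = pd.Timestamp(bd)
        if min_birthdate is not None and bd < pd.Timestamp(min_birthdate):
            continue
        f = ped.inbreeding(iid)
        if drop_zero_f and f == 0.0:
            continue
        xs.append(bd.to_julian_date() / DAYS_PER_YEAR)
        ys.append(math.log1p(-f))
    if len(xs) < 2:
        raise ValueError("need at least two individuals with birthdate and F")
    slope, _ = np.polyfit(np.asarray(xs), np.asarray(ys), 1)
    slope = float(slope)
    df_gen = -slope * generation_interval_years
    if df_gen <= 0:
        return NeEstimate(
            ne=float("nan"),
            delta_f_per_generation=df_gen,
            slope=slope,
            generation_interval_years=generation_interval_years,
            n_individuals_used=len(xs),
            defined=False,
        )
    return NeEstimate(
        ne=1.0 / (2.0 * df_gen),
        delta_f_per_generation=df_gen,
        slope=slope,
        generation_interval_years=generation_interval_years,
        n_individuals_used=len(xs),
    )
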