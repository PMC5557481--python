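"""Synthetic genotype, pedigree and population generators with known truth.

Every generator is driven by a single root seed and is fully deterministic:
the same configuration and seed produce bit-identical output.  Internally
each operation derives independent child streams from the root seed via
``numpy.random.SeedSequence`` so that adding draws to one stage never
perturbs another.

Generators provided:

* a two-cluster population under the Balding-Nichols model, for testing
  differentiation statistics at a controlled background F_ST with a
  handful of strongly differentiated outlier loci;
* a pedigree simulator with gene-dropped genotypes, where founder
  haplotypes carry unique labels so identity-by-descent (autozygosity) is
  known exactly;
* an ROH "planting" utility that writes a homozygous stretch into an
  existing genotype matrix;
* a diploid Wright-Fisher forward simulator with recombination, providing
  populations of known effective size for calibrating LD-based Ne
  estimators.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix, MarkerMap
from .pedigree import Pedigree

DEFAULT_GENERATION_INTERVAL_YEARS = 4.5


@dataclass
class SimConfig:
    """Configuration of the two-cluster Balding-Nichols generator.

    ``fst_background`` sets the expected differentiation of ordinary loci
    (the study-level divergence, ~0.05); ``n_outlier_loci`` loci instead use
    ``fst_outlier`` to emulate strongly selected regions.
    """

    n_individuals: int = 100  # per cluster
    n_snps: int = 5000
    n_chromosomes: int = 10
    chromosome_length_bp: int = 60_000_000
    fst_background: float = 0.05
    n_outlier_loci: int = 5
    fst_outlier: float = 0.4
    outlier_block_snps: int = 5
    maf_floor: float = 0.05
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fst_background", "fst_outlier", "maf_floor", "missing_rate"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        if self.n_snps < self.n_chromosomes:
            raise ValueError("need at least one SNP per chromosome")
        if self.outlier_block_snps < 1:
            raise ValueError("outlier_block_snps must be >= 1")
        if self.n_outlier_loci * self.outlier_block_snps > self.n_snps:
            raise ValueError("more outlier loci than SNPs")


@dataclass
class TwoClusterSim:
    genotypes: GenotypeMatrix
    cluster_labels: np.ndarray  # 0/1 per sample
    true_freqs: np.ndarray      # (2, n_snps) per-cluster allele frequencies
    ancestral_freqs: np.ndarray
    outlier_indices: np.ndarray   # every SNP drawn at the outlier F_ST
    outlier_blocks: list = field(default_factory=list)  # (start, end) index pairs

    @property
    def map(self) -> MarkerMap:
        return self.genotypes.map


@dataclass
class WrightFisherConfig:
    """Configuration of the diploid Wright-Fisher forward simulator."""

    ne_true: int = 100
    n_generations: int = 200
    n_snps: int = 400
    recomb_rate: float = 1e-8  # per bp per meiosis (1 cM/Mb)
    sample_size: int = 50
    chromosome_length_bp: int = 10_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ne_true < 2:
            raise ValueError("ne_true must be at least 2")
        if self.sample_size > self.ne_true:
            raise ValueError("sample_size cannot exceed the census size")


@dataclass
class WrightFisherSim:
    genotypes: GenotypeMatrix
    monomorphic: np.ndarray  # boolean per SNP, fixed in the sample

    @property
    def map(self) -> MarkerMap:
        return self.genotypes.map


@dataclass
class GeneDropSim:
    pedigree: Pedigree
    genotypes: GenotypeMatrix
    autozygous_fraction: dict  # id -> realized IBD fraction of the genome
    generation: dict           # id -> generation index (founders = 0)


def _jittered_positions(rng: np.random.Generator, n: int, length_bp: int) -> np.ndarray:
    """Evenly spaced 1-based positions with uniform jitter, strictly increasing."""
    spacing = length_bp / (n + 1)
    base = spacing * np.arange(1, n + 1)
    jitter = rng.uniform(-0.3 * spacing, 0.3 * spacing, size=n)
    pos = np.sort(np.round(base + jitter)).astype(np.int64)
    pos = np.maximum(pos, 1)
    # enforce strict monotonicity after rounding
    for i in range(1, n):
        if pos[i] <= pos[i - 1]:
            pos[i] = pos[i - 1] + 1
    return pos


def make_marker_map(rng: np.random.Generator, n_snps: int, n_chromosomes: int,
                    chromosome_length_bp: int) -> MarkerMap:
    per = np.full(n_chromosomes, n_snps // n_chromosomes, dtype=int)
    per[: n_snps % n_chromosomes] += 1
    chrom, bp, ids = [], [], []
    for c in range(n_chromosomes):
        pos = _jittered_positions(rng, int(per[c]), chromosome_length_bp)
        chrom.extend([c + 1] * int(per[c]))
        bp.extend(pos.tolist())
        ids.extend([f"snp{c + 1}_{i + 1}" for i in range(int(per[c]))])
    return MarkerMap(chrom=np.array(chrom), bp=np.array(bp),
                     snp_id=np.array(ids, dtype=object))


def simulate_two_cluster_genotypes(config: SimConfig) -> TwoClusterSim:
    """Two-cluster population under the Balding-Nichols model.

    Ancestral frequencies are uniform on [maf_floor, 1 - maf_floor]; each
    cluster's frequency at a locus is Beta(p(1-F)/F, (1-p)(1-F)/F) with
    F = ``fst_background`` (outlier loci use ``fst_outlier``), and F = 0
    means both clusters share the ancestral frequency exactly.  Genotypes
    are binomial(2, p_cluster) dosages with the configured missing rate.
    """
    root = np.random.SeedSequence(config.seed)
    s_map, s_freq, s_geno, s_miss = (np.random.default_rng(s) for s in root.spawn(4))

    m = config.n_snps
    mmap = make_marker_map(s_map, m, config.n_chromosomes, config.chromosome_length_bp)

    p_anc = s_freq.uniform(config.maf_floor, 1.0 - config.maf_floor, size=m)
    fst = np.full(m, config.fst_background)
    blocks = _draw_outlier_blocks(s_freq, mmap, config.n_outlier_loci,
                                  config.outlier_block_snps)
    outliers = (
        np.concatenate([np.arange(a, b + 1) for a, b in blocks])
        if blocks else np.array([], dtype=np.int64)
    )
    fst[outliers] = config.fst_outlier

    freqs = np.empty((2, m))
    for k in range(2):
        with np.errstate(divide="ignore"):
            a = p_anc * (1.0 - fst) / np.where(fst > 0, fst, 1.0)
            b = (1.0 - p_anc) * (1.0 - fst) / np.where(fst > 0, fst, 1.0)
        drawn = s_freq.beta(np.where(fst > 0, a, 1.0), np.where(fst > 0, b, 1.0))
        freqs[k] = np.where(fst > 0, drawn, p_anc)

    # Outlier blocks model divergent selection: the cluster frequencies are
    # displaced symmetrically around the ancestral frequency so the locus
    # sits at the target divergence (Wright's F_ST = delta^2 / p(1-p)),
    # rather than drifting freely -- a Beta draw at high F frequently sends
    # both clusters to the same extreme, which is differentiation in name
    # only.  The direction of displacement is randomised per block.
    for (a0, b0) in blocks:
        sign = 1 if s_freq.random() < 0.5 else -1
        for j in range(a0, b0 + 1):
            p = p_anc[j]
            delta = np.sqrt(config.fst_outlier * p * (1.0 - p))
            lo = np.clip(p - delta, 0.01, 0.99)
            hi = np.clip(p + delta, 0.01, 0.99)
            freqs[0, j], freqs[1, j] = (lo, hi) if sign > 0 else (hi, lo)

    n = config.n_individuals
    dos = np.empty((2 * n, m), dtype=np.int8)
    labels = np.repeat([0, 1], n)
    for k in range(2):
        dos[k * n:(k + 1) * n] = s_geno.binomial(2, freqs[k], size=(n, m))
    if config.missing_rate > 0:
        mask = s_miss.random(dos.shape) < config.missing_rate
        dos[mask] = MISSING

    ids = [f"c{labels[i] + 1}_{i + 1}" for i in range(2 * n)]
    gm = GenotypeMatrix(dosages=dos, sample_ids=ids, map=mmap)
    return TwoClusterSim(
        genotypes=gm,
        cluster_labels=labels,
        true_freqs=freqs,
        ancestral_freqs=p_anc,
        outlier_indices=outliers,
        outlier_blocks=blocks,
    )


def _draw_outlier_blocks(rng: np.random.Generator, mmap: MarkerMap,
                         n_blocks: int, block_snps: int) -> list:
    """Non-overlapping runs of ``block_snps`` consecutive same-chromosome
    markers, emulating the local extent of a differentiated (selected)
    haplotype region."""
    if n_blocks == 0:
        return []
    blocks: list = []
    taken = np.zeros(mmap.n_snps, dtype=bool)
    attempts = 0
    while len(blocks) < n_blocks:
        attempts += 1
        if attempts > 1000 * n_blocks:
            raise RuntimeError("could not place non-overlapping outlier blocks")
        start = int(rng.integers(mmap.n_snps - block_snps + 1))
        end = start + block_snps - 1
        if mmap.chrom[start] != mmap.chrom[end]:
            continue
        if taken[max(0, start - block_snps):end + block_snps + 1].any():
            continue  # keep a one-block guard gap between planted regions
        taken[start:end + 1] = True
        blocks.append((start, end))
    return sorted(blocks)


# ---------------------------------------------------------------------------
# pedigree + gene drop
# ---------------------------------------------------------------------------

class MatingError(RuntimeError):
    """Raised when the requested mating rule cannot find mates."""


def simulate_pedigree_with_genedrop(
    n_founders: int = 20,
    n_generations: int = 8,
    litter_size: int = 2,
    mating_rule: str = "random",
    seed: int = 0,
    n_snps: int = 1000,
    n_chromosomes: int = 5,
    chromosome_length_bp: int = 50_000_000,
    recomb_rate: float = 1e-8,
    offspring_per_generation: int | None = None,
    generation_interval_years: float = DEFAULT_GENERATION_INTERVAL_YEARS,
    start_date: str = "1990-01-01",
) -> GeneDropSim:
    """Closed-line pedigree with gene-dropped genotypes and known IBD.

    Founders are unrelated and non-inbred.  Each non-founder generation is
    produced under ``mating_rule``:

    * ``"random"`` — each litter has a random sire and random dam from the
      previous generation (a closed random-mating line of roughly constant
      census size);
    * ``"full_sib"`` — a single brother-sister pair per generation, giving
      the textbook repeated-full-sib inbreeding series F = 0.25, 0.375, ...

    Founder chromosomes carry globally unique haplotype labels; gametes are
    formed with Poisson crossovers at ``recomb_rate`` per bp, so each
    individual's realized autozygous (identical-label) genome fraction is
    known exactly and is returned as ground truth.  Labels are collapsed to
    biallelic dosages using founder-haplotype allele assignments with
    uniform frequencies on [0.2, 0.8].
    """
    if n_founders < 2:
        raise ValueError("need at least two founders")
    root = np.random.SeedSequence(seed)
    s_map, s_allele, s_mate, s_drop = (np.random.default_rng(s) for s in root.spawn(4))

    mmap = make_marker_map(s_map, n_snps, n_chromosomes, chromosome_length_bp)
    chrom_idx = [mmap.chrom_indices(c) for c in mmap.chromosomes()]

    # founder haplotype labels (unique) and their biallelic allele states
    n_hap = 2 * n_founders
    q = s_allele.uniform(0.2, 0.8, size=n_snps)
    hap_alleles = (s_allele.random((n_hap, n_snps)) < q).astype(np.int8)

    interval_days = int(round(generation_interval_years * 365.25))
    t0 = pd.Timestamp(start_date)

    # per-individual pair of label arrays over all SNPs
    haplos: dict = {}
    records = []
    generation: dict = {}
    sexes: dict = {}

    founders = [f"G0_{i + 1}" for i in range(n_founders)]
    for i, iid in enumerate(founders):
        haplos[iid] = np.vstack([
            np.full(n_snps, 2 * i, dtype=np.int32),
            np.full(n_snps, 2 * i + 1, dtype=np.int32),
        ])
        records.append((iid, None, None, t0))
        generation[iid] = 0
        sexes[iid] = i % 2  # 0 = male, 1 = female

    def gamete(parent_id: str) -> np.ndarray:
        """One recombinant haplotype label array from ``parent_id``."""
        hp = haplos[parent_id]
        out = np.empty(n_snps, dtype=np.int32)
        for idx in chrom_idx:
            pos = mmap.bp[idx]
            length = int(pos[-1] - pos[0]) if idx.size > 1 else 0
            n_x = s_drop.poisson(recomb_rate * length) if length > 0 else 0
            cuts = np.sort(s_drop.uniform(pos[0], pos[-1], size=n_x)) if n_x else np.empty(0)
            which = (np.searchsorted(cuts, pos, side="right") + s_drop.integers(2)) % 2
            out[idx] = np.where(which == 0, hp[0, idx], hp[1, idx])
        return out

    prev = founders
    target = offspring_per_generation or n_founders
    for g in range(1, n_generations + 1):
        males = [i for i in prev if sexes[i] == 0]
        females = [i for i in prev if sexes[i] == 1]
        if mating_rule == "full_sib":
            if g == 1:
                pairs = [(founders[0], founders[1])]
            else:
                sibs = prev
                m = [i for i in sibs if sexes[i] == 0]
                f = [i for i in sibs if sexes[i] == 1]
                if not m or not f:
                    raise MatingError(f"generation {g}: no opposite-sex full sibs")
                pairs = [(m[0], f[0])]
            n_off = max(litter_size, 2)
        elif mating_rule == "random":
            if not males or not females:
                raise MatingError(f"generation {g}: need both sexes to mate")
            n_off = target
            pairs = None
        else:
            raise ValueError(f"unknown mating rule {mating_rule!r}")

        birth = t0 + pd.Timedelta(days=g * interval_days)
        offspring = []
        made = 0
        while made < n_off:
            if mating_rule == "full_sib":
                sire, dam = pairs[0]
            else:
                sire = males[s_mate.integers(len(males))]
                dam = females[s_mate.integers(len(females))]
            for _ in range(min(litter_size, n_off - made)):
                iid = f"G{g}_{made + 1}"
                haplos[iid] = np.vstack([gamete(sire), gamete(dam)])
                records.append((iid, sire, dam, birth))
                generation[iid] = g
                sexes[iid] = made % 2  # alternate: balanced sex ratio
                offspring.append(iid)
                made += 1
        # full-sib line needs both sexes among offspring
        if mating_rule == "full_sib":
            sexes[offspring[0]] = 0
            sexes[offspring[1]] = 1
        prev = offspring

    ped = Pedigree(records)
    ids = [r[0] for r in records]
    dos = np.empty((len(ids), n_snps), dtype=np.int8)
    autoz: dict = {}
    for i, iid in enumerate(ids):
        h0, h1 = haplos[iid]
        cols = np.arange(n_snps)
        a0 = hap_alleles[h0, cols]
        a1 = hap_alleles[h1, cols]
        dos[i] = (a0 + a1).astype(np.int8)
        autoz[iid] = float(np.mean(h0 == h1))
    gm = GenotypeMatrix(dosages=dos, sample_ids=ids, map=mmap)
    return GeneDropSim(pedigree=ped, genotypes=gm,
                       autozygous_fraction=autoz, generation=generation)


def plant_roh(gm: GenotypeMatrix, individual, chrom: int, start_bp: int,
              end_bp: int, fill_dosage: int = 0) -> GenotypeMatrix:
    """Return a copy of ``gm`` with one homozygous stretch written in.

    All SNPs of ``individual`` on ``chrom`` with start_bp <= bp <= end_bp
    become homozygous: heterozygous and missing calls are replaced by
    ``fill_dosage`` (0 or 2, i.e. one haplotype copied through the region);
    calls already homozygous are left as they are.  Everything outside the
    interval is untouched.  An empty interval returns an identical copy.
    """
    if fill_dosage not in (0, 2):
        raise ValueError("fill_dosage must be a homozygous dosage (0 or 2)")
    i = gm.sample_index(individual)
    if chrom not in gm.map.chrom:
        raise KeyError(f"unknown chromosome {chrom!r}")
    idx = gm.map.chrom_indices(chrom)
    sel = idx[(gm.map.bp[idx] >= start_bp) & (gm.map.bp[idx] <= end_bp)]
    dos = gm.dosages.copy()
    row = dos[i, sel]
    row[(row == 1) | (row == MISSING)] = fill_dosage
    dos[i, sel] = row
    return GenotypeMatrix(dosages=dos, sample_ids=list(gm.sample_ids), map=gm.map)


# ---------------------------------------------------------------------------
# Wright-Fisher forward simulation
# ---------------------------------------------------------------------------

def simulate_wright_fisher(config: WrightFisherConfig) -> WrightFisherSim:
    """Forward simulation of a diploid Wright-Fisher population.

    2 * ``ne_true`` haplotypes evolve for ``n_generations`` with random
    union of gametes and Poisson-free per-interval recombination (adjacent
    loci recombine with probability distance * ``recomb_rate``, capped at
    1/2).  Loci start at frequency 1/2.  The final generation is sampled
    for ``sample_size`` diploids; loci fixed in the sample are flagged
    monomorphic.
    """
    root = np.random.SeedSequence(config.seed)
    s_map, s_init, s_evo, s_samp = (np.random.default_rng(s) for s in root.spawn(4))

    L = config.n_snps
    N = config.ne_true
    mmap = make_marker_map(s_map, L, 1, config.chromosome_length_bp)
    c_adj = np.minimum(np.diff(mmap.bp) * config.recomb_rate, 0.5)

    haps = (s_init.random((2 * N, L)) < 0.5).astype(np.int8)
    for _ in range(config.n_generations):
        parents = s_evo.integers(N, size=2 * N)  # gamete g comes from parents[g]
        switch = s_evo.random((2 * N, L - 1)) < c_adj
        start = s_evo.integers(2, size=(2 * N, 1))
        which = (start + np.concatenate(
            [np.zeros((2 * N, 1), dtype=np.int64), np.cumsum(switch, axis=1)], axis=1
        )) % 2
        a = haps[2 * parents]
        b = haps[2 * parents + 1]
        haps = np.where(which == 0, a, b).astype(np.int8)

    chosen = s_samp.choice(N, size=config.sample_size, replace=False)
    dos = (haps[2 * chosen] + haps[2 * chosen + 1]).astype(np.int8)
    freqs = dos.mean(axis=0) / 2.0
    mono = (freqs == 0.0) | (freqs == 1.0)
    if mono.all():
        warnings.warn("all loci fixed in the sampled population; no usable markers")
    ids = [f"wf_{i + 1}" for i in range(config.sample_size)]
    gm = GenotypeMatrix(dosages=dos, sample_ids=ids, map=mmap)
    return WrightFisherSim(genotypes=gm, monomorphic=mono)


def write_ground_truth(path, **payload) -> None:
    """JSON sidecar with simulation ground truth (frequencies, Ne, ROH...)."""

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON serialisable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=default)
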