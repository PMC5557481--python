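"""Genotype quality control: call-rate, MAF and Hardy-Weinberg filters.

The cascade mirrors standard SNP-array practice: low-call-rate samples are
dropped first, then markers failing call-rate, minor-allele-frequency,
autosome and Hardy-Weinberg-equilibrium rules, in that order, each rule
counted on the matrix it receives.  All thresholds are strict inequalities
in the removal direction (a marker exactly at a call-rate threshold is
retained).

Intensity-based marker rules used by genotyping-platform software (GenTrain
score, AB R mean) require raw intensity data and are therefore reported as
not applicable for dosage-level input.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .core import GenotypeMatrix

#: Chromosome codes treated as non-autosomal under the canine array coding
#: (X, Y, pseudo-autosomal, MT; 0 = unplaced).
DEFAULT_SEX_CHROMOSOMES: tuple = (0, 39, 40, 41, 42)


@dataclass
class QCThresholds:
    """Thresholds for the QC cascade.

    Defaults follow common array-QC practice for a high-density canine
    panel: samples below 95% call rate are removed, then markers with call
    rate < 98%, MAF < 0.01, non-autosomal placement, or an exact
    Hardy-Weinberg test p-value below a Bonferroni-style cutoff of 8.0e-8.
    """

    sample_call_rate_min: float = 0.95
    marker_call_rate_min: float = 0.98
    maf_min: float = 0.01
    hwe_alpha: float = 8.0e-8
    autosomes_only: bool = True
    sex_chromosomes: tuple = DEFAULT_SEX_CHROMOSOMES


@dataclass
class QCReport:
    """Removal counts per rule, in application order."""

    n_samples_in: int
    n_markers_in: int
    n_samples_removed: int = 0
    n_markers_removed_by_rule: dict = field(default_factory=dict)
    not_applicable_rules: tuple = ("gentrain_score", "ab_r_mean")
    n_samples_out: int = 0
    n_markers_out: int = 0

    def validate(self) -> None:
        if self.n_samples_in - self.n_samples_removed != self.n_samples_out:
            raise AssertionError("sample removal counts do not partition")
        removed = sum(self.n_markers_removed_by_rule.values())
        if self.n_markers_in - removed != self.n_markers_out:
            raise AssertionError("marker removal counts do not partition")

    def to_json(self, path=None) -> str:
        payload = {
            "n_samples_in": self.n_samples_in,
            "n_markers_in": self.n_markers_in,
            "n_samples_removed": self.n_samples_removed,
            "n_markers_removed_by_rule": self.n_markers_removed_by_rule,
            "not_applicable_rules": list(self.not_applicable_rules),
            "n_samples_out": self.n_samples_out,
            "n_markers_out": self.n_markers_out,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def hwe_exact_test(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Exact test of Hardy-Weinberg proportions for one biallelic locus.

    Conditions on the observed allele counts and sums, over all possible
    heterozygote counts, the probabilities of outcomes no more probable than
    the observed one (the standard two-sided exact SNP-HWE test).  Returns a
    p-value in (0, 1]; a monomorphic locus returns 1 by convention.
    """
    if min(n_hom1, n_het, n_hom2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom1 + n_het + n_hom2
    if n < 1:
        raise ValueError("at least one genotyped individual required")
    # rare-allele copy count; the test is symmetric in the two homozygotes
    r = min(2 * n_hom1 + n_het, 2 * n_hom2 + n_het)
    if r == 0:
        return 1.0
    ks = np.arange(r % 2, r + 1, 2)
    # exclude configurations needing more common-allele copies than exist
    ks = ks[(2 * n - r - ks) >= 0]
    log_probs = (
        gammaln(n + 1)
        - gammaln((r - ks) / 2 + 1)
        - gammaln(ks + 1)
        - gammaln((2 * n - r - ks) / 2 + 1)
        + ks * np.log(2.0)
        - (gammaln(2 * n + 1) - gammaln(r + 1) - gammaln(2 * n - r + 1))
    )
    probs = np.exp(log_probs)
    probs /= probs.sum()  # guard against rounding drift
    p_obs = probs[np.flatnonzero(ks == n_het)[0]]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def genotype_counts(gm: GenotypeMatrix) -> np.ndarray:
    """(n_markers, 3) array of hom-coded / het / hom-other counts."""
    counts = np.empty((gm.n_snps, 3), dtype=np.int64)
    counts[:, 0] = (gm.dosages == 2).sum(axis=0)
    counts[:, 1] = (gm.dosages == 1).sum(axis=0)
    counts[:, 2] = (gm.dosages == 0).sum(axis=0)
    return counts


def hwe_pvalues(gm: GenotypeMatrix) -> np.ndarray:
    counts = genotype_counts(gm)
    out = np.ones(gm.n_snps)
    for j in range(gm.n_snps):
        if counts[j].sum() > 0:
            out[j] = hwe_exact_test(*counts[j])
    return out


def apply_qc(gm: GenotypeMatrix, thresholds: QCThresholds | None = None):
    """Run the full QC cascade; returns ``(filtered_matrix, QCReport)``.

    Rules run in order: sample call rate, marker call rate, MAF,
    autosome restriction, Hardy-Weinberg exact test.  Each marker rule is
    evaluated on the matrix surviving the previous rules.  Setting a
    threshold to 0 (or ``autosomes_only=False``) disables the rule.
    """
    thr = thresholds or QCThresholds()
    report = QCReport(n_samples_in=gm.n_samples, n_markers_in=gm.n_snps)

    # 1. sample call rate
    keep_samples = np.flatnonzero(gm.sample_call_rate() >= thr.sample_call_rate_min)
    report.n_samples_removed = gm.n_samples - keep_samples.size
    out = gm.subset(samples=keep_samples) if report.n_samples_removed else gm

    def drop_markers(mat: GenotypeMatrix, bad: np.ndarray, rule: str) -> GenotypeMatrix:
        report.n_markers_removed_by_rule[rule] = int(bad.sum())
        if bad.any():
            return mat.subset(markers=np.flatnonzero(~bad))
        return mat

    # 2. marker call rate
    if out.n_samples > 0:
        bad = out.marker_call_rate() < thr.marker_call_rate_min
    else:
        bad = np.zeros(out.n_snps, dtype=bool)
    out = drop_markers(out, bad, "marker_call_rate")

    # 3. MAF (on non-missing calls; markers with no calls have nan maf -> kept
    #    only because rule 2 already removed them at any positive threshold)
    maf = out.maf()
    bad = np.nan_to_num(maf, nan=1.0) < thr.maf_min
    out = drop_markers(out, bad, "maf")

    # 4. autosomes
    if thr.autosomes_only:
        bad = np.isin(out.map.chrom, thr.sex_chromosomes)
    else:
        bad = np.zeros(out.n_snps, dtype=bool)
    out = drop_markers(out, bad, "sex_chromosome")

    # 5. HWE
    if thr.hwe_alpha > 0 and out.n_samples > 0:
        bad = hwe_pvalues(out) < thr.hwe_alpha
    else:
        bad = np.zeros(out.n_snps, dtype=bool)
    out = drop_markers(out, bad, "hwe")

    report.n_samples_out = out.n_samples
    report.n_markers_out = out.n_snps
    report.validate()
    return out, report
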