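"""Core in-memory containers for SNP-array genotype data.

Genotypes are held as a dense samples x SNPs dosage matrix with values in
{0, 1, 2} counting copies of the coded (by convention, minor) allele, and a
single sentinel :data:`MISSING` for no-calls.  Marker metadata lives in a
:class:`MarkerMap` whose positions are 1-based base pairs, strictly
increasing within each chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype call in a dosage matrix.
MISSING: int = -1


@dataclass
class MarkerMap:
    """Per-SNP chromosome, identifier, genetic and physical position.

    Parameters
    ----------
    chrom
        Integer chromosome codes, grouped (all markers of a chromosome are
        contiguous in array order).
    bp
        1-based physical positions, strictly increasing within chromosome.
    snp_id
        Unique marker identifiers.
    cm
        Genetic positions in centimorgans (0 when unknown, as in MAP files).
    allele1, allele2
        Allele labels; ``allele1`` is the coded allele of the dosage matrix.
    """

    chrom: np.ndarray
    bp: np.ndarray
    snp_id: np.ndarray
    cm: np.ndarray = field(default=None)  # type: ignore[assignment]
    allele1: np.ndarray = field(default=None)  # type: ignore[assignment]
    allele2: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=np.int64)
        self.bp = np.asarray(self.bp, dtype=np.int64)
        self.snp_id = np.asarray(self.snp_id, dtype=object)
        n = self.chrom.size
        if self.bp.size != n or self.snp_id.size != n:
            raise ValueError("marker map columns have inconsistent lengths")
        if self.cm is None:
            self.cm = np.zeros(n, dtype=float)
        else:
            self.cm = np.asarray(self.cm, dtype=float)
        if self.allele1 is None:
            self.allele1 = np.asarray(["A"] * n, dtype=object)
        else:
            self.allele1 = np.asarray(self.allele1, dtype=object)
        if self.allele2 is None:
            self.allele2 = np.asarray(["B"] * n, dtype=object)
        else:
            self.allele2 = np.asarray(self.allele2, dtype=object)
        self._validate_sorted()

    def _validate_sorted(self) -> None:
        for c in np.unique(self.chrom):
            pos = self.bp[self.chrom == c]
            if pos.size > 1 and not np.all(np.diff(pos) > 0):
                raise ValueError(
                    f"positions on chromosome {c} are not strictly increasing"
                )

    @property
    def n_snps(self) -> int:
        return int(self.chrom.size)

    def chromosomes(self) -> np.ndarray:
        """Chromosome codes in order of first appearance."""
        _, idx = np.unique(self.chrom, return_index=True)
        return self.chrom[np.sort(idx)]

    def chrom_indices(self, c: int) -> np.ndarray:
        """Array indices of the markers on chromosome ``c`` (map order)."""
        return np.flatnonzero(self.chrom == c)

    def subset(self, idx: np.ndarray) -> "MarkerMap":
        idx = np.asarray(idx)
        return MarkerMap(
            chrom=self.chrom[idx],
            bp=self.bp[idx],
            snp_id=self.snp_id[idx],
            cm=self.cm[idx],
            allele1=self.allele1[idx],
            allele2=self.allele2[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "snp_id": self.snp_id,
                "cm": self.cm,
                "bp": self.bp,
                "allele1": self.allele1,
                "allele2": self.allele2,
            }
        )


@dataclass
class GenotypeMatrix:
    """Samples x SNPs dosage matrix with sample identifiers and marker map.

    ``dosages[i, j]`` counts copies of the coded allele of SNP ``j`` carried
    by sample ``i`` (0, 1 or 2), or :data:`MISSING`.
    """

    dosages: np.ndarray
    sample_ids: list
    map: MarkerMap

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        self.sample_ids = list(self.sample_ids)
        if self.dosages.ndim != 2:
            raise ValueError("dosage matrix must be 2-D (samples x SNPs)")
        if self.dosages.shape[0] != len(self.sample_ids):
            raise ValueError("number of sample ids does not match matrix rows")
        if self.dosages.shape[1] != self.map.n_snps:
            raise ValueError("marker map length does not match matrix columns")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def called(self) -> np.ndarray:
        """Boolean mask of non-missing calls."""
        return self.dosages != MISSING

    def sample_call_rate(self) -> np.ndarray:
        return self.called().mean(axis=1)

    def marker_call_rate(self) -> np.ndarray:
        return self.called().mean(axis=0)

    def allele_frequency(self) -> np.ndarray:
        """Frequency of the coded allele per marker, over non-missing calls.

        Markers with no calls get ``nan``.
        """
        called = self.called()
        n_called = called.sum(axis=0)
        dos = np.where(called, self.dosages, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_called > 0, dos / (2.0 * n_called), np.nan)

    def maf(self) -> np.ndarray:
        """Minor allele frequency per marker (nan where no calls)."""
        p = self.allele_frequency()
        return np.minimum(p, 1.0 - p)

    def subset(self, samples=None, markers=None) -> "GenotypeMatrix":
        """New matrix restricted to the given sample/marker index arrays."""
        dos = self.dosages
        ids = self.sample_ids
        mmap = self.map
        if samples is not None:
            samples = np.asarray(samples)
            dos = dos[samples, :]
            ids = [self.sample_ids[i] for i in samples]
        if markers is not None:
            markers = np.asarray(markers)
            dos = dos[:, markers]
            mmap = mmap.subset(markers)
        return GenotypeMatrix(dosages=dos.copy(), sample_ids=ids, map=mmap)

    def sample_index(self, sample_id) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample id: {sample_id!r}") from None
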