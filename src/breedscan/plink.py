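"""Text PED/MAP reading and writing, plus pedigree and label CSV helpers.

The dialect is the classic whitespace-delimited text format: each PED line is
``FID IID PAT MAT SEX PHENO`` followed by two allele columns per SNP, with
``0 0`` marking a missing call; the MAP file has one ``chrom snp_id cm bp``
line per SNP in the same column order.

On reading, genotypes are collapsed to dosages of the minor allele as
computed from the data itself (ties broken toward the lexicographically
smaller allele label).
"""

from __future__ import annotations

from collections import Counter

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix, MarkerMap


def read_map(map_path) -> MarkerMap:
    rows = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4:
                raise ValueError(f"{map_path}:{lineno}: expected 4 columns, got {len(parts)}")
            rows.append((int(parts[0]), parts[1], float(parts[2]), int(parts[3])))
    chrom, snp_id, cm, bp = zip(*rows)
    return MarkerMap(chrom=np.array(chrom), bp=np.array(bp),
                     snp_id=np.array(snp_id, dtype=object), cm=np.array(cm))


def read_ped_map(ped_path, map_path) -> GenotypeMatrix:
    """Read a PED/MAP pair into a :class:`GenotypeMatrix`.

    Raises ``ValueError`` naming the offending line on ragged rows, allele
    column counts inconsistent with the MAP, or duplicate sample ids.
    """
    mmap = read_map(map_path)
    m = mmap.n_snps
    sample_ids: list = []
    allele_rows: list = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 6:
                raise ValueError(f"{ped_path}:{lineno}: fewer than 6 leading columns")
            alleles = parts[6:]
            if len(alleles) != 2 * m:
                raise ValueError(
                    f"{ped_path}:{lineno}: expected {2 * m} allele columns, got {len(alleles)}"
                )
            iid = parts[1]
            if iid in sample_ids:
                raise ValueError(f"{ped_path}:{lineno}: duplicate sample id {iid!r}")
            sample_ids.append(iid)
            allele_rows.append(alleles)

    n = len(sample_ids)
    a = np.array(allele_rows, dtype=object).reshape(n, m, 2) if n else np.empty((0, m, 2), object)

    dosages = np.full((n, m), MISSING, dtype=np.int8)
    allele1 = np.empty(m, dtype=object)
    allele2 = np.empty(m, dtype=object)
    for j in range(m):
        col = a[:, j, :]
        missing = (col[:, 0] == "0") | (col[:, 1] == "0")
        counts = Counter(col[~missing].ravel().tolist())
        labels = sorted(counts)  # lexicographic tiebreak
        if len(labels) > 2:
            raise ValueError(f"{ped_path}: marker {mmap.snp_id[j]} has >2 alleles")
        if not labels:
            allele1[j], allele2[j] = "A", "B"
            continue
        if len(labels) == 1:
            minor, major = labels[0], labels[0]
        else:
            # minor = least frequent; lexicographic on ties
            minor = min(labels, key=lambda x: (counts[x], x))
            major = labels[0] if minor == labels[1] else labels[1]
        allele1[j], allele2[j] = minor, major
        dos = (col[:, 0] == minor).astype(np.int8) + (col[:, 1] == minor).astype(np.int8)
        if minor == major:
            dos = np.zeros(n, dtype=np.int8)
        dosages[~missing, j] = dos[~missing]

    mmap = MarkerMap(chrom=mmap.chrom, bp=mmap.bp, snp_id=mmap.snp_id, cm=mmap.cm,
                     allele1=allele1, allele2=allele2)
    return GenotypeMatrix(dosages=dosages, sample_ids=sample_ids, map=mmap)


def write_ped_map(gm: GenotypeMatrix, ped_path, map_path) -> None:
    """Write a genotype matrix as a text PED/MAP pair.

    Dosage d is emitted as d copies of ``allele1`` and 2-d of ``allele2``;
    missing calls as ``0 0``.
    """
    mmap = gm.map
    with open(map_path, "w") as fh:
        for j in range(mmap.n_snps):
            fh.write(f"{mmap.chrom[j]}\t{mmap.snp_id[j]}\t{mmap.cm[j]:g}\t{mmap.bp[j]}\n")
    a1, a2 = mmap.allele1, mmap.allele2
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(gm.sample_ids):
            fields = [str(sid), str(sid), "0", "0", "0", "-9"]
            row = gm.dosages[i]
            for j in range(gm.n_snps):
                d = row[j]
                if d == MISSING:
                    fields += ["0", "0"]
                elif d == 0:
                    fields += [str(a2[j]), str(a2[j])]
                elif d == 1:
                    fields += [str(a1[j]), str(a2[j])]
                else:
                    fields += [str(a1[j]), str(a1[j])]
            fh.write(" ".join(fields) + "\n")


def read_pedigree_csv(path) -> pd.DataFrame:
    """Read a pedigree CSV (id, sire, dam, birthdate; empty field = unknown)."""
    df = pd.read_csv(path, dtype={"id": str, "sire": str, "dam": str})
    for col in ("id", "sire", "dam"):
        if col not in df.columns:
            raise ValueError(f"pedigree CSV missing column {col!r}")
    if "birthdate" in df.columns:
        df["birthdate"] = pd.to_datetime(df["birthdate"], errors="coerce")
    return df


def write_pedigree_csv(df: pd.DataFrame, path) -> None:
    out = df.copy()
    if "birthdate" in out.columns:
        out["birthdate"] = pd.to_datetime(out["birthdate"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_labels_csv(path) -> pd.DataFrame:
    """Read a sample label / membership-coefficient CSV (id plus data columns)."""
    df = pd.read_csv(path, dtype={"id": str})
    if "id" not in df.columns:
        raise ValueError("labels CSV missing 'id' column")
    return df
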