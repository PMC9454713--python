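"""Genotype container and plain-text SNP file I/O.

Dosages are stored as an ``int8`` animals x SNPs matrix coded 0/1/2 with
``MISSING`` (-1) for no-calls, alongside a marker map (snp id, chromosome
label, physical bp position).  Chromosome labels are strings; ``"0"`` means
unmapped and ``"X"``/``"Y"`` are the sex chromosomes.

PLINK PED/MAP text pairs are read and written directly (alleles A/B,
missing ``0 0``); a simple dosage-matrix TSV is supported as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

MISSING = np.int8(-1)

__all__ = ["GenotypeSet", "MISSING", "read_plink", "write_plink"]


@dataclass
class GenotypeSet:
    """Animals x SNPs dosage matrix plus marker map.

    Attributes
    ----------
    dosages : ndarray of int8, shape (n_animals, n_snps)
        Allele counts 0/1/2; -1 marks a missing call.
    animal_ids : ndarray
    snp_map : DataFrame with columns ``snp``, ``chrom`` (str), ``bp`` (int)
    """

    dosages: np.ndarray
    animal_ids: np.ndarray
    snp_map: pd.DataFrame

    def __post_init__(self) -> None:
        if self.dosages.shape != (len(self.animal_ids), len(self.snp_map)):
            raise ValueError(
                f"dosage matrix {self.dosages.shape} does not match "
                f"{len(self.animal_ids)} animals x {len(self.snp_map)} SNPs"
            )
        self.snp_map = self.snp_map.reset_index(drop=True)
        self.snp_map["chrom"] = self.snp_map["chrom"].astype(str)

    @property
    def n_animals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def snp_call_rate(self) -> np.ndarray:
        return (self.dosages != MISSING).mean(axis=0)

    def animal_call_rate(self) -> np.ndarray:
        return (self.dosages != MISSING).mean(axis=1)

    def allele_freq(self) -> np.ndarray:
        """Observed alternative-allele frequency per SNP (missing excluded)."""
        d = self.dosages
        ok = d != MISSING
        with np.errstate(invalid="ignore"):
            return np.where(ok, d, 0).sum(axis=0) / (2.0 * ok.sum(axis=0))

    def take_snps(self, mask_or_idx) -> "GenotypeSet":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return replace(
            self,
            dosages=self.dosages[:, idx],
            snp_map=self.snp_map.iloc[idx].reset_index(drop=True),
        )

    def take_animals(self, mask_or_idx) -> "GenotypeSet":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return replace(
            self, dosages=self.dosages[idx], animal_ids=self.animal_ids[idx]
        )


def write_plink(gset: GenotypeSet, prefix: str, sex=None) -> None:
    """Write a PED/MAP text pair (alleles coded A/B, missing 0 0)."""
    mp = gset.snp_map
    with open(f"{prefix}.map", "w") as fh:
        for _, r in mp.iterrows():
            fh.write(f"{r['chrom']}\t{r['snp']}\t0\t{int(r['bp'])}\n")
    allele = {0: "A A", 1: "A B", 2: "B B", -1: "0 0"}
    with open(f"{prefix}.ped", "w") as fh:
        for i, aid in enumerate(gset.animal_ids):
            sx = 0 if sex is None else sex[i]
            row = " ".join(allele[int(d)] for d in gset.dosages[i])
            fh.write(f"FAM {aid} 0 0 {sx} -9 {row}\n")


def read_plink(prefix: str) -> GenotypeSet:
    """Read a PED/MAP text pair written by :func:`write_plink` (or compatible)."""
    mp = pd.read_csv(
        f"{prefix}.map",
        sep=r"\s+",
        header=None,
        names=["chrom", "snp", "cm", "bp"],
        dtype={"chrom": str},
    )
    snp_map = mp[["snp", "chrom", "bp"]].copy()
    ids = []
    rows = []
    n_snps = len(snp_map)
    with open(f"{prefix}.ped") as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if len(parts) != 6 + 2 * n_snps:
                raise ValueError(
                    f"{prefix}.ped line {lineno}: expected {6 + 2 * n_snps} "
                    f"fields, got {len(parts)}"
                )
            ids.append(parts[1])
            a = parts[6::2]
            b = parts[7::2]
            dos = np.full(n_snps, MISSING, dtype=np.int8)
            for j, (x, y) in enumerate(zip(a, b)):
                if x == "0" or y == "0":
                    continue
                dos[j] = (x == "B") + (y == "B")
            rows.append(dos)
    ids_arr = np.array(ids)
    try:  # numeric animal ids round-trip as integers
        ids_arr = ids_arr.astype(np.int64)
    except ValueError:
        pass
    return GenotypeSet(np.array(rows, dtype=np.int8), ids_arr, snp_map)
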