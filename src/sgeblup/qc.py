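"""Genotype quality control with per-filter bookkeeping.

SNP filters, applied in order with first-failure attribution:

1. unmapped (chromosome ``"0"`` or unplaced) or on a sex chromosome;
2. call rate < 0.90;
3. minor allele frequency < 0.05;
4. monomorphic.

Animal filters (after SNP filters, on the surviving matrix):

5. call rate < 0.90;
6. Mendelian conflicts: opposing-homozygote dosages in a genotyped
   parent-offspring duo, animal removed when the conflict rate across its
   testable duo-SNPs exceeds a threshold (default 1%).

A single pass is made: rates are computed on the matrix current at each
filter stage and not iterated.  All boundaries are strict inequalities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .genotypes import MISSING, GenotypeSet
from .pedigree import Pedigree

SEX_CHROMS = {"X", "Y", "XY", "MT", "19", "20"}  # pig: 18 autosomes
UNMAPPED = {"0", "U", "UN", "NA"}

__all__ = ["QcReport", "filter_snps", "filter_animals", "run_qc"]


@dataclass
class QcReport:
    """Removal counts and id lists per filter, in application order."""

    input_shape: tuple
    removed: dict = field(default_factory=dict)  # filter name -> list of ids
    output_shape: tuple = None

    def counts(self) -> dict:
        return {k: len(v) for k, v in self.removed.items()}

    def n_removed(self) -> int:
        return sum(len(v) for v in self.removed.values())

    def to_json(self, path=None) -> str:
        payload = {
            "input_shape": list(self.input_shape),
            "output_shape": list(self.output_shape),
            "removed_counts": self.counts(),
            "removed_ids": {k: [str(x) for x in v] for k, v in self.removed.items()},
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def summary(self) -> str:
        lines = [f"input: {self.input_shape[0]} animals x {self.input_shape[1]} SNPs"]
        for k, v in self.removed.items():
            lines.append(f"  removed by {k}: {len(v)}")
        lines.append(
            f"output: {self.output_shape[0]} animals x {self.output_shape[1]} SNPs"
        )
        return "\n".join(lines)


def filter_snps(gset: GenotypeSet) -> tuple[GenotypeSet, QcReport]:
    """Apply the four SNP filters; first failing criterion gets the removal."""
    report = QcReport(input_shape=gset.dosages.shape)
    n = gset.n_snps
    chroms = gset.snp_map["chrom"].to_numpy()
    unmapped = np.isin(chroms, list(UNMAPPED)) | np.isin(chroms, list(SEX_CHROMS))
    call = gset.snp_call_rate()
    freq = gset.allele_freq()
    with np.errstate(invalid="ignore"):
        maf = np.minimum(freq, 1.0 - freq)
    mono = np.zeros(n, dtype=bool)
    for j in range(n):
        col = gset.dosages[:, j]
        obs = np.unique(col[col != MISSING])
        mono[j] = len(obs) <= 1
    # first-failure attribution in the listed order
    assigned = np.zeros(n, dtype=bool)
    snps = gset.snp_map["snp"].to_numpy()
    # a fixed SNP (maf == 0) belongs to the monomorphic category, not the
    # MAF filter, mirroring how the criteria are listed separately
    for name, mask in [
        ("unmapped_or_sex_chrom", unmapped),
        ("snp_call_rate_lt_0.90", call < 0.90),
        ("maf_lt_0.05", (maf < 0.05) & ~mono),
        ("monomorphic", mono),
    ]:
        hit = mask & ~assigned
        report.removed[name] = snps[hit].tolist()
        assigned |= hit
    out = gset.take_snps(~assigned)
    if out.n_snps == 0:
        raise ValueError("QC removed every SNP")
    report.output_shape = out.dosages.shape
    return out, report


def mendelian_conflicts(
    gset: GenotypeSet, ped: Pedigree
) -> tuple[np.ndarray, np.ndarray]:
    """Per-animal counts of opposing-homozygote conflicts and testable duo-SNPs.

    A conflict is dosage (0, 2) or (2, 0) between a genotyped animal and a
    genotyped parent; each parent duo is tested independently and conflicts
    are attributed to the offspring.
    """
    gpos = {a: i for i, a in enumerate(gset.animal_ids)}
    n = gset.n_animals
    conflicts = np.zeros(n, dtype=np.int64)
    tested = np.zeros(n, dtype=np.int64)
    ids = ped.ids
    for row in range(len(ped)):
        child = ids[row]
        if child not in gpos:
            continue
        ci = gpos[child]
        for pidx in (ped.sire_idx[row], ped.dam_idx[row]):
            if pidx < 0 or ids[pidx] not in gpos:
                continue
            pi = gpos[ids[pidx]]
            c = gset.dosages[ci]
            p = gset.dosages[pi]
            ok = (c != MISSING) & (p != MISSING)
            tested[ci] += int(ok.sum())
            conflicts[ci] += int((ok & (np.abs(c - p) == 2) & ((c == 0) | (c == 2))).sum())
    return conflicts, tested


def filter_animals(
    gset: GenotypeSet, ped: Pedigree | None = None, conflict_threshold: float = 0.01
) -> tuple[GenotypeSet, QcReport]:
    """Remove animals with call rate < 0.90 or excess Mendelian conflicts."""
    report = QcReport(input_shape=gset.dosages.shape)
    call_fail = gset.animal_call_rate() < 0.90
    report.removed["animal_call_rate_lt_0.90"] = gset.animal_ids[call_fail].tolist()
    survivors = gset.take_animals(~call_fail)
    if ped is not None:
        conf, tested = mendelian_conflicts(survivors, ped)
        with np.errstate(invalid="ignore"):
            rate = np.where(tested > 0, conf / np.maximum(tested, 1), 0.0)
        mend_fail = rate > conflict_threshold
        report.removed["mendelian_conflicts"] = survivors.animal_ids[
            mend_fail
        ].tolist()
        survivors = survivors.take_animals(~mend_fail)
    else:
        report.removed["mendelian_conflicts"] = []
    report.output_shape = survivors.dosages.shape
    return survivors, report


def run_qc(
    gset: GenotypeSet, ped: Pedigree | None = None, conflict_threshold: float = 0.01
) -> tuple[GenotypeSet, QcReport]:
    """SNP filters then animal filters, single pass; merged report."""
    out, rep_snp = filter_snps(gset)
    out, rep_ani = filter_animals(out, ped, conflict_threshold)
    merged = QcReport(input_shape=gset.dosages.shape)
    merged.removed = {**rep_snp.removed, **rep_ani.removed}
    merged.output_shape = out.dosages.shape
    return out, merged
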