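"""Synthetic populations with known direct and social genetic effects.

Emulates the study system: a purebred Duroc (DUC) nucleus plus a
crossbreeding chain using Korean native pigs (KNP) —

    F1 = DUC x KNP;  F2 = F1 x DUC;  terminal crossbred = F1 x F2

(the terminal animals are 62.5% DUC / 37.5% KNP in expectation).  Phenotyped
animals (DUC and terminal crossbreds) are housed in pens formed within
population and birth batch, and their growth records are generated by the
same model the package fits:

    y = fixed effects + a_D(own) + f_g * sum(a_S of pen mates) + pen + litter + e

with the four genetic components (direct/social x purebred/crossbred trait)
drawn jointly from a 4x4 covariance ``true_G0`` with pedigree covariance
(recursive Mendelian sampling, equivalent to a Cholesky of ``A``).

Genotypes are produced by gene dropping founder haplotypes with
recombination (one Morgan per chromosome, uniformly spaced markers, no
interference).  An optional marker-effect mode builds the direct genetic
values from true SNP effects — including planted large-effect QTLs — for
GWAS power studies.

Every operation takes an explicit seed; the same configuration and seed
reproduce identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeSet
from .pedigree import Pedigree, inbreeding, validate_and_sort

__all__ = [
    "SimConfig",
    "TruthRecord",
    "default_true_g0",
    "simulate_pedigree",
    "simulate_genotypes",
    "sample_genetic_values",
    "simulate_phenotypes",
    "inject_defects",
    "simulate_all",
]

#: Component order of true_G0 (matches the fitted model with two traits).
COMPONENTS = ("aD_pure", "aS_pure", "aD_cross", "aS_cross")


def default_true_g0() -> np.ndarray:
    """Default 4x4 genetic covariance among (aD_p, aS_p, aD_c, aS_c).

    Variances in (g/day)^2 of a magnitude typical for pig growth, with a
    correlation structure in which the purebred social effect is strongly
    aligned with the crossbred direct effect.  The matrix is positive
    definite (checked at import of any simulation using it).
    """
    sd = np.sqrt([1377.0, 75.0, 3410.0, 72.0])
    corr = np.array(
        [
            [1.00, 0.03, 0.48, -0.53],
            [0.03, 1.00, 0.77, -0.27],
            [0.48, 0.77, 1.00, -0.15],
            [-0.53, -0.27, -0.15, 1.00],
        ]
    )
    return corr * np.outer(sd, sd)


@dataclass
class SimConfig:
    """Configuration of the synthetic populations.

    Variances are in (g/day)^2 throughout; per-trait tuples are
    (purebred, crossbred).
    """

    n_founders_per_breed: dict = field(
        default_factory=lambda: {"DUC": 80, "KNP": 24}
    )
    n_generations: int = 3
    n_litters_per_gen: dict = field(
        default_factory=lambda: {"DUC": 24, "CROSS": 24}
    )
    litter_size_mean: float = 8.0
    pen_size_levels: tuple = (2, 3, 4, 5, 6, 7)
    n_snps: int = 2000
    n_chromosomes: int = 5
    chrom_length_bp: int = 100_000_000
    founder_maf_range: tuple = (0.1, 0.5)
    true_G0: np.ndarray = field(default_factory=default_true_g0)
    var_group: tuple = (800.0, 700.0)
    var_litter: tuple = (900.0, 800.0)
    var_resid: tuple = (5565.0, 4250.0)
    mean_adg: tuple = (986.0, 849.0)
    sex_effect: float = 40.0  # male minus female, g/day
    batch_sd: float = 30.0
    slope_start_wt: float = 0.005  # g/day per g start weight
    slope_age_end: float = -2.0  # g/day per day of age at end weight
    marker_effect_mode: bool = False
    qtl: tuple = ()  # (snp_index, fraction_of_direct_variance) pairs
    seed: int = 0

    def __post_init__(self) -> None:
        self.true_G0 = np.asarray(self.true_G0, dtype=float)
        if self.true_G0.shape != (4, 4) or not np.allclose(
            self.true_G0, self.true_G0.T
        ):
            raise ValueError("true_G0 must be a symmetric 4x4 matrix")
        if np.linalg.eigvalsh(self.true_G0).min() < -1e-8:
            raise ValueError("true_G0 must be positive semidefinite")
        lo, hi = self.founder_maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("founder_maf_range must lie within (0, 0.5]")
        if min(self.pen_size_levels) < 2:
            raise ValueError("pen sizes must be at least 2")
        if any(v < 1 for v in self.n_founders_per_breed.values()):
            raise ValueError("need at least one founder per breed")


@dataclass
class TruthRecord:
    """True simulated effects for recovery tests.

    ``animals``: per-animal frame with the four genetic components, the
    population trait expressed (if any) and its TBV; ``pens``/``litters``:
    true random effects; plus the configured variances.
    """

    animals: pd.DataFrame
    pens: pd.DataFrame
    litters: pd.DataFrame
    config: SimConfig
    avg_pen_size: dict
    snp_effects: pd.DataFrame | None = None


def simulate_pedigree(config: SimConfig) -> Pedigree:
    """Breeding scheme: DUC purebred line plus DUC/KNP crossbreeding chain.

    Generation 1 produces DUC litters and F1 (DUC x KNP); generation 2 adds
    F2 (F1 x DUC); generation 3 onwards adds terminal crossbreds (F1 x F2).
    Returns a validated, topologically sorted pedigree with columns
    id, sire, dam, breed, sex, birth_batch, litter.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    next_id = 1

    def add(sire, dam, breed, batch, litter):
        nonlocal next_id
        sex = "M" if rng.random() < 0.5 else "F"
        rows.append(
            {
                "id": next_id,
                "sire": sire,
                "dam": dam,
                "breed": breed,
                "sex": sex,
                "birth_batch": batch,
                "litter": litter,
            }
        )
        next_id += 1
        return rows[-1]

    for breed, n in config.n_founders_per_breed.items():
        for _ in range(n):
            add(0, 0, breed, 0, 0)

    def pool(breed, sex):
        return [r["id"] for r in rows if r["breed"] == breed and r["sex"] == sex]

    litter_id = 0
    for gen in range(1, config.n_generations + 1):
        matings = []
        sires_duc, dams_duc = pool("DUC", "M"), pool("DUC", "F")
        if not sires_duc or not dams_duc:
            raise ValueError("DUC founder pool lacks one sex; increase founders")
        for _ in range(config.n_litters_per_gen.get("DUC", 0)):
            matings.append((rng.choice(sires_duc), rng.choice(dams_duc), "DUC"))
        n_cross = config.n_litters_per_gen.get("CROSS", 0)
        if gen == 1:
            dams = pool("KNP", "F")
            for _ in range(n_cross):
                matings.append((rng.choice(sires_duc), rng.choice(dams), "F1"))
        elif gen == 2:
            dams = pool("F1", "F")
            for _ in range(n_cross):
                if dams:
                    matings.append((rng.choice(sires_duc), rng.choice(dams), "F2"))
        else:
            sires, dams = pool("F1", "M"), pool("F2", "F")
            for _ in range(n_cross):
                if sires and dams:
                    matings.append((rng.choice(sires), rng.choice(dams), "CROSS"))
        for sire, dam, breed in matings:
            litter_id += 1
            size = max(2, int(rng.poisson(config.litter_size_mean)))
            for _ in range(size):
                add(int(sire), int(dam), breed, gen, litter_id)

    return validate_and_sort(pd.DataFrame(rows))


def _marker_positions(config: SimConfig) -> pd.DataFrame:
    """Uniformly spaced marker map over the configured chromosomes."""
    per = np.full(config.n_chromosomes, config.n_snps // config.n_chromosomes)
    per[: config.n_snps % config.n_chromosomes] += 1
    recs = []
    snp = 0
    for c in range(config.n_chromosomes):
        k = per[c]
        bp = np.linspace(
            config.chrom_length_bp / (k + 1),
            config.chrom_length_bp * k / (k + 1),
            k,
        ).astype(np.int64)
        for b in bp:
            snp += 1
            recs.append({"snp": f"snp{snp}", "chrom": str(c + 1), "bp": int(b)})
    return pd.DataFrame(recs)


def simulate_genotypes(
    ped: Pedigree, config: SimConfig, seed: int | None = None
) -> GenotypeSet:
    """Gene-drop genotypes down the pedigree with recombination.

    Founder alleles are drawn from breed-specific frequencies (each breed
    draws its own frequency within the configured MAF range, on a random
    side of 0.5).  Each non-founder receives one recombined gamete per
    parent; one chromosome spans one Morgan with uniform marker spacing.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    snp_map = _marker_positions(config)
    m = len(snp_map)
    n = len(ped)
    breeds = sorted(config.n_founders_per_breed)
    lo, hi = config.founder_maf_range
    freqs = {}
    for b in breeds:
        maf = rng.uniform(lo, hi, size=m)
        flip = rng.random(m) < 0.5
        freqs[b] = np.where(flip, 1.0 - maf, maf)

    chrom = snp_map["chrom"].to_numpy()
    # per-adjacent-marker recombination fraction: uniform spacing on a
    # 1-Morgan chromosome, Haldane-free (small interval) Bernoulli crossovers
    rec = np.zeros(m)
    for c in np.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        if len(idx) > 1:
            rec[idx[1:]] = 1.0 / len(idx)
        rec[idx[0]] = 0.5  # independent start per chromosome

    hap = np.zeros((2, n, m), dtype=np.int8)
    s, d = ped.sire_idx, ped.dam_idx
    breed_col = ped.df["breed"].to_numpy() if "breed" in ped.df.columns else None

    def gamete(parent: int) -> np.ndarray:
        cross = rng.random(m) < rec
        sel = np.cumsum(cross) % 2
        return np.where(sel == 0, hap[0, parent], hap[1, parent])

    for i in range(n):
        if s[i] < 0 and d[i] < 0:
            b = str(breed_col[i]) if breed_col is not None else breeds[0]
            p = freqs.get(b, freqs[breeds[0]])
            hap[0, i] = rng.random(m) < p
            hap[1, i] = rng.random(m) < p
        elif s[i] >= 0 and d[i] >= 0:
            hap[0, i] = gamete(s[i])
            hap[1, i] = gamete(d[i])
        else:
            raise ValueError(
                f"animal {ped.ids[i]!r} has exactly one known parent; "
                "gene dropping needs both or neither"
            )
    dosages = (hap[0] + hap[1]).astype(np.int8)
    return GenotypeSet(dosages, ped.ids.copy(), snp_map)


def sample_genetic_values(
    ped: Pedigree, G0: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw (n_anim x n_comp) genetic values with covariance G0 ⊗ A.

    Recursive Mendelian sampling: founders ~ N(0, G0); offspring get the
    parental average plus a Mendelian deviation with variance d_i * G0,
    d_i = 0.5 − 0.25 (F_sire + F_dam).  Exactly equivalent to a Cholesky of
    A but linear-time in pedigree size.
    """
    n = len(ped)
    nc = G0.shape[0]
    jitter = 1e-12 * (np.trace(G0) / nc if np.trace(G0) > 0 else 1.0)
    L = np.linalg.cholesky(G0 + jitter * np.eye(nc))
    F = inbreeding(ped)
    s, d = ped.sire_idx, ped.dam_idx
    u = np.zeros((n, nc))
    z = rng.standard_normal((n, nc))
    for i in range(n):
        si, di = s[i], d[i]
        if si < 0 and di < 0:
            u[i] = L @ z[i]
        else:
            pa = np.zeros(nc)
            dm = 1.0
            if si >= 0 and di >= 0:
                pa = 0.5 * (u[si] + u[di])
                dm = 0.5 - 0.25 * (F[si] + F[di])
            elif si >= 0:
                pa = 0.5 * u[si]
                dm = 0.75 - 0.25 * F[si]
            else:
                pa = 0.5 * u[di]
                dm = 0.75 - 0.25 * F[di]
            u[i] = pa + np.sqrt(dm) * (L @ z[i])
    return u


def _marker_direct_values(
    ped: Pedigree,
    genotypes: GenotypeSet,
    config: SimConfig,
    pheno_mask: np.ndarray,
    target_var: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Direct genetic values as sums of true SNP effects (marker mode).

    Planted QTLs get effects sized so each contributes its configured
    fraction of the direct genetic variance; the polygenic background takes
    the rest.  Values are scaled so the variance over phenotyped animals
    equals ``target_var``.
    """
    d = genotypes.dosages.astype(float)
    p = d.mean(axis=0) / 2.0
    Z = d - 2.0 * p
    m = Z.shape[1]
    beta = rng.standard_normal(m)
    het = 2.0 * p * (1.0 - p)
    qtl_idx = np.array([int(i) for i, _ in config.qtl], dtype=int)
    qtl_frac = np.array([float(f) for _, f in config.qtl])
    if qtl_frac.sum() >= 1.0:
        raise ValueError("planted QTL fractions must sum to < 1")
    poly = np.ones(m, dtype=bool)
    poly[qtl_idx] = False
    var_poly = float(np.sum(het[poly] * beta[poly] ** 2))
    for i, fr in zip(qtl_idx, qtl_frac):
        # variance share fr of total: v_q / (var_poly + sum v_q) = fr
        v_q = fr / (1.0 - qtl_frac.sum()) * var_poly
        beta[i] = np.sign(rng.standard_normal()) * np.sqrt(v_q / max(het[i], 1e-12))
    a = Z @ beta
    scale = np.sqrt(target_var / max(np.var(a[pheno_mask]), 1e-30))
    beta *= scale
    a *= scale
    eff = genotypes.snp_map.copy()
    eff["beta"] = beta
    eff["is_qtl"] = False
    if len(qtl_idx):
        eff.loc[qtl_idx, "is_qtl"] = True
    return a, eff


def simulate_phenotypes(
    ped: Pedigree,
    genotypes: GenotypeSet | None,
    config: SimConfig,
    seed: int | None = None,
) -> tuple[pd.DataFrame, TruthRecord]:
    """Generate growth records under the direct + social model.

    Phenotyped animals are the non-founder DUC (purebred trait) and terminal
    CROSS animals (crossbred trait).  Pens are drawn from
    ``pen_size_levels`` within population x birth batch; litters follow the
    pedigree.  Returns the phenotype table and a :class:`TruthRecord`.
    """
    rng = np.random.default_rng(config.seed + 7919 if seed is None else seed)
    df = ped.df
    non_founder = (ped.sire_idx >= 0) | (ped.dam_idx >= 0)
    pop = np.where(
        (df["breed"] == "DUC") & non_founder,
        "purebred",
        np.where(df["breed"] == "CROSS", "crossbred", ""),
    )

    u = sample_genetic_values(ped, config.true_G0, rng)
    snp_eff = None
    traits = ("purebred", "crossbred")
    if config.marker_effect_mode:
        if genotypes is None:
            raise ValueError("marker_effect_mode requires genotypes")
        for t, trait in enumerate(traits):
            mask = pop == trait
            if not mask.any():
                continue
            var_t = config.true_G0[2 * t, 2 * t]
            a, eff = _marker_direct_values(ped, genotypes, config, mask, var_t, rng)
            u[:, 2 * t] = a
            if snp_eff is None:
                eff = eff.rename(columns={"beta": f"beta_{trait}"})
                snp_eff = eff
            else:
                snp_eff[f"beta_{trait}"] = eff["beta"]

    records = []
    pens_truth = []
    litters_truth = []
    pen_id = 0
    avg_pen_size = {}
    pen_assign = {}  # row index -> (pen id, members)
    for t, trait in enumerate(traits):
        members_all = np.flatnonzero(pop == trait)
        if len(members_all) == 0:
            continue
        pen_sizes_used = []
        for batch in sorted(set(df["birth_batch"].iloc[members_all])):
            idx = [i for i in members_all if df["birth_batch"].iat[i] == batch]
            rng.shuffle(idx)
            k = 0
            while k < len(idx):
                size = int(rng.choice(config.pen_size_levels))
                group = idx[k : k + size]
                k += size
                if len(group) < size:
                    # an incomplete trailing group stays unphenotyped so
                    # realised pen sizes always come from pen_size_levels
                    continue
                pen_id += 1
                for i in group:
                    pen_assign[i] = pen_id
        # realised pen sizes
        sizes = pd.Series([pen_assign[i] for i in members_all if i in pen_assign])
        counts = sizes.value_counts()
        avg_pen_size[trait] = float(counts.mean())
        pen_sizes_used = counts.to_dict()

        pen_eff = {p: rng.normal(0.0, np.sqrt(config.var_group[t])) for p in counts.index}
        litters = sorted(set(df["litter"].iloc[members_all]))
        lit_eff = {l: rng.normal(0.0, np.sqrt(config.var_litter[t])) for l in litters}
        batches = sorted(set(df["birth_batch"].iloc[members_all]))
        batch_eff = {b: rng.normal(0.0, config.batch_sd) for b in batches}

        nbar = avg_pen_size[trait]
        by_pen: dict = {}
        for i in members_all:
            if i in pen_assign:
                by_pen.setdefault(pen_assign[i], []).append(i)
        for p, members in by_pen.items():
            ng = len(members)
            f = (nbar - 1.0) / (ng - 1.0)
            for i in members:
                mates_as = sum(u[j, 2 * t + 1] for j in members if j != i)
                sex = df["sex"].iat[i]
                start_wt = rng.normal(30000.0, 2000.0)
                age_end = rng.normal(180.0, 10.0)
                yv = (
                    config.mean_adg[t]
                    + (config.sex_effect / 2 if sex == "M" else -config.sex_effect / 2)
                    + batch_eff[df["birth_batch"].iat[i]]
                    + config.slope_start_wt * (start_wt - 30000.0)
                    + config.slope_age_end * (age_end - 180.0)
                    + u[i, 2 * t]
                    + f * mates_as
                    + pen_eff[p]
                    + lit_eff[df["litter"].iat[i]]
                    + rng.normal(0.0, np.sqrt(config.var_resid[t]))
                )
                records.append(
                    {
                        "animal": int(df["id"].iat[i]),
                        "population": trait,
                        "adg": yv,
                        "sex": sex,
                        "batch": int(df["birth_batch"].iat[i]),
                        "pen": int(p),
                        "pen_size": ng,
                        "litter": int(df["litter"].iat[i]),
                        "start_wt": start_wt,
                        "age_end": age_end,
                    }
                )
        pens_truth.extend(
            {"pen": int(p), "population": trait, "effect": pen_eff[p], "size": int(n)}
            for p, n in pen_sizes_used.items()
        )
        litters_truth.extend(
            {"litter": int(l), "population": trait, "effect": e}
            for l, e in lit_eff.items()
        )

    pheno = pd.DataFrame(records)
    animals = pd.DataFrame(
        {
            "id": ped.ids,
            "population": pop,
            **{name: u[:, k] for k, name in enumerate(COMPONENTS)},
        }
    )
    tbv = np.zeros(len(ped))
    for t, trait in enumerate(traits):
        if trait in avg_pen_size:
            mask = pop == trait
            nbar = avg_pen_size[trait]
            tbv[mask] = u[mask, 2 * t] + (nbar - 1.0) * u[mask, 2 * t + 1]
    animals["tbv"] = tbv
    truth = TruthRecord(
        animals=animals,
        pens=pd.DataFrame(pens_truth),
        litters=pd.DataFrame(litters_truth),
        config=config,
        avg_pen_size=avg_pen_size,
        snp_effects=snp_eff,
    )
    return pheno, truth


def inject_defects(
    gset: GenotypeSet,
    miss_rate_snp: float = 0.0,
    miss_rate_animal: float = 0.0,
    n_mendel_errors: int = 0,
    seed: int = 0,
    ped: Pedigree | None = None,
    n_bad_snps: int = 1,
    n_bad_animals: int = 1,
    conflict_rate: float = 0.05,
) -> tuple[GenotypeSet, dict]:
    """Plant missingness and Mendelian-inconsistent dosages at known positions.

    ``miss_rate_snp`` makes ``n_bad_snps`` randomly chosen SNPs missing at
    that per-entry rate; ``miss_rate_animal`` likewise for animals.
    ``n_mendel_errors`` picks that many animals with a genotyped parent and
    sets ``conflict_rate`` of their parent-homozygous SNPs to the opposing
    homozygote.  Returns the modified set and a record of every planted
    defect, for QC bookkeeping tests.
    """
    for r in (miss_rate_snp, miss_rate_animal, conflict_rate):
        if not 0.0 <= r <= 1.0:
            raise ValueError("rates must be within [0, 1]")
    rng = np.random.default_rng(seed)
    d = gset.dosages.copy()
    rec: dict = {"missing_snps": [], "missing_animals": [], "mendel": []}

    if miss_rate_snp > 0:
        snps = rng.choice(gset.n_snps, size=min(n_bad_snps, gset.n_snps), replace=False)
        for j in snps:
            hit = rng.random(gset.n_animals) < miss_rate_snp
            d[hit, j] = MISSING
            rec["missing_snps"].append(
                {"snp": gset.snp_map["snp"].iat[int(j)], "n_missing": int(hit.sum())}
            )
    if miss_rate_animal > 0:
        anims = rng.choice(
            gset.n_animals, size=min(n_bad_animals, gset.n_animals), replace=False
        )
        for i in anims:
            hit = rng.random(gset.n_snps) < miss_rate_animal
            d[i, hit] = MISSING
            rec["missing_animals"].append(
                {"animal": gset.animal_ids[int(i)], "n_missing": int(hit.sum())}
            )
    if n_mendel_errors > 0:
        if ped is None:
            raise ValueError("planting Mendelian errors requires the pedigree")
        gpos = {a: i for i, a in enumerate(gset.animal_ids)}
        # only corrupt leaves (animals that are nobody's parent) so the
        # planted conflicts cannot cascade to descendants' duos
        parent_ids = set(ped.df["sire"]) | set(ped.df["dam"])
        candidates = []
        for row in range(len(ped)):
            child = ped.ids[row]
            if child not in gpos or child in parent_ids:
                continue
            for pidx in (ped.sire_idx[row], ped.dam_idx[row]):
                if pidx >= 0 and ped.ids[pidx] in gpos:
                    candidates.append((gpos[child], gpos[ped.ids[pidx]]))
                    break
        rng.shuffle(candidates)
        for ci, pi in candidates[:n_mendel_errors]:
            homo = np.flatnonzero((d[pi] == 0) | (d[pi] == 2))
            k = max(1, int(round(conflict_rate * len(homo))))
            chosen = rng.choice(homo, size=min(k, len(homo)), replace=False)
            for j in chosen:
                d[ci, j] = 2 - d[pi, j]  # opposing homozygote
            rec["mendel"].append(
                {
                    "animal": gset.animal_ids[ci],
                    "parent": gset.animal_ids[pi],
                    "n_snps": int(len(chosen)),
                }
            )
    out = GenotypeSet(d, gset.animal_ids.copy(), gset.snp_map.copy())
    return out, rec


def simulate_all(config: SimConfig, outdir=None):
    """Pedigree + genotypes + phenotypes in one call; optionally write files.

    Writes pedigree CSV, PLINK PED/MAP, phenotype TSV, truth TSV and a
    run-manifest JSON recording all seeds when ``outdir`` is given.
    """
    ped = simulate_pedigree(config)
    gset = simulate_genotypes(ped, config, seed=config.seed + 1)
    pheno, truth = simulate_phenotypes(ped, gset, config, seed=config.seed + 2)
    if outdir is not None:
        from pathlib import Path

        from .genotypes import write_plink

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        ped.to_csv(outdir / "pedigree.csv")
        write_plink(gset, str(outdir / "genotypes"))
        pheno.to_csv(outdir / "phenotypes.tsv", sep="\t", index=False)
        truth.animals.to_csv(outdir / "truth_animals.tsv", sep="\t", index=False)
        cfg = asdict(config)
        cfg["true_G0"] = np.asarray(cfg["true_G0"]).tolist()
        manifest = {
            "seed": config.seed,
            "genotype_seed": config.seed + 1,
            "phenotype_seed": config.seed + 2,
            "config": {
                k: (list(v) if isinstance(v, tuple) else v) for k, v in cfg.items()
            },
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
    return ped, gset, pheno, truth
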