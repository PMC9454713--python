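"""Weighted single-step GWAS: SNP back-solving, iterative reweighting,
window variance and QTL calling.

From the breeding values of the genotyped animals for one genetic component
(direct or social, per population), SNP effects are back-solved as

    u_hat = D Z' [Z D Z']⁻¹ a_hat_g

and each SNP's weight is updated to d_i = u_hat_i² 2 p_i (1 − p_i), then
normalised so that sum(d_i 2 p_i (1 − p_i)) keeps its initial (D = I)
value — constant implied total genetic variance.  Rebuilding the genomic
matrix with the new weights, re-solving the mixed-model equations and
re-back-solving is iterated (three rounds by default).

SNPs are grouped into fixed, non-overlapping 0.4-Mb windows tiled from
position zero; the percentage of the component's genetic variance explained
by a window is Var(sum_j Z_j u_hat_j over the window) / sigma_a^2 * 100,
with sigma_a^2 the variance of the component's total genomic value over the
genotyped animals (so the single-window case self-normalises to 100%).
Windows exceeding the significance threshold (0.4% by default) seed 1-Mb
QTL regions centred on the window midpoint; overlapping regions merge,
keeping the peak.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import sparse

from .mme import DesignSet, VarComp, assemble_mme, solve_mme
from .relmat import SnpWeightState, blend_g, center_genotypes, h_inverse, vanraden_g

__all__ = [
    "WindowResult",
    "QtlRegion",
    "backsolve_snp_effects",
    "update_weights",
    "wssgblup",
    "window_variance",
    "call_qtls",
    "annotate_qtls",
    "read_gff3_genes",
]


@dataclass
class WindowResult:
    """One 0.4-Mb window of one genetic component."""

    chrom: str
    start_bp: int
    end_bp: int
    snps: list
    pct_variance: float
    component: str


@dataclass
class QtlRegion:
    """A 1-Mb region centred on a significant window midpoint."""

    chrom: str
    start_bp: int
    end_bp: int
    peak_pct: float
    component: str


def backsolve_snp_effects(
    a_hat_g: np.ndarray, Z: np.ndarray, weights: SnpWeightState, g_inv: np.ndarray | None = None
) -> np.ndarray:
    """SNP effects u_hat = D Z' [Z D Z']⁻¹ a_hat_g.

    ``g_inv`` may supply a precomputed inverse of the (blended) genomic
    matrix on the same q scale as :func:`vanraden_g`; the normalising factor
    cancels between D Z'/q and (Z D Z'/q)⁻¹.
    """
    if g_inv is None:
        G = vanraden_g(Z, weights)
        try:
            g_inv = np.linalg.inv(G)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "Z D Z' is singular; blend the genomic matrix (blend_g) first"
            ) from exc
    return (weights.d / weights.q) * (Z.T @ (g_inv @ a_hat_g))


def update_weights(u_hat: np.ndarray, state: SnpWeightState) -> SnpWeightState:
    """New weights d_i ∝ u_hat_i² 2 p_i (1 − p_i), conservation-normalised.

    The rescale keeps sum(d_i 2 p_i (1 − p_i)) at its initial value
    (= q, the D = I heterozygosity sum), so total genetic variance implied
    by the weighted genomic matrix is unchanged.
    """
    het = 2.0 * state.p * (1.0 - state.p)
    d_new = u_hat**2 * het
    tot = float(np.sum(d_new * het))
    if tot <= 0:
        raise ValueError("all back-solved SNP effects are zero; weights degenerate")
    d_new *= state.q / tot
    return replace(state, d=d_new, iteration=state.iteration + 1)


def wssgblup(
    design: DesignSet,
    genotypes,
    varcomp: VarComp,
    k_inv_pedigree: sparse.spmatrix,
    a22_mat: np.ndarray,
    genotyped_index: np.ndarray,
    components: list | None = None,
    n_iter: int = 3,
    tau: float = 0.05,
    weight_cap: float = 10.0,
    solve_method: str = "auto",
) -> dict:
    """Iterative weighted single-step GBLUP scan.

    For each requested genetic component the loop rebuilds the blended
    genomic matrix with the current SNP weights, assembles H⁻¹, solves the
    mixed-model equations at fixed variance components, back-solves SNP
    effects and updates the weights; ``n_iter`` rounds (3 by default).
    Weights above ``weight_cap`` are clipped (with a warning) before
    normalisation.  Returns per-component effects, weights and the centred
    genotype matrix.
    """
    import warnings

    spec = design.spec
    comp_idx = components if components is not None else list(range(spec.n_comp))
    Z, p = center_genotypes(genotypes.dosages)
    out: dict = {"Z": Z, "p": p, "components": {}, "iterations": []}
    for c in comp_idx:
        state = SnpWeightState.initial(p)
        u_hat = None
        for it in range(n_iter):
            G = vanraden_g(Z, state)
            Gb = blend_g(G, a22_mat, tau=tau)
            g_inv = np.linalg.inv(Gb)
            hinv = h_inverse(k_inv_pedigree, Gb, a22_mat, genotyped_index)
            system = assemble_mme(design, varcomp, hinv)
            sol = solve_mme(system, method=solve_method)
            a_hat = sol.genetic()[genotyped_index, c]
            u_hat = backsolve_snp_effects(a_hat, Z, state, g_inv=g_inv)
            out["iterations"].append(
                {"component": c, "iteration": it, "max_weight": float(state.d.max())}
            )
            if it < n_iter - 1:
                state = update_weights(u_hat, state)
                if state.d.max() > weight_cap:
                    warnings.warn(
                        f"SNP weights clipped at {weight_cap} (component {c}, "
                        f"iteration {it + 1})"
                    )
                    het = 2.0 * state.p * (1.0 - state.p)
                    d = np.minimum(state.d, weight_cap)
                    d *= state.q / float(np.sum(d * het))
                    state = replace(state, d=d)
        out["components"][c] = {"u_hat": u_hat, "weights": state, "a_hat": a_hat}
    return out


def window_variance(
    Z: np.ndarray,
    u_hat: np.ndarray,
    snp_map: pd.DataFrame,
    window_bp: int = 400_000,
    component: str = "",
    chrom_lengths: dict | None = None,
) -> list:
    """Percent of genetic variance explained per fixed 0.4-Mb window.

    Windows tile each chromosome from position 0; empty windows are retained
    with 0%.  The denominator is Var(Z u_hat) over the genotyped animals.
    """
    total = float(np.var(Z @ u_hat))
    results: list[WindowResult] = []
    bp = snp_map["bp"].to_numpy()
    chroms = snp_map["chrom"].to_numpy()
    for c in sorted(set(chroms), key=str):
        on = np.flatnonzero(chroms == c)
        cmax = int(chrom_lengths[c]) if chrom_lengths else int(bp[on].max())
        n_win = int(np.ceil(cmax / window_bp)) or 1
        win_of = np.minimum(bp[on] // window_bp, n_win - 1)
        for w in range(n_win):
            members = on[win_of == w]
            if len(members) == 0 or total == 0:
                pct = 0.0
            else:
                gv = Z[:, members] @ u_hat[members]
                pct = float(np.var(gv)) / total * 100.0
            results.append(
                WindowResult(
                    chrom=str(c),
                    start_bp=w * window_bp,
                    end_bp=min((w + 1) * window_bp, max(cmax, (w + 1) * window_bp)),
                    snps=snp_map["snp"].iloc[members].tolist(),
                    pct_variance=pct,
                    component=component,
                )
            )
    return results


def windows_to_frame(windows: list) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [w.chrom for w in windows],
            "start_bp": [w.start_bp for w in windows],
            "end_bp": [w.end_bp for w in windows],
            "n_snps": [len(w.snps) for w in windows],
            "pct_variance": [w.pct_variance for w in windows],
            "component": [w.component for w in windows],
        }
    )


def call_qtls(
    windows: list,
    threshold_pct: float = 0.4,
    qtl_span_bp: int = 1_000_000,
    chrom_lengths: dict | None = None,
) -> list:
    """1-Mb QTL regions centred on significant (> threshold) window midpoints.

    Overlapping regions of the same component are merged, retaining the
    largest peak.  Regions are clipped at chromosome ends when lengths are
    supplied.
    """
    regions: list[QtlRegion] = []
    for w in windows:
        if w.pct_variance <= threshold_pct:
            continue
        mid = (w.start_bp + w.end_bp) // 2
        start = max(0, mid - qtl_span_bp // 2)
        end = start + qtl_span_bp
        if chrom_lengths and w.chrom in chrom_lengths:
            end = min(end, int(chrom_lengths[w.chrom]))
            start = max(0, end - qtl_span_bp)
        regions.append(
            QtlRegion(
                chrom=w.chrom,
                start_bp=start,
                end_bp=end,
                peak_pct=w.pct_variance,
                component=w.component,
            )
        )
    regions.sort(key=lambda r: (r.component, str(r.chrom), r.start_bp))
    merged: list[QtlRegion] = []
    for r in regions:
        if (
            merged
            and merged[-1].component == r.component
            and merged[-1].chrom == r.chrom
            and r.start_bp <= merged[-1].end_bp
        ):
            last = merged[-1]
            merged[-1] = QtlRegion(
                chrom=last.chrom,
                start_bp=last.start_bp,
                end_bp=max(last.end_bp, r.end_bp),
                peak_pct=max(last.peak_pct, r.peak_pct),
                component=last.component,
            )
        else:
            merged.append(r)
    return merged


def read_gff3_genes(path) -> pd.DataFrame:
    """Gene features (seqid, start, end, name) from a local GFF3 file.

    Only ``gene`` rows are kept.  Malformed lines raise with their line
    number.  Coordinates stay 1-based closed as in the file.
    """
    recs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(
                    f"{path}: line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(parts)}"
                )
            seqid, _, ftype, start, end, _, _, _, attrs = parts
            if ftype != "gene":
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            name = ""
            for kv in attrs.split(";"):
                if "=" in kv:
                    k, v = kv.split("=", 1)
                    if k in ("Name", "gene", "ID"):
                        name = v
                        if k == "Name":
                            break
            recs.append(
                {"seqid": seqid, "start": start_i, "end": end_i, "name": name}
            )
    return pd.DataFrame(recs, columns=["seqid", "start", "end", "name"])


def annotate_qtls(qtls: list, gff3_path) -> dict:
    """Genes whose span intersects each QTL (1-based closed intervals).

    QTL coordinates are treated as 1-based closed [start+1, end] when the
    region was built on 0-based tiling; callers passing 1-based regions get
    standard closed-interval overlap.
    """
    genes = read_gff3_genes(gff3_path)
    out = {}
    for i, q in enumerate(qtls):
        qs, qe = q.start_bp + 1, q.end_bp
        hit = genes[
            (genes["seqid"].astype(str) == str(q.chrom))
            & (genes["start"] <= qe)
            & (genes["end"] >= qs)
        ]
        out[i] = hit["name"].tolist()
    return out
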