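"""Design matrices and mixed-model equations for the direct + social model.

The phenotypic model per record (animal i, in pen g of its population) is

    y_i = x_i' b + a_D,i + f_g * sum_{j in pen, j != i} a_S,j + d_g + l_i + e_i

with fixed effects ``b`` (sex, batch, group-size class, covariates), direct
genetic effect ``a_D``, social genetic effects ``a_S`` of the pen mates,
random pen effect ``d``, random litter effect ``l`` and residual ``e``.
``f_g = (n̄ - 1)/(n_g - 1)`` is the dilution factor that makes the social
contribution comparable across pens of different sizes (``n̄`` is the
population's average pen size).

Two traits (purebred and crossbred growth) are supported; each record
belongs to exactly one trait and the residual covariance between traits is
fixed at zero (no animal has both records, so it is not estimable).  The
genetic effects of *all* pedigree animals are carried for every component
(direct/social x trait), with covariance ``G0 ⊗ K`` flowing through the
shared pedigree (``K`` is ``A`` or ``H``).

Equation order: [fixed(trait 0) | fixed(trait 1) | genetic, animal-major
(n_comp consecutive equations per animal) | pen(t0) | pen(t1) | litter(t0)
| litter(t1)].  Fixed-effect rank deficiency is handled by dropping the
last level of every factor (treatment coding with intercept).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import cg, splu

from .pedigree import Pedigree

__all__ = [
    "ModelSpec",
    "VarComp",
    "DesignSet",
    "MmeSystem",
    "MmeSolution",
    "dilution_factor",
    "build_design",
    "assemble_mme",
    "solve_mme",
]


def dilution_factor(pen_size: int, avg_pen_size: float) -> float:
    """Dilution factor (n̄ − 1)/(n_g − 1) applied to social incidence."""
    if pen_size < 2:
        raise ValueError(f"pen of size {pen_size}: social term undefined")
    if avg_pen_size <= 1:
        raise ValueError("average pen size must exceed 1")
    return (avg_pen_size - 1.0) / (pen_size - 1.0)


@dataclass
class ModelSpec:
    """Declaration of the fitted model (traits, effects, covariates)."""

    traits: tuple = ("purebred", "crossbred")
    fixed_factors: tuple = ("sex", "batch", "pen_size")
    covariates: tuple = ("start_wt", "age_end")
    include_genetic: bool = True
    include_social: bool = True
    include_pen: bool = True
    include_litter: bool = True
    trait_col: str = "population"
    animal_col: str = "animal"
    pen_col: str = "pen"
    litter_col: str = "litter"
    y_col: str = "adg"
    avg_pen_size: dict | None = None  # per trait; observed mean if None

    @property
    def n_traits(self) -> int:
        return len(self.traits)

    @property
    def components(self) -> list:
        """Genetic components in equation order, e.g. [(t, 'D'), (t, 'S'), ...]."""
        out = []
        if not self.include_genetic:
            return out
        for t in range(self.n_traits):
            out.append((t, "D"))
            if self.include_social:
                out.append((t, "S"))
        return out

    @property
    def n_comp(self) -> int:
        return len(self.components)


@dataclass
class VarComp:
    """(Co)variance components of the model.

    ``G0`` is the n_comp x n_comp genetic covariance among the components in
    :attr:`ModelSpec.components` order; the scalar lists are per trait.
    """

    G0: np.ndarray
    var_pen: list
    var_litter: list
    var_resid: list

    def copy(self) -> "VarComp":
        return VarComp(
            self.G0.copy(),
            list(self.var_pen),
            list(self.var_litter),
            list(self.var_resid),
        )


@dataclass
class DesignSet:
    """Per-trait design matrices over a shared global equation space."""

    spec: ModelSpec
    W: list  # csr per trait, n_records_t x n_eq
    y: list  # per trait
    n_eq: int
    n_anim: int
    gen_offset: int
    fixed_slices: list
    pen_slices: list
    litter_slices: list
    fixed_labels: list  # per trait, list of column labels
    pen_levels: list  # per trait, pen ids in column order
    litter_levels: list
    avg_pen_size: list
    records: list  # per trait, the phenotype sub-frame used

    @property
    def n_comp(self) -> int:
        return self.spec.n_comp

    def genetic_slice(self) -> slice:
        return slice(self.gen_offset, self.gen_offset + self.n_anim * self.n_comp)

    def genetic_column(self, animal_index: int, comp: int) -> int:
        return self.gen_offset + animal_index * self.n_comp + comp


def _fixed_columns(sub: pd.DataFrame, spec: ModelSpec):
    """Treatment-coded fixed-effect columns for one trait's records.

    Returns (list of (label, values) dense columns).  Factors drop their last
    level; single-level factors contribute nothing (absorbed by intercept);
    covariates are centred for numerical stability.
    """
    cols = [("intercept", np.ones(len(sub)))]
    for f in spec.fixed_factors:
        if f not in sub.columns:
            continue
        levels = sorted(pd.unique(sub[f]))
        for lev in levels[:-1]:
            cols.append((f"{f}={lev}", (sub[f] == lev).to_numpy(float)))
    for c in spec.covariates:
        if c not in sub.columns:
            continue
        v = sub[c].to_numpy(float)
        cols.append((f"cov:{c}", v - v.mean()))
    return cols


def build_design(
    phenotypes: pd.DataFrame, pedigree: Pedigree, spec: ModelSpec
) -> DesignSet:
    """Build per-trait design matrices including the dilution-weighted Z_S."""
    n_anim = len(pedigree)
    n_comp = spec.n_comp
    anim_pos = {a: i for i, a in enumerate(pedigree.ids)}

    subs, fixed_cols, pen_levels, litter_levels, avg_ns = [], [], [], [], []
    for t, trait in enumerate(spec.traits):
        sub = phenotypes[phenotypes[spec.trait_col] == trait].reset_index(drop=True)
        if len(sub) == 0:
            raise ValueError(f"no records for trait {trait!r}")
        if sub[spec.animal_col].duplicated().any():
            raise ValueError(f"duplicate records per animal for trait {trait!r}")
        subs.append(sub)
        fixed_cols.append(_fixed_columns(sub, spec))
        pens = sub.groupby(spec.pen_col).size()
        if spec.include_social and (pens < 2).any():
            bad = pens[pens < 2].index.tolist()
            raise ValueError(f"pens of size 1 are not allowed with social effects: {bad}")
        pen_levels.append(list(pens.index))
        litter_levels.append(sorted(pd.unique(sub[spec.litter_col])))
        if spec.avg_pen_size is not None and trait in spec.avg_pen_size:
            avg_ns.append(float(spec.avg_pen_size[trait]))
        else:
            avg_ns.append(float(pens.mean()))

    # global column layout
    fixed_slices, off = [], 0
    for t in range(spec.n_traits):
        fixed_slices.append(slice(off, off + len(fixed_cols[t])))
        off += len(fixed_cols[t])
    gen_offset = off
    off += n_anim * n_comp
    pen_slices = []
    for t in range(spec.n_traits):
        k = len(pen_levels[t]) if spec.include_pen else 0
        pen_slices.append(slice(off, off + k))
        off += k
    litter_slices = []
    for t in range(spec.n_traits):
        k = len(litter_levels[t]) if spec.include_litter else 0
        litter_slices.append(slice(off, off + k))
        off += k
    n_eq = off

    W_list, y_list = [], []
    for t in range(spec.n_traits):
        sub = subs[t]
        nrec = len(sub)
        rows, cols, vals = [], [], []
        # fixed effects (dense columns placed into the sparse design)
        for k, (_, v) in enumerate(fixed_cols[t]):
            nz = np.flatnonzero(v)
            rows.extend(nz.tolist())
            cols.extend([fixed_slices[t].start + k] * len(nz))
            vals.extend(v[nz].tolist())
        # genetic: direct incidence + dilution-weighted social incidence
        pen_of = sub[spec.pen_col].to_numpy()
        if spec.include_genetic:
            comp_D = spec.components.index((t, "D"))
            comp_S = spec.components.index((t, "S")) if spec.include_social else None
            anim_idx = np.array([anim_pos[a] for a in sub[spec.animal_col]])
            pen_members: dict = {}
            for r, p in enumerate(pen_of):
                pen_members.setdefault(p, []).append(r)
            for r in range(nrec):
                rows.append(r)
                cols.append(gen_offset + anim_idx[r] * n_comp + comp_D)
                vals.append(1.0)
                if comp_S is not None:
                    members = pen_members[pen_of[r]]
                    f = dilution_factor(len(members), avg_ns[t])
                    for m in members:
                        if m == r:
                            continue
                        rows.append(r)
                        cols.append(gen_offset + anim_idx[m] * n_comp + comp_S)
                        vals.append(f)
        # pen and litter incidence
        if spec.include_pen:
            ppos = {p: i for i, p in enumerate(pen_levels[t])}
            for r, p in enumerate(pen_of):
                rows.append(r)
                cols.append(pen_slices[t].start + ppos[p])
                vals.append(1.0)
        if spec.include_litter:
            lpos = {l: i for i, l in enumerate(litter_levels[t])}
            for r, l in enumerate(sub[spec.litter_col]):
                rows.append(r)
                cols.append(litter_slices[t].start + lpos[l])
                vals.append(1.0)
        W = sparse.coo_matrix(
            (vals, (rows, cols)), shape=(nrec, n_eq)
        ).tocsr()
        W_list.append(W)
        y_list.append(sub[spec.y_col].to_numpy(float))

    return DesignSet(
        spec=spec,
        W=W_list,
        y=y_list,
        n_eq=n_eq,
        n_anim=n_anim,
        gen_offset=gen_offset,
        fixed_slices=fixed_slices,
        pen_slices=pen_slices,
        litter_slices=litter_slices,
        fixed_labels=[[lab for lab, _ in fc] for fc in fixed_cols],
        pen_levels=pen_levels,
        litter_levels=litter_levels,
        avg_pen_size=avg_ns,
        records=subs,
    )


def genetic_prior_precision(
    k_inv: sparse.spmatrix, G0_inv: np.ndarray
) -> sparse.csr_matrix:
    """K⁻¹ ⊗ G0⁻¹ in animal-major ordering (n_comp x n_comp blocks)."""
    k = sparse.csr_matrix(k_inv)
    nc = G0_inv.shape[0]
    data = k.data[:, None, None] * G0_inv[None, :, :]
    bsr = sparse.bsr_matrix(
        (data, k.indices, k.indptr), shape=(k.shape[0] * nc, k.shape[1] * nc)
    )
    return bsr.tocsr()


@dataclass
class MmeSystem:
    """Assembled mixed-model equations."""

    lhs: sparse.csr_matrix
    rhs: np.ndarray
    design: DesignSet
    varcomp: VarComp
    active: np.ndarray = field(default=None, repr=False)  # bool mask of live columns


def assemble_mme(
    design: DesignSet, varcomp: VarComp, k_inv: sparse.spmatrix
) -> MmeSystem:
    """Henderson MME: W'R⁻¹W + prior precision, with per-trait residuals.

    A zero variance component removes its equations from the system (the
    effect is fixed at 0), so the fixed-effects-only limit reduces to OLS.
    """
    spec = design.spec
    G0 = np.asarray(varcomp.G0, dtype=float)
    if G0.shape != (design.n_comp, design.n_comp):
        raise ValueError(f"G0 must be {design.n_comp}x{design.n_comp}")
    n_eq = design.n_eq
    active = np.ones(n_eq, dtype=bool)

    lhs = sparse.csr_matrix((n_eq, n_eq))
    rhs = np.zeros(n_eq)
    for t in range(spec.n_traits):
        r_inv = 1.0 / varcomp.var_resid[t]
        W = design.W[t]
        lhs = lhs + (W.T @ W) * r_inv
        rhs += r_inv * (W.T @ design.y[t])

    gen_zero = np.all(G0 == 0)
    if gen_zero:
        active[design.genetic_slice()] = False
    else:
        try:
            G0_inv = np.linalg.inv(G0)
            np.linalg.cholesky(G0)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError("G0 is not positive definite") from exc
        gp = genetic_prior_precision(k_inv, G0_inv)
        pad_pre = design.gen_offset
        pad_post = n_eq - design.gen_offset - gp.shape[0]
        lhs = lhs + sparse.block_diag(
            [
                sparse.csr_matrix((pad_pre, pad_pre)),
                gp,
                sparse.csr_matrix((pad_post, pad_post)),
            ],
            format="csr",
        )

    diag_add = np.zeros(n_eq)
    for t in range(spec.n_traits):
        for sl, var in (
            (design.pen_slices[t], varcomp.var_pen[t] if spec.include_pen else 0.0),
            (
                design.litter_slices[t],
                varcomp.var_litter[t] if spec.include_litter else 0.0,
            ),
        ):
            if sl.stop == sl.start:
                continue
            if var == 0:
                active[sl] = False
            else:
                diag_add[sl.start : sl.stop] = 1.0 / var
    lhs = lhs + sparse.diags(diag_add)
    return MmeSystem(lhs=lhs.tocsr(), rhs=rhs, design=design, varcomp=varcomp, active=active)


@dataclass
class MmeSolution:
    """Solution vector with labelled access to effect blocks."""

    theta: np.ndarray
    design: DesignSet

    def fixed(self, trait: int) -> pd.Series:
        sl = self.design.fixed_slices[trait]
        return pd.Series(self.theta[sl], index=self.design.fixed_labels[trait])

    def genetic(self) -> np.ndarray:
        """(n_anim, n_comp) matrix of genetic solutions, pedigree order."""
        sl = self.design.genetic_slice()
        return self.theta[sl].reshape(self.design.n_anim, self.design.n_comp)

    def pen(self, trait: int) -> np.ndarray:
        return self.theta[self.design.pen_slices[trait]]

    def litter(self, trait: int) -> np.ndarray:
        return self.theta[self.design.litter_slices[trait]]


def solve_mme(
    system: MmeSystem, method: str = "auto", tol: float = 1e-8
) -> MmeSolution:
    """Solve the MME by direct factorisation or preconditioned CG.

    ``auto`` uses a direct solve up to 20,000 equations, PCG beyond.  Inactive
    (zero-variance) equations are excluded and returned as zeros.
    """
    act = (
        system.active
        if system.active is not None
        else np.ones(system.lhs.shape[0], dtype=bool)
    )
    A = system.lhs[act][:, act].tocsc()
    b = system.rhs[act]
    n = A.shape[0]
    if method == "auto":
        method = "direct" if n <= 20000 else "pcg"
    if method == "direct":
        if n <= 6000:
            x = np.linalg.solve(A.toarray(), b)
        else:
            x = splu(A).solve(b)
    elif method == "pcg":
        M = sparse.diags(1.0 / A.diagonal())
        x, info = cg(A, b, M=M, rtol=tol, maxiter=20 * n)
        if info != 0:
            res = float(np.linalg.norm(A @ x - b) / max(np.linalg.norm(b), 1e-30))
            raise RuntimeError(
                f"PCG did not converge (info={info}, relative residual {res:.2e})"
            )
    else:
        raise ValueError(f"unknown method {method!r}")
    theta = np.zeros(system.lhs.shape[0])
    theta[act] = x
    return MmeSolution(theta=theta, design=system.design)
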