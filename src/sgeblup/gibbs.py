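"""Gibbs sampling of all (co)variance components of the direct + social model.

One round consists of

1. single-site Gauss–Seidel draws of every location parameter (fixed,
   genetic, pen, litter) from its normal full conditional;
2. the genetic covariance ``G0`` from its inverted-Wishart full conditional
   with scale ``U' K⁻¹ U + S0`` and degrees of freedom ``n_animals + ν0``;
3. pen and litter variances per trait from scaled inverse chi-square full
   conditionals;
4. per-trait residual variances likewise, using only that trait's records.

Priors default to weakly informative: inverted Wishart with ν0 = n_comp + 2
for ``G0`` and scaled inverse chi-square with ν0 = 4 for every scalar
variance, both scaled to a small fraction of the phenotypic variance.  Fixed
effects carry flat priors.

The coefficient matrix changes every round only through variance
multipliers, so its sparsity union is built once and the per-round data
vector is refreshed by indexed scatter-adds; the location sweep itself runs
in a compiled kernel.  Chains are reproducible bit-for-bit for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.stats import invwishart

from ._kernels import csr_positions, gauss_seidel_sample, quad_form_csr
from .mme import DesignSet, VarComp, assemble_mme

__all__ = ["GibbsConfig", "PosteriorSummary", "GibbsChains", "run_gibbs", "post_gibbs", "effective_sample_size"]


@dataclass
class GibbsConfig:
    """Chain settings; the production default mirrors a long single chain.

    ``retained = floor((total_rounds - burn_in) / thin)`` samples enter every
    posterior summary.
    """

    total_rounds: int = 120_000
    burn_in: int = 20_000
    thin: int = 10
    seed: int = 0
    # priors: inverted Wishart (df, scale) for G0; scaled inverse chi-square
    # (df, scale) for each scalar variance.  None = derive weakly
    # informative defaults from the data variance.
    prior_g0_df: float | None = None
    prior_g0_scale: np.ndarray | None = None
    prior_scalar_df: float = 4.0
    prior_scalar_scale: float | None = None

    def __post_init__(self) -> None:
        if not self.burn_in < self.total_rounds:
            raise ValueError("burn_in must be smaller than total_rounds")
        if self.thin < 1:
            raise ValueError("thin must be at least 1")

    @property
    def n_retained(self) -> int:
        return (self.total_rounds - self.burn_in) // self.thin


@dataclass
class GibbsChains:
    """Retained post-burn-in samples of every variance component."""

    G0: np.ndarray  # (n_samples, n_comp, n_comp)
    var_pen: np.ndarray  # (n_samples, n_traits)
    var_litter: np.ndarray
    var_resid: np.ndarray
    config: GibbsConfig
    design: DesignSet = field(repr=False, default=None)
    location_mean: np.ndarray = field(repr=False, default=None)

    @property
    def n_samples(self) -> int:
        return self.G0.shape[0]

    def to_frame(self):
        import pandas as pd

        spec = self.design.spec
        cols = {}
        for a in range(self.G0.shape[1]):
            for b in range(a, self.G0.shape[2]):
                ta, ea = spec.components[a]
                tb, eb = spec.components[b]
                cols[f"g0_{ea}{ta}_{eb}{tb}"] = self.G0[:, a, b]
        for t in range(self.var_pen.shape[1]):
            cols[f"var_pen_{t}"] = self.var_pen[:, t]
            cols[f"var_litter_{t}"] = self.var_litter[:, t]
            cols[f"var_resid_{t}"] = self.var_resid[:, t]
        return pd.DataFrame(cols)


class _UnionSystem:
    """Fixed-pattern coefficient matrix with per-round data refresh."""

    def __init__(self, design: DesignSet, k_inv, varcomp0: VarComp):
        spec = design.spec
        self.design = design
        # pattern-building varcomp: a dense PD G0 so every cross-component
        # position exists in the union sparsity, whatever G0 is sampled later
        nc = spec.n_comp
        pattern_vc = varcomp0.copy()
        if nc:
            scale = float(np.trace(varcomp0.G0)) / nc or 1.0
            pattern_vc.G0 = scale * (0.5 * np.eye(nc) + 0.5 * np.ones((nc, nc)))
        base = assemble_mme(design, pattern_vc, k_inv)
        lhs = base.lhs.tocsr()
        lhs.sort_indices()
        self.indptr, self.indices = lhs.indptr, lhs.indices
        self.nnz = lhs.nnz
        n_eq = design.n_eq

        # data-part components: W_t' W_t scaled by 1/var_resid[t]
        self.data_parts = []
        for t in range(spec.n_traits):
            wtw = design.W[t].T @ design.W[t]
            wtw.eliminate_zeros()  # cancelled entries are absent from the union
            wtw = wtw.tocoo()
            pos = csr_positions(
                self.indptr, self.indices, wtw.row.astype(np.int64), wtw.col.astype(np.int64)
            )
            assert (pos >= 0).all()
            self.data_parts.append((pos, wtw.data.copy()))
        # genetic prior: for each K⁻¹ entry, an n_comp x n_comp block
        k = sparse.csr_matrix(k_inv).copy()
        k.eliminate_zeros()
        k = k.tocoo()
        nc = spec.n_comp
        off = design.gen_offset
        rows = (off + k.row[:, None, None] * nc + np.arange(nc)[None, :, None]).astype(np.int64)
        cols = (off + k.col[:, None, None] * nc + np.arange(nc)[None, None, :]).astype(np.int64)
        rows = np.broadcast_to(rows, (len(k.data), nc, nc)).ravel()
        cols = np.broadcast_to(cols, (len(k.data), nc, nc)).ravel()
        self.gen_pos = csr_positions(self.indptr, self.indices, rows.copy(), cols.copy())
        assert (self.gen_pos >= 0).all()
        self.k_data = k.data.copy()
        self.k_csr = sparse.csr_matrix(k_inv)
        # pen / litter diagonal positions
        diag_idx = []
        for t in range(spec.n_traits):
            for sl in (design.pen_slices[t], design.litter_slices[t]):
                r = np.arange(sl.start, sl.stop, dtype=np.int64)
                diag_idx.append(csr_positions(self.indptr, self.indices, r, r))
        self.diag_idx = diag_idx  # order: pen0, litter0, pen1, litter1, ...
        self.data = np.zeros(self.nnz)
        self.wty = [design.W[t].T @ design.y[t] for t in range(spec.n_traits)]
        self.rhs = np.zeros(n_eq)

    def refresh(self, varcomp: VarComp) -> None:
        spec = self.design.spec
        self.data[:] = 0.0
        self.rhs[:] = 0.0
        for t, (pos, vals) in enumerate(self.data_parts):
            r_inv = 1.0 / varcomp.var_resid[t]
            np.add.at(self.data, pos, vals * r_inv)  # traits can share entries
            self.rhs += self.wty[t] * r_inv
        if varcomp.G0.size:
            g0_inv = np.linalg.inv(varcomp.G0)
            contrib = (self.k_data[:, None, None] * g0_inv[None, :, :]).ravel()
            self.data[self.gen_pos] += contrib  # positions unique within block
        k = 0
        for t in range(spec.n_traits):
            for var in (varcomp.var_pen[t], varcomp.var_litter[t]):
                idx = self.diag_idx[k]
                k += 1
                if len(idx):
                    self.data[idx] += 1.0 / var


def _default_priors(design: DesignSet, config: GibbsConfig):
    nc = design.spec.n_comp
    vy = float(np.mean([np.var(y) for y in design.y]))
    vy = max(vy, 1e-8)  # degenerate (constant) data still needs proper priors
    g0_df = config.prior_g0_df if config.prior_g0_df is not None else nc + 2.0
    if config.prior_g0_scale is not None:
        g0_scale = np.asarray(config.prior_g0_scale, dtype=float)
    else:
        g0_scale = np.eye(nc) * vy * 0.01
    s_df = config.prior_scalar_df
    s_scale = (
        config.prior_scalar_scale if config.prior_scalar_scale is not None else vy * 0.01
    )
    return g0_df, g0_scale, s_df, s_scale


def run_gibbs(
    design: DesignSet,
    k_inv,
    config: GibbsConfig,
    varcomp0: VarComp | None = None,
) -> GibbsChains:
    """Run the Gibbs sampler and return the retained variance chains."""
    spec = design.spec
    nc = spec.n_comp
    nt = spec.n_traits
    rng = np.random.default_rng(config.seed)
    g0_df, g0_scale, s_df, s_scale = _default_priors(design, config)

    if varcomp0 is None:
        vy = max(float(np.mean([np.var(y) for y in design.y])), 1e-8)
        varcomp0 = VarComp(
            G0=np.eye(nc) * vy * 0.2,
            var_pen=[vy * 0.1] * nt,
            var_litter=[vy * 0.1] * nt,
            var_resid=[vy * 0.6] * nt,
        )
    vc = varcomp0.copy()
    system = _UnionSystem(design, k_inv, vc)
    n_eq = design.n_eq
    theta = np.zeros(n_eq)
    n_anim, gen_off = design.n_anim, design.gen_offset

    n_keep = config.n_retained
    chains = GibbsChains(
        G0=np.zeros((n_keep, nc, nc)),
        var_pen=np.zeros((n_keep, nt)),
        var_litter=np.zeros((n_keep, nt)),
        var_resid=np.zeros((n_keep, nt)),
        config=config,
        design=design,
    )
    loc_sum = np.zeros(n_eq)
    kept = 0
    n_rec = [len(y) for y in design.y]
    n_pen = [sl.stop - sl.start for sl in design.pen_slices]
    n_lit = [sl.stop - sl.start for sl in design.litter_slices]

    for it in range(config.total_rounds):
        system.refresh(vc)
        z = rng.standard_normal(n_eq)
        gauss_seidel_sample(
            system.indptr, system.indices, system.data, system.rhs, theta, z
        )
        # residual variances, per trait
        for t in range(nt):
            e = design.y[t] - design.W[t] @ theta
            ss = float(e @ e) + s_df * s_scale
            vc.var_resid[t] = ss / rng.chisquare(n_rec[t] + s_df)
        # genetic covariance
        if nc > 0:
            U = theta[gen_off : gen_off + n_anim * nc].reshape(n_anim, nc)
            S = quad_form_csr(
                system.k_csr.indptr, system.k_csr.indices, system.k_csr.data, U
            )
            S = 0.5 * (S + S.T) + g0_scale
            draw = invwishart.rvs(df=n_anim + g0_df, scale=S, random_state=rng)
            vc.G0 = np.atleast_2d(draw)
            vc.G0 = 0.5 * (vc.G0 + vc.G0.T)
            if not np.all(np.isfinite(vc.G0)):
                raise FloatingPointError(f"non-finite G0 draw at round {it}")
        # pen and litter variances
        for t in range(nt):
            if n_pen[t]:
                d = theta[design.pen_slices[t]]
                ss = float(d @ d) + s_df * s_scale
                vc.var_pen[t] = ss / rng.chisquare(n_pen[t] + s_df)
            if n_lit[t]:
                l = theta[design.litter_slices[t]]
                ss = float(l @ l) + s_df * s_scale
                vc.var_litter[t] = ss / rng.chisquare(n_lit[t] + s_df)
        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0 and kept < n_keep:
            chains.G0[kept] = vc.G0
            chains.var_pen[kept] = vc.var_pen
            chains.var_litter[kept] = vc.var_litter
            chains.var_resid[kept] = vc.var_resid
            loc_sum += theta
            kept += 1
    chains.location_mean = loc_sum / max(kept, 1)
    return chains


def effective_sample_size(x: np.ndarray) -> float:
    """ESS by Geyer's initial positive sequence of autocovariances."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 4 or np.var(x) == 0:
        return float(n)
    xc = x - x.mean()
    acov = np.correlate(xc, xc, mode="full")[n - 1 :] / n
    rho = acov / acov[0]
    # sum consecutive pairs until a pair sum goes non-positive
    s = 0.0
    for k in range(1, n // 2):
        pair = rho[2 * k - 1] + rho[2 * k]
        if pair <= 0:
            break
        s += pair
    ess = n / (1.0 + 2.0 * s)
    return float(min(max(ess, 1.0), n))


@dataclass
class PosteriorSummary:
    """Posterior means, standard deviations and ESS per reported quantity."""

    mean: dict
    psd: dict
    ess: dict
    n_retained: int
    derived_chains: dict = field(repr=False, default_factory=dict)

    def table(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "mean": pd.Series(self.mean),
                "psd": pd.Series(self.psd),
                "ess": pd.Series(self.ess),
            }
        )


def post_gibbs(
    chains: GibbsChains, avg_pen_size: list | None = None
) -> PosteriorSummary:
    """Posterior summaries, with derived parameters evaluated sample-wise.

    Heritabilities, total heritable variance and correlations are computed
    per retained sample and then averaged — their posterior standard
    deviations are the spreads of those per-sample values.  ``avg_pen_size``
    (per trait) defaults to the value observed in the design.
    """
    from .genparams import population_report

    if chains.n_samples == 0:
        raise ValueError("no retained samples to summarise")
    design = chains.design
    spec = design.spec
    nbar = avg_pen_size if avg_pen_size is not None else design.avg_pen_size
    derived: dict[str, np.ndarray] = {}
    ns = chains.n_samples
    if not spec.include_genetic:
        for t, trait in enumerate(spec.traits):
            derived[f"{trait}.sigma2_e"] = chains.var_resid[:, t]
            if spec.include_pen:
                derived[f"{trait}.sigma2_d"] = chains.var_pen[:, t]
            if spec.include_litter:
                derived[f"{trait}.sigma2_l"] = chains.var_litter[:, t]
        mean = {k: float(np.mean(v)) for k, v in derived.items()}
        psd = {
            k: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
            for k, v in derived.items()
        }
        ess = {k: effective_sample_size(v) for k, v in derived.items()}
        return PosteriorSummary(
            mean=mean, psd=psd, ess=ess, n_retained=ns, derived_chains=derived
        )
    for t, trait in enumerate(spec.traits):
        iD = spec.components.index((t, "D"))
        iS = spec.components.index((t, "S")) if spec.include_social else None
        for name in ("sigma2_aD", "sigma2_aS", "cov_aD_aS", "sigma2_p", "sigma2_TBV", "h2", "T2", "r_DS"):
            derived[f"{trait}.{name}"] = np.zeros(ns)
        derived[f"{trait}.sigma2_d"] = chains.var_pen[:, t]
        derived[f"{trait}.sigma2_l"] = chains.var_litter[:, t]
        derived[f"{trait}.sigma2_e"] = chains.var_resid[:, t]
        for k in range(ns):
            s2d = chains.G0[k, iD, iD]
            s2s = chains.G0[k, iS, iS] if iS is not None else 0.0
            cds = chains.G0[k, iD, iS] if iS is not None else 0.0
            rep = population_report(
                s2d,
                s2s,
                cds,
                chains.var_pen[k, t],
                chains.var_litter[k, t],
                chains.var_resid[k, t],
                nbar[t],
            )
            for name in ("sigma2_aD", "sigma2_aS", "cov_aD_aS", "sigma2_p", "sigma2_TBV", "h2", "T2", "r_DS"):
                derived[f"{trait}.{name}"][k] = rep[name]
    # cross-component correlations, sample-wise
    nc = spec.n_comp
    if nc > 1:
        from .genparams import genetic_correlations

        for a in range(nc):
            for b in range(a + 1, nc):
                ta, ea = spec.components[a]
                tb, eb = spec.components[b]
                key = f"r_{ea}.{spec.traits[ta]}_{eb}.{spec.traits[tb]}"
                vals = np.array(
                    [genetic_correlations(chains.G0[k])[a, b] for k in range(ns)]
                )
                derived[key] = vals
    mean = {k: float(np.mean(v)) for k, v in derived.items()}
    psd = {k: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0 for k, v in derived.items()}
    ess = {k: effective_sample_size(v) for k, v in derived.items()}
    return PosteriorSummary(
        mean=mean, psd=psd, ess=ess, n_retained=ns, derived_chains=derived
    )
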