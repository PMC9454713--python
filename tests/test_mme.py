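"""Design construction and mixed-model equation solving."""

import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from sgeblup.mme import (
    ModelSpec,
    VarComp,
    assemble_mme,
    build_design,
    dilution_factor,
    solve_mme,
)
from sgeblup.pedigree import a_inverse, a_matrix, validate_and_sort
from sgeblup.relmat import SnpWeightState, blend_g, center_genotypes, h_inverse, vanraden_g


class TestDilutionFactor:
    def test_average_pen_gives_one(self):
        assert dilution_factor(4, 4.0) == 1.0

    @pytest.mark.parametrize("avg,size,expect", [(5.0, 3, 2.0), (4.2, 5, 0.8)])
    def test_direct_arithmetic(self, avg, size, expect):
        assert dilution_factor(size, avg) == pytest.approx(expect)

    def test_pen_of_one_rejected(self):
        with pytest.raises(ValueError, match="size 1"):
            dilution_factor(1, 3.0)


def one_trait_pheno(n_pens=4, pen_size=3, seed=0):
    """Small single-population phenotype frame on founder animals."""
    rng = np.random.default_rng(seed)
    rows = []
    a = 1
    for p in range(1, n_pens + 1):
        for _ in range(pen_size):
            rows.append(
                {
                    "animal": a,
                    "population": "purebred",
                    "adg": float(rng.normal(900, 30)),
                    "sex": "M" if a % 2 else "F",
                    "batch": 1,
                    "pen": p,
                    "pen_size": pen_size,
                    "litter": (a - 1) // 4 + 1,
                    "start_wt": float(rng.normal(30000, 1000)),
                    "age_end": float(rng.normal(180, 5)),
                }
            )
            a += 1
    ped = validate_and_sort(
        pd.DataFrame([(i, 0, 0) for i in range(1, a)], columns=["id", "sire", "dam"])
    )
    return pd.DataFrame(rows), ped


class TestBuildDesign:
    def test_social_row_structure_equal_pens(self):
        pheno, ped = one_trait_pheno(n_pens=2, pen_size=3)
        spec = ModelSpec(traits=("purebred",), include_pen=False, include_litter=False)
        des = build_design(pheno, ped, spec)
        W = des.W[0].toarray()
        # row for animal 1 (pen {1,2,3}, dilution 1): social coefficient 1.0
        # at mates' social columns, none at its own
        cS = des.spec.components.index((0, "S"))
        own = des.genetic_column(0, cS)
        m1 = des.genetic_column(1, cS)
        m2 = des.genetic_column(2, cS)
        assert W[0, own] == 0.0
        assert W[0, m1] == 1.0 and W[0, m2] == 1.0

    def test_pen_of_two_with_larger_average(self):
        pheno, ped = one_trait_pheno(n_pens=2, pen_size=2)
        spec = ModelSpec(traits=("purebred",), avg_pen_size={"purebred": 3.0})
        des = build_design(pheno, ped, spec)
        W = des.W[0].toarray()
        cS = des.spec.components.index((0, "S"))
        assert W[0, des.genetic_column(1, cS)] == pytest.approx(2.0)

    def test_social_row_sums_identity(self, small_sim):
        # row sum over social columns = dilution * (pen_size - 1), checked
        # by a brute-force scan of every record
        pheno, ped = small_sim["pheno"], small_sim["ped"]
        spec = ModelSpec()
        des = build_design(pheno, ped, spec)
        for t in range(2):
            sub = des.records[t]
            nbar = des.avg_pen_size[t]
            cS = des.spec.components.index((t, "S"))
            social_cols = np.array(
                [des.genetic_column(a, cS) for a in range(des.n_anim)]
            )
            W = des.W[t].tocsc()[:, social_cols].toarray()
            sums = W.sum(axis=1)
            expect = [
                dilution_factor(int(r.pen_size), nbar) * (int(r.pen_size) - 1)
                for r in sub.itertuples()
            ]
            assert np.allclose(sums, expect, atol=1e-10)

    def test_pen_of_one_rejected(self):
        pheno, ped = one_trait_pheno(n_pens=2, pen_size=3)
        pheno = pheno.iloc[:4]  # second pen has 1 record
        spec = ModelSpec(traits=("purebred",))
        with pytest.raises(ValueError, match="size 1"):
            build_design(pheno, ped, spec)

    def test_duplicate_animal_record_rejected(self):
        pheno, ped = one_trait_pheno()
        dup = pd.concat([pheno, pheno.iloc[:1]], ignore_index=True)
        with pytest.raises(ValueError, match="duplicate"):
            build_design(dup, ped, ModelSpec(traits=("purebred",)))


def simple_varcomp(nc, g=20.0, pen=5.0, lit=5.0, res=50.0, ntr=1):
    return VarComp(
        G0=np.eye(nc) * g,
        var_pen=[pen] * ntr,
        var_litter=[lit] * ntr,
        var_resid=[res] * ntr,
    )


class TestAssembleAndSolve:
    def test_zero_variances_reduce_to_ols(self):
        pheno, ped = one_trait_pheno(n_pens=4, pen_size=3, seed=3)
        spec = ModelSpec(traits=("purebred",), include_social=False)
        des = build_design(pheno, ped, spec)
        vc = VarComp(G0=np.zeros((1, 1)), var_pen=[0.0], var_litter=[0.0], var_resid=[1.0])
        kinv = a_inverse(ped)
        sol = solve_mme(assemble_mme(des, vc, kinv))
        # OLS oracle on the fixed-effect columns
        X = des.W[0][:, des.fixed_slices[0]].toarray()
        beta = np.linalg.lstsq(X, des.y[0], rcond=None)[0]
        assert np.allclose(sol.theta[des.fixed_slices[0]], beta, atol=1e-8)

    def test_ridge_closed_form(self):
        # single trait, direct effect only, A = I, no pen/litter: MME
        # solutions equal the ridge estimate with lambda = var_e / var_a
        pheno, ped = one_trait_pheno(n_pens=2, pen_size=3, seed=4)
        pheno = pheno.iloc[:5].copy()
        pheno["pen"] = [1, 1, 1, 2, 2]
        spec = ModelSpec(
            traits=("purebred",),
            fixed_factors=(),
            covariates=(),
            include_social=False,
            include_pen=False,
            include_litter=False,
        )
        des = build_design(pheno, ped, spec)
        var_a, var_e = 10.0, 40.0
        vc = VarComp(G0=np.array([[var_a]]), var_pen=[0], var_litter=[0], var_resid=[var_e])
        kinv = sparse.identity(len(ped), format="csr")
        sol = solve_mme(assemble_mme(des, vc, kinv))
        W = des.W[0].toarray()
        lam = var_e / var_a
        act = W.any(axis=0)
        Wa = W[:, act]
        D = np.zeros(Wa.shape[1])
        D[1:] = lam  # intercept unpenalised
        oracle = np.linalg.solve(Wa.T @ Wa + np.diag(D), Wa.T @ des.y[0])
        assert np.allclose(sol.theta[act], oracle, atol=1e-8)

    def test_dense_equals_sparse_assembly(self, small_sim):
        pheno, ped = small_sim["pheno"], small_sim["ped"]
        pheno = pheno.groupby("population", group_keys=False).head(25)
        # keep full pens only
        keep = pheno.groupby("pen")["animal"].transform("size") == pheno["pen_size"]
        pheno = pheno[keep]
        spec = ModelSpec()
        des = build_design(pheno, ped, spec)
        vc = simple_varcomp(4, ntr=2)
        kinv = a_inverse(ped)
        system = assemble_mme(des, vc, kinv)
        # dense assembly oracle
        G0inv = np.linalg.inv(vc.G0)
        dense = np.zeros((des.n_eq, des.n_eq))
        for t in range(2):
            W = des.W[t].toarray()
            dense += W.T @ W / vc.var_resid[t]
        K = kinv.toarray()
        gsl = des.genetic_slice()
        dense[gsl, gsl.start : gsl.stop] += np.kron(K, G0inv)
        for t in range(2):
            for sl, v in ((des.pen_slices[t], vc.var_pen[t]), (des.litter_slices[t], vc.var_litter[t])):
                for j in range(sl.start, sl.stop):
                    dense[j, j] += 1.0 / v
        assert np.allclose(system.lhs.toarray(), dense, atol=1e-8)

    def test_identity_lhs_returns_rhs(self):
        from sgeblup.mme import MmeSystem

        pheno, ped = one_trait_pheno()
        des = build_design(pheno, ped, ModelSpec(traits=("purebred",)))
        rhs = np.arange(des.n_eq, dtype=float)
        system = MmeSystem(
            lhs=sparse.identity(des.n_eq, format="csr"),
            rhs=rhs,
            design=des,
            varcomp=None,
            active=np.ones(des.n_eq, bool),
        )
        sol = solve_mme(system, method="direct")
        assert np.allclose(sol.theta, rhs)

    def test_pcg_agrees_with_direct(self, small_sim):
        pheno, ped = small_sim["pheno"], small_sim["ped"]
        des = build_design(pheno, ped, ModelSpec())
        vc = simple_varcomp(4, ntr=2)
        system = assemble_mme(des, vc, a_inverse(ped))
        direct = solve_mme(system, method="direct")
        pcg = solve_mme(system, method="pcg", tol=1e-10)
        assert np.allclose(direct.theta, pcg.theta, atol=1e-6)

    def test_nonpd_g0_rejected(self):
        pheno, ped = one_trait_pheno()
        des = build_design(pheno, ped, ModelSpec(traits=("purebred",)))
        vc = VarComp(
            G0=np.array([[1.0, 2.0], [2.0, 1.0]]),
            var_pen=[1.0],
            var_litter=[1.0],
            var_resid=[1.0],
        )
        with pytest.raises(np.linalg.LinAlgError):
            assemble_mme(des, vc, a_inverse(ped))


class TestSingleStepEquivalences:
    def test_ablup_equals_ssgblup_with_no_genotypes(self, small_sim):
        pheno, ped = small_sim["pheno"], small_sim["ped"]
        des = build_design(pheno, ped, ModelSpec())
        vc = simple_varcomp(4, ntr=2)
        ainv = a_inverse(ped)
        hinv = h_inverse(ainv, np.zeros((0, 0)), np.zeros((0, 0)), np.array([], int))
        sa = solve_mme(assemble_mme(des, vc, ainv))
        sh = solve_mme(assemble_mme(des, vc, hinv))
        assert np.allclose(sa.theta, sh.theta, atol=1e-8)

    def test_all_genotyped_equals_gblup(self):
        # 30-animal fixture, everyone genotyped: MME with H⁻¹ equals GBLUP
        # with G_b⁻¹ as the relationship inverse
        rng = np.random.default_rng(8)
        n = 30
        ped = validate_and_sort(
            pd.DataFrame([(i, 0, 0) for i in range(1, n + 1)], columns=["id", "sire", "dam"])
        )
        dos = rng.choice([0, 1, 2], size=(n, 120))
        Z, p = center_genotypes(dos)
        G = vanraden_g(Z, SnpWeightState.initial(p))
        A22 = a_matrix(ped)
        Gb = blend_g(G, A22, tau=0.05)
        rows = []
        for i in range(1, n + 1):
            rows.append(
                {
                    "animal": i,
                    "population": "purebred",
                    "adg": float(rng.normal(900, 30)),
                    "sex": "M" if i % 2 else "F",
                    "batch": 1,
                    "pen": (i - 1) // 3 + 1,
                    "pen_size": 3,
                    "litter": (i - 1) // 5 + 1,
                    "start_wt": 30000.0,
                    "age_end": 180.0,
                }
            )
        pheno = pd.DataFrame(rows)
        spec = ModelSpec(traits=("purebred",), covariates=())
        des = build_design(pheno, ped, spec)
        vc = simple_varcomp(2)
        ainv = a_inverse(ped)
        hinv = h_inverse(ainv, Gb, A22, np.arange(n))
        sol_h = solve_mme(assemble_mme(des, vc, hinv))
        ginv = sparse.csr_matrix(np.linalg.inv(Gb))
        sol_g = solve_mme(assemble_mme(des, vc, ginv))
        assert np.allclose(sol_h.theta, sol_g.theta, atol=1e-6)

    def test_equal_pens_match_classical_undiluted_model(self):
        # with all pens the same size the dilution factor is 1 everywhere,
        # so solutions equal those of the classical social model
        pheno, ped = one_trait_pheno(n_pens=4, pen_size=3, seed=9)
        spec1 = ModelSpec(traits=("purebred",))
        des1 = build_design(pheno, ped, spec1)
        spec2 = ModelSpec(traits=("purebred",), avg_pen_size={"purebred": 3.0})
        des2 = build_design(pheno, ped, spec2)
        vc = simple_varcomp(2)
        kinv = a_inverse(ped)
        s1 = solve_mme(assemble_mme(des1, vc, kinv))
        s2 = solve_mme(assemble_mme(des2, vc, kinv))
        assert np.allclose(s1.theta, s2.theta, atol=1e-10)
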