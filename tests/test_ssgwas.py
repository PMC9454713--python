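"""SNP back-solving, weight iteration, window variance and QTL calling."""

import numpy as np
import pandas as pd
import pytest

from sgeblup.mme import ModelSpec, VarComp, build_design
from sgeblup.pedigree import a22, a_inverse
from sgeblup.relmat import SnpWeightState, center_genotypes
from sgeblup.simulate import SimConfig, simulate_all
from sgeblup.ssgwas import (
    QtlRegion,
    WindowResult,
    annotate_qtls,
    backsolve_snp_effects,
    call_qtls,
    read_gff3_genes,
    update_weights,
    window_variance,
    wssgblup,
)


@pytest.fixture
def zp(rng):
    d = rng.choice([0, 1, 2], size=(25, 60), p=[0.3, 0.4, 0.3])
    Z, p = center_genotypes(d)
    return Z, p


class TestBacksolve:
    def test_zero_breeding_values_give_zero_effects(self, zp):
        Z, p = zp
        u = backsolve_snp_effects(np.zeros(25), Z, SnpWeightState.initial(p))
        assert np.allclose(u, 0.0)

    def test_projection_identity(self, rng):
        # Z u_hat reconstructs a_hat exactly when ZDZ' is invertible;
        # centring must use external frequencies, otherwise 1'Z = 0 makes
        # ZZ' exactly singular
        d = rng.choice([0, 1, 2], size=(25, 60), p=[0.3, 0.4, 0.3])
        Z, p = center_genotypes(d, freqs=np.full(60, 0.45))
        a_hat = rng.standard_normal(25)
        w = SnpWeightState.initial(p)
        u = backsolve_snp_effects(a_hat, Z, w)
        assert np.allclose(Z @ u, a_hat, atol=1e-8)

    def test_one_snp_scalar_algebra(self):
        # single SNP column z = (1, -1), d = 1, consistent a = (2, -2):
        # the scalar solution of z u = a is u = (z.a)/(z.z) = 2, and the
        # back-solve with a pseudo-inverse (zz' is rank 1) reproduces it
        # up to the d/q prefactor
        Z = np.array([[1.0], [-1.0]])
        w = SnpWeightState(d=np.array([1.0]), p=np.array([0.5]))
        a_hat = np.array([2.0, -2.0])
        u = (w.d / w.q) * (Z.T @ (np.linalg.pinv(Z @ Z.T) @ a_hat))
        scalar_oracle = (Z[:, 0] @ a_hat) / (Z[:, 0] @ Z[:, 0])
        assert u[0] == pytest.approx((w.d[0] / w.q) * scalar_oracle, rel=1e-12)
        assert np.allclose(Z @ (u * w.q / w.d), a_hat)


class TestUpdateWeights:
    def test_symmetric_input_gives_unit_weights(self):
        p = np.full(10, 0.3)
        w = SnpWeightState.initial(p)
        u = np.full(10, 0.7)
        w2 = update_weights(u, w)
        assert np.allclose(w2.d, 1.0)
        assert w2.iteration == 1

    def test_scale_invariance(self, rng):
        p = rng.uniform(0.1, 0.9, 30)
        u = rng.standard_normal(30)
        w = SnpWeightState.initial(p)
        assert np.allclose(update_weights(u, w).d, update_weights(2 * u, w).d)

    def test_conservation_of_weighted_heterozygosity(self, rng):
        p = rng.uniform(0.05, 0.95, 100)
        u = rng.standard_normal(100)
        w = SnpWeightState.initial(p)
        w2 = update_weights(u, w)
        assert w2.het_sum() == pytest.approx(w.q, abs=1e-10)

    def test_all_zero_effects_rejected(self):
        w = SnpWeightState.initial(np.full(5, 0.4))
        with pytest.raises(ValueError, match="degenerate"):
            update_weights(np.zeros(5), w)


def snp_frame(bps, chrom="1"):
    return pd.DataFrame(
        {"snp": [f"s{i}" for i in range(len(bps))], "chrom": chrom, "bp": bps}
    )


class TestWindowVariance:
    def test_single_window_self_normalises_to_100(self, zp, rng):
        Z, p = zp
        u = rng.standard_normal(60) * 0.01
        mp = snp_frame(np.linspace(1000, 300_000, 60).astype(int))
        wins = window_variance(Z, u, mp, window_bp=400_000)
        assert len(wins) == 1
        assert wins[0].pct_variance == pytest.approx(100.0)

    def test_zero_effects_zero_percent(self, zp):
        Z, p = zp
        mp = snp_frame(np.linspace(1000, 300_000, 60).astype(int))
        u = np.zeros(60)
        u[0] = 1.0  # total variance nonzero
        mp2 = snp_frame(
            np.concatenate([[100], np.linspace(500_000, 700_000, 59)]).astype(int)
        )
        wins = window_variance(Z, u, mp2, window_bp=400_000)
        late = [w for w in wins if w.start_bp >= 400_000]
        assert all(w.pct_variance == pytest.approx(0.0) for w in late)

    def test_windows_tile_and_partition_snps(self, zp, rng):
        Z, p = zp
        u = rng.standard_normal(60)
        bps = rng.integers(1, 2_000_000, size=60)
        mp = snp_frame(np.sort(bps))
        wins = window_variance(Z, u, mp, window_bp=400_000)
        all_snps = [s for w in wins for s in w.snps]
        assert sorted(all_snps) == sorted(mp["snp"])
        starts = [w.start_bp for w in wins]
        assert starts == sorted(starts)
        assert all(w.start_bp % 400_000 == 0 for w in wins)

    def test_unlinked_snps_window_percents_sum_near_100(self, rng):
        # independent SNPs: window variances are nearly additive
        n, m = 400, 50
        d = rng.choice([0, 1, 2], size=(n, m), p=[0.25, 0.5, 0.25])
        Z, p = center_genotypes(d)
        u = rng.standard_normal(m)
        mp = snp_frame(np.linspace(0, 10_000_000, m).astype(int))
        wins = window_variance(Z, u, mp, window_bp=400_000)
        total = sum(w.pct_variance for w in wins)
        assert total == pytest.approx(100.0, abs=12.0)


class TestCallQtls:
    def win(self, pct, start, end=None, chrom="10", comp="DGE.purebred"):
        return WindowResult(
            chrom=chrom,
            start_bp=start,
            end_bp=end if end is not None else start + 400_000,
            snps=[],
            pct_variance=pct,
            component=comp,
        )

    def test_no_significant_windows(self):
        assert call_qtls([self.win(0.39, 0)]) == []

    def test_region_centered_on_window_midpoint(self):
        # a 0.7% window centred at 31.9 Mb yields the 31.4-32.4 Mb region
        w = self.win(0.7, 31_700_000, 32_100_000)
        (q,) = call_qtls([w])
        assert (q.start_bp, q.end_bp) == (31_400_000, 32_400_000)
        assert q.peak_pct == pytest.approx(0.7)

    def test_nearby_windows_merge_keeping_peak(self):
        a = self.win(0.5, 10_000_000)
        b = self.win(0.9, 10_700_000)  # regions 0.3 Mb apart -> overlap
        (q,) = call_qtls([a, b])
        assert q.peak_pct == pytest.approx(0.9)
        assert q.start_bp == 9_700_000 and q.end_bp == 11_400_000

    def test_components_do_not_merge(self):
        a = self.win(0.5, 10_000_000, comp="DGE.purebred")
        b = self.win(0.6, 10_200_000, comp="SGE.purebred")
        assert len(call_qtls([a, b])) == 2

    def test_clipped_at_chromosome_end(self):
        w = self.win(0.8, 0, 400_000)
        (q,) = call_qtls([w], chrom_lengths={"10": 600_000})
        assert q.start_bp == 0 and q.end_bp == 600_000


class TestGff3:
    def write_gff(self, tmp_path, lines):
        path = tmp_path / "genes.gff3"
        path.write_text("##gff-version 3\n" + "\n".join(lines) + "\n")
        return path

    def gene(self, seqid, start, end, name):
        return (
            f"{seqid}\tsrc\tgene\t{start}\t{end}\t.\t+\t.\tID=gene-{name};Name={name}"
        )

    def test_overlap_enumeration(self, tmp_path):
        genes = [self.gene("10", s, s + 50_000, f"G{i}") for i, s in enumerate(
            [100_000, 500_000, 900_000, 1_500_000, 2_000_000, 2_500_000,
             3_000_000, 3_500_000, 4_000_000, 4_500_000]
        )]
        path = self.write_gff(tmp_path, genes)
        qtl = QtlRegion("10", 400_000, 1_600_000, 0.5, "DGE")
        hits = annotate_qtls([qtl], path)[0]
        assert hits == ["G1", "G2", "G3"]

    def test_gene_ending_just_before_not_reported(self, tmp_path):
        path = self.write_gff(tmp_path, [self.gene("1", 100, 1_000_000, "A")])
        qtl = QtlRegion("1", 1_000_000, 2_000_000, 0.5, "DGE")  # starts at 1,000,001
        assert annotate_qtls([qtl], path)[0] == []
        qtl2 = QtlRegion("1", 999_999, 2_000_000, 0.5, "DGE")
        assert annotate_qtls([qtl2], path)[0] == ["A"]

    def test_malformed_line_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.gff3"
        path.write_text("##gff-version 3\n1\tsrc\tgene\t1\n")
        with pytest.raises(ValueError, match="line 2"):
            read_gff3_genes(path)


class TestWssgblup:
    @pytest.fixture(scope="class")
    def gwas_sim(self):
        cfg = SimConfig(
            seed=31,
            n_founders_per_breed={"DUC": 60, "KNP": 10},
            n_generations=2,
            n_litters_per_gen={"DUC": 20, "CROSS": 0},
            litter_size_mean=6.0,
            n_snps=400,
            n_chromosomes=2,
            pen_size_levels=(4,),
            marker_effect_mode=True,
            qtl=((37, 0.10),),
            true_G0=np.diag([30.0, 2.0, 30.0, 2.0]),
            var_group=(5.0, 5.0),
            var_litter=(5.0, 5.0),
            var_resid=(58.0, 58.0),
            mean_adg=(0.0, 0.0),
            sex_effect=5.0,
            batch_sd=1.0,
            slope_start_wt=0.0,
            slope_age_end=0.0,
        )
        ped, gset, pheno, truth = simulate_all(cfg)
        spec = ModelSpec(traits=("purebred",), covariates=())
        des = build_design(pheno, ped, spec)
        vc = VarComp(
            G0=np.array([[30.0, 0.0], [0.0, 2.0]]),
            var_pen=[5.0],
            var_litter=[5.0],
            var_resid=[58.0],
        )
        gidx = np.flatnonzero(np.isin(ped.ids, pheno["animal"]))
        sub = gset.take_animals(gidx)
        A22 = a22(ped, sub.animal_ids, method="dense")
        ainv = a_inverse(ped)
        return {
            "ped": ped,
            "gset": sub,
            "des": des,
            "vc": vc,
            "ainv": ainv,
            "A22": A22,
            "gidx": gidx,
            "truth": truth,
        }

    def test_weight_of_planted_qtl_increases(self, gwas_sim):
        s = gwas_sim
        res = wssgblup(
            s["des"], s["gset"], s["vc"], s["ainv"], s["A22"], s["gidx"],
            components=[0], n_iter=3,
        )
        w = res["components"][0]["weights"]
        assert w.iteration == 2  # two updates over three iterations
        assert w.d[37] > 1.0
        assert w.d[37] > np.median(w.d) * 3

    def test_single_iteration_is_plain_backsolve(self, gwas_sim):
        s = gwas_sim
        res = wssgblup(
            s["des"], s["gset"], s["vc"], s["ainv"], s["A22"], s["gidx"],
            components=[0], n_iter=1,
        )
        w = res["components"][0]["weights"]
        assert np.allclose(w.d, 1.0)

    def test_deterministic(self, gwas_sim):
        s = gwas_sim
        r1 = wssgblup(
            s["des"], s["gset"], s["vc"], s["ainv"], s["A22"], s["gidx"],
            components=[0], n_iter=2,
        )
        r2 = wssgblup(
            s["des"], s["gset"], s["vc"], s["ainv"], s["A22"], s["gidx"],
            components=[0], n_iter=2,
        )
        assert np.array_equal(
            r1["components"][0]["u_hat"], r2["components"][0]["u_hat"]
        )

    def test_planted_qtl_called(self, gwas_sim):
        s = gwas_sim
        res = wssgblup(
            s["des"], s["gset"], s["vc"], s["ainv"], s["A22"], s["gidx"],
            components=[0], n_iter=3,
        )
        u = res["components"][0]["u_hat"]
        wins = window_variance(
            res["Z"], u, s["gset"].snp_map, component="DGE.purebred"
        )
        qtls = call_qtls(wins)
        qtl_bp = int(s["gset"].snp_map["bp"].iloc[37])
        qtl_chrom = str(s["gset"].snp_map["chrom"].iloc[37])
        assert any(
            q.chrom == qtl_chrom and q.start_bp <= qtl_bp <= q.end_bp for q in qtls
        )
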