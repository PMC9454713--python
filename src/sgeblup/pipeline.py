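"""End-to-end driver: simulate → qc → relmat → fit → params → gwas → report.

Configuration is one YAML file with per-stage sections; every stage writes
its outputs under the run directory and records them (with checksums) in a
manifest.  A stage is skipped on re-run when its configuration and its
inputs' checksums are unchanged, so editing only the QTL threshold re-runs
only the GWAS and report stages.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import sparse

DEFAULT_CONFIG = {
    "seed": 1,
    "outdir": "sgeblup_run",
    "simulate": {
        "n_founders_per_breed": {"DUC": 80, "KNP": 24},
        "n_generations": 3,
        "n_litters_per_gen": {"DUC": 24, "CROSS": 24},
        "litter_size_mean": 6.0,
        "pen_size_levels": [2, 3, 4, 5, 6, 7],
        "n_snps": 1000,
        "n_chromosomes": 5,
        "chrom_length_bp": 100_000_000,
    },
    "qc": {"conflict_threshold": 0.01},
    "relmat": {"tau": 0.05},
    "fit": {
        "relationship": "H",  # A or H
        "total_rounds": 12_000,
        "burn_in": 2_000,
        "thin": 10,
    },
    "gwas": {
        "n_iter": 3,
        "window_bp": 400_000,
        "qtl_threshold": 0.4,
        "components": None,  # default: all genetic components
    },
}

STAGES = ["simulate", "qc", "relmat", "fit", "params", "gwas", "report"]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _cfg_hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()


def load_config(path=None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for k, v in user.items():
            if isinstance(v, dict) and isinstance(cfg.get(k), dict):
                cfg[k].update(v)
            else:
                cfg[k] = v
    return cfg


class PipelineRun:
    """Stateful pipeline over one run directory with cached stages."""

    def __init__(self, config: dict):
        self.config = config
        self.outdir = Path(config["outdir"])
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.outdir / "manifest.json"
        if self.manifest_path.exists():
            with open(self.manifest_path) as fh:
                self.manifest = json.load(fh)
        else:
            self.manifest = {"stages": {}, "seed": config["seed"]}
        self._mem: dict = {}

    # -- caching helpers -------------------------------------------------
    def _stage_key(self, stage: str, inputs: list, extra_config=None) -> str:
        dep = {
            "config": self.config.get(stage, {}),
            "extra": extra_config,
            "seed": self.config["seed"],
            "inputs": {str(p): _sha256(Path(p)) for p in inputs if Path(p).exists()},
        }
        return _cfg_hash(dep)

    def _is_cached(self, stage: str, key: str, outputs: list) -> bool:
        rec = self.manifest["stages"].get(stage)
        return (
            rec is not None
            and rec.get("key") == key
            and all(Path(p).exists() for p in outputs)
        )

    def _record(self, stage: str, key: str, outputs: list, t0: float) -> None:
        self.manifest["stages"][stage] = {
            "key": key,
            "outputs": {str(p): _sha256(Path(p)) for p in outputs},
            "seconds": round(time.time() - t0, 2),
        }
        with open(self.manifest_path, "w") as fh:
            json.dump(self.manifest, fh, indent=2)

    def _path(self, name: str) -> Path:
        return self.outdir / name

    # -- stages ----------------------------------------------------------
    def stage_simulate(self) -> bool:
        from .simulate import SimConfig, simulate_all

        out = [self._path(n) for n in (
            "pedigree.csv", "genotypes.ped", "genotypes.map",
            "phenotypes.tsv", "truth_animals.tsv", "manifest.json")]
        key = self._stage_key("simulate", [])
        if self._is_cached("simulate", key, out[:5]):
            return False
        t0 = time.time()
        sim = dict(self.config["simulate"])
        sim["pen_size_levels"] = tuple(sim.get("pen_size_levels", (2, 3, 4, 5, 6, 7)))
        cfg = SimConfig(seed=self.config["seed"], **sim)
        simulate_all(cfg, outdir=self.outdir)
        self._record("simulate", key, out[:5], t0)
        return True

    def _load_inputs(self):
        from .genotypes import read_plink
        from .pedigree import Pedigree

        if "ped" not in self._mem:
            self._mem["ped"] = Pedigree.from_csv(self._path("pedigree.csv"))
            self._mem["pheno"] = pd.read_csv(self._path("phenotypes.tsv"), sep="\t")
            self._mem["gset_raw"] = read_plink(str(self._path("genotypes")))
        return self._mem["ped"], self._mem["pheno"], self._mem["gset_raw"]

    def stage_qc(self) -> bool:
        from .genotypes import write_plink
        from .qc import run_qc

        inputs = [self._path("genotypes.ped"), self._path("pedigree.csv")]
        out = [self._path("genotypes_qc.ped"), self._path("genotypes_qc.map"),
               self._path("qc_report.json")]
        key = self._stage_key("qc", inputs)
        if self._is_cached("qc", key, out):
            return False
        t0 = time.time()
        ped, _, gset = self._load_inputs()
        clean, report = run_qc(gset, ped, **self.config["qc"])
        write_plink(clean, str(self._path("genotypes_qc")))
        report.to_json(self._path("qc_report.json"))
        with open(self._path("qc_report.log"), "w") as fh:
            fh.write(report.summary() + "\n")
        self._record("qc", key, out, t0)
        return True

    def stage_relmat(self) -> bool:
        from .genotypes import read_plink
        from .pedigree import a22 as a22_fn
        from .pedigree import a_inverse
        from .relmat import SnpWeightState, blend_g, center_genotypes, vanraden_g

        inputs = [self._path("genotypes_qc.ped"), self._path("pedigree.csv")]
        out = [self._path("relmat.npz")]
        key = self._stage_key("relmat", inputs)
        if self._is_cached("relmat", key, out):
            return False
        t0 = time.time()
        ped, _, _ = self._load_inputs()
        clean = read_plink(str(self._path("genotypes_qc")))
        Z, p = center_genotypes(clean.dosages)
        G = vanraden_g(Z, SnpWeightState.initial(p))
        A22 = a22_fn(ped, clean.animal_ids)
        Gb = blend_g(G, A22, tau=self.config["relmat"]["tau"])
        ainv = a_inverse(ped)
        np.savez(
            self._path("relmat.npz"),
            Gb=Gb,
            A22=A22,
            p=p,
            genotyped_ids=clean.animal_ids,
            ainv_data=ainv.data,
            ainv_indices=ainv.indices,
            ainv_indptr=ainv.indptr,
        )
        self._record("relmat", key, out, t0)
        return True

    def _k_inverse(self):
        from .relmat import h_inverse

        ped, _, _ = self._load_inputs()
        dat = np.load(self._path("relmat.npz"), allow_pickle=True)
        n = len(ped)
        ainv = sparse.csr_matrix(
            (dat["ainv_data"], dat["ainv_indices"], dat["ainv_indptr"]), shape=(n, n)
        )
        if self.config["fit"]["relationship"].upper() == "A":
            return ainv
        gidx = ped.index_of(dat["genotyped_ids"])
        return h_inverse(ainv, dat["Gb"], dat["A22"], gidx)

    def stage_fit(self) -> bool:
        from .gibbs import GibbsConfig, post_gibbs, run_gibbs
        from .mme import ModelSpec, build_design

        inputs = [self._path("phenotypes.tsv"), self._path("relmat.npz")]
        out = [self._path("chains.csv"), self._path("posterior.json")]
        key = self._stage_key("fit", inputs)
        if self._is_cached("fit", key, out):
            return False
        t0 = time.time()
        ped, pheno, _ = self._load_inputs()
        traits = tuple(sorted(pheno["population"].unique()))
        spec = ModelSpec(traits=traits)
        design = build_design(pheno, ped, spec)
        kinv = self._k_inverse()
        fit_cfg = self.config["fit"]
        gc = GibbsConfig(
            total_rounds=fit_cfg["total_rounds"],
            burn_in=fit_cfg["burn_in"],
            thin=fit_cfg["thin"],
            seed=self.config["seed"],
        )
        chains = run_gibbs(design, kinv, gc)
        chains.to_frame().to_csv(self._path("chains.csv"), index=False)
        summary = post_gibbs(chains)
        payload = {
            "mean": summary.mean,
            "psd": summary.psd,
            "ess": summary.ess,
            "n_retained": summary.n_retained,
            "avg_pen_size": dict(zip(spec.traits, design.avg_pen_size)),
        }
        with open(self._path("posterior.json"), "w") as fh:
            json.dump(payload, fh, indent=2)
        self._mem["design"] = design
        self._mem["summary"] = summary
        self._record("fit", key, out, t0)
        return True

    def stage_params(self) -> bool:
        inputs = [self._path("posterior.json")]
        out = [self._path("genetic_parameters.tsv")]
        key = self._stage_key("params", inputs)
        if self._is_cached("params", key, out):
            return False
        t0 = time.time()
        with open(self._path("posterior.json")) as fh:
            post = json.load(fh)
        rows = []
        for trait in post["avg_pen_size"]:
            for q in ("sigma2_aD", "sigma2_aS", "cov_aD_aS", "sigma2_d", "sigma2_l",
                      "sigma2_e", "sigma2_p", "sigma2_TBV", "h2", "T2", "r_DS"):
                k = f"{trait}.{q}"
                if k in post["mean"]:
                    rows.append(
                        {
                            "population": trait,
                            "parameter": q,
                            "mean": post["mean"][k],
                            "psd": post["psd"][k],
                            "n_bar": post["avg_pen_size"][trait],
                        }
                    )
        pd.DataFrame(rows).to_csv(out[0], sep="\t", index=False)
        self._record("params", key, [str(o) for o in out], t0)
        return True

    def stage_gwas(self) -> bool:
        from .genotypes import read_plink
        from .mme import ModelSpec, VarComp, build_design
        from .ssgwas import call_qtls, window_variance, windows_to_frame, wssgblup

        inputs = [self._path("posterior.json"), self._path("relmat.npz"),
                  self._path("genotypes_qc.ped")]
        out = [self._path("snp_effects.tsv"), self._path("windows.tsv"),
               self._path("qtls.bed")]
        key = self._stage_key("gwas", inputs)
        if self._is_cached("gwas", key, out):
            return False
        t0 = time.time()
        ped, pheno, _ = self._load_inputs()
        clean = read_plink(str(self._path("genotypes_qc")))
        with open(self._path("posterior.json")) as fh:
            post = json.load(fh)
        traits = tuple(sorted(pheno["population"].unique()))
        spec = ModelSpec(traits=traits)
        design = build_design(pheno, ped, spec)
        # variance components fixed at posterior means
        nc = spec.n_comp
        G0 = np.zeros((nc, nc))
        for a, (ta, ea) in enumerate(spec.components):
            for b, (tb, eb) in enumerate(spec.components):
                kk = f"g0_{ea}{ta}_{eb}{tb}" if a <= b else f"g0_{eb}{tb}_{ea}{ta}"
                chains = pd.read_csv(self._path("chains.csv"))
                if kk in chains:
                    G0[a, b] = chains[kk].mean()
        G0 = 0.5 * (G0 + G0.T)
        vc = VarComp(
            G0=G0,
            var_pen=[post["mean"][f"{t}.sigma2_d"] for t in spec.traits],
            var_litter=[post["mean"][f"{t}.sigma2_l"] for t in spec.traits],
            var_resid=[post["mean"][f"{t}.sigma2_e"] for t in spec.traits],
        )
        dat = np.load(self._path("relmat.npz"), allow_pickle=True)
        n = len(ped)
        ainv = sparse.csr_matrix(
            (dat["ainv_data"], dat["ainv_indices"], dat["ainv_indptr"]), shape=(n, n)
        )
        gidx = ped.index_of(clean.animal_ids)
        gcfg = self.config["gwas"]
        comps = gcfg["components"] or list(range(nc))
        res = wssgblup(
            design, clean, vc, ainv, dat["A22"], gidx,
            components=comps, n_iter=gcfg["n_iter"],
            tau=self.config["relmat"]["tau"],
        )
        eff_rows, win_frames, qtl_rows = [], [], []
        for c in comps:
            t, e = spec.components[c]
            label = f"{'DGE' if e == 'D' else 'SGE'}.{spec.traits[t]}"
            comp = res["components"][c]
            eff = clean.snp_map.copy()
            eff["component"] = label
            eff["u_hat"] = comp["u_hat"]
            eff["weight"] = comp["weights"].d
            eff_rows.append(eff)
            wins = window_variance(
                res["Z"], comp["u_hat"], clean.snp_map,
                window_bp=gcfg["window_bp"], component=label,
            )
            win_frames.append(windows_to_frame(wins))
            for q in call_qtls(wins, threshold_pct=gcfg["qtl_threshold"]):
                qtl_rows.append(
                    f"{q.chrom}\t{q.start_bp}\t{q.end_bp}\t{q.component}\t{q.peak_pct:.4f}"
                )
        pd.concat(eff_rows).to_csv(out[0], sep="\t", index=False)
        pd.concat(win_frames).to_csv(out[1], sep="\t", index=False)
        with open(out[2], "w") as fh:
            fh.write("\n".join(qtl_rows) + ("\n" if qtl_rows else ""))
        self._record("gwas", key, [str(o) for o in out], t0)
        return True

    def stage_report(self) -> bool:
        inputs = [self._path("genetic_parameters.tsv"), self._path("windows.tsv"),
                  self._path("qtls.bed"), self._path("qc_report.json")]
        out = [self._path("report.txt")]
        key = self._stage_key("report", inputs, extra_config=self.config["gwas"])
        if self._is_cached("report", key, out):
            return False
        t0 = time.time()
        lines = ["sgeblup run report", "=" * 40]
        params = pd.read_csv(self._path("genetic_parameters.tsv"), sep="\t")
        for trait, sub in params.groupby("population"):
            lines.append(f"\n[{trait}] (n_bar = {sub['n_bar'].iloc[0]:.2f})")
            for r in sub.itertuples():
                lines.append(f"  {r.parameter:12s} {r.mean:10.3f} ({r.psd:.3f})")
        wins = pd.read_csv(self._path("windows.tsv"), sep="\t")
        thr = self.config["gwas"]["qtl_threshold"]
        sig = wins[wins["pct_variance"] > thr]
        lines.append(f"\nwindows above {thr}%: {len(sig)} of {len(wins)}")
        for comp, sub in sig.groupby("component"):
            lines.append(f"  {comp}: {len(sub)} windows, sum {sub['pct_variance'].sum():.2f}%")
        text = "\n".join(lines) + "\n"
        with open(out[0], "w") as fh:
            fh.write(text)
        self._record("report", key, [str(o) for o in out], t0)
        return True

    def run(self, stages=None) -> dict:
        """Execute the requested stages in order; returns {stage: ran?}."""
        todo = STAGES if stages is None else [s for s in STAGES if s in stages]
        ran = {}
        for s in todo:
            fn = getattr(self, f"stage_{s}")
            try:
                ran[s] = fn()
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {s!r} failed: {exc}") from exc
        return ran


def run_pipeline(config_path=None, config: dict | None = None, stages=None) -> dict:
    """Convenience wrapper: load config, run stages, return the manifest."""
    cfg = config if config is not None else load_config(config_path)
    run = PipelineRun(cfg)
    ran = run.run(stages)
    return {"ran": ran, "manifest": run.manifest, "outdir": str(run.outdir)}
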