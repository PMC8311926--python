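"""End-to-end orchestration: simulate/load -> normalize -> GRM -> variance
components -> genome scans -> permutation FDR -> fine-mapping.

Every stage writes TSV outputs into a deterministic run-directory layout
and appends a structured line (stage, seed, wall time, counts) to
``log.txt``. Reruns with the same configuration and seed reproduce the
deterministic stages bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cages import CageStructure
from .covariance import component_matrices
from .fdr import estimate_fdr, loci_to_frame, permute_scan
from .grm import compute_grm, flag_related_cages
from .io import (
    read_cage_assignments,
    read_covariates,
    read_genotypes_hdf5,
    read_genotypes_tsv,
    read_phenotypes,
    write_grm_tsv,
)
from .normalize import boxcox_normalize, filter_stable_cages
from .qvalue import qvalues
from .simulate import SimulationSpec, simulate_dataset
from .varcomp import analyze_phenotype, subset_comps

__all__ = ["RunConfig", "ValidationError", "run_pipeline"]


class ValidationError(ValueError):
    """Raised when inputs fail consistency checks (CLI exit code 2)."""


@dataclass
class RunConfig:
    out_dir: str = "run"
    # either simulate ...
    simulate: SimulationSpec | None = None
    # ... or load from files
    genotypes_path: str | None = None
    phenotypes_path: str | None = None
    covariates_path: str | None = None
    cages_path: str | None = None
    phenotypes: list = field(default_factory=list)
    covariate_map: dict = field(default_factory=dict)  # phenotype -> columns
    cage_size: int = 3
    normalize: bool = True
    sibling_threshold: float = 0.3
    maf_min: float = 0.01
    modes: tuple = ("ige",)
    condition: bool = True
    social_coding: str = "sum"
    collapse_env: bool | None = None
    n_restarts: int = 1
    K: int = 100
    fdr_threshold: float = 0.10
    clump_window_bp: int = 1_500_000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "simulate" in raw and raw["simulate"] is not None:
            raw["simulate"] = SimulationSpec(**raw["simulate"])
        if "modes" in raw:
            raw["modes"] = tuple(raw["modes"])
        return cls(**raw)

    def to_yaml(self, path):
        raw = dataclasses.asdict(self)
        if self.simulate is not None:
            raw["simulate"] = dataclasses.asdict(self.simulate)
        raw["modes"] = list(self.modes)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


class _Log:
    def __init__(self, path):
        self.path = Path(path)
        self.t0 = time.time()

    def write(self, stage: str, **info):
        line = f"[{time.time() - self.t0:8.2f}s] {stage}: " + " ".join(
            f"{k}={v}" for k, v in info.items()
        )
        with open(self.path, "a") as fh:
            fh.write(line + "\n")


def _load_inputs(config: RunConfig, log: _Log):
    if config.simulate is not None:
        spec = dataclasses.replace(config.simulate, seed=config.seed)
        genotypes, cages, y, realised = simulate_dataset(spec)
        phenos = pd.DataFrame(
            {"simulated": y}, index=pd.Index(genotypes.individual_ids, name="individual_id")
        )
        covars = pd.DataFrame(
            index=pd.Index(genotypes.individual_ids, name="individual_id")
        )
        cage_df = pd.DataFrame(
            {
                "individual_id": cages.individual_ids,
                "cage_id": cages.cage_labels,
            }
        )
        log.write("simulate", n=genotypes.n, p=genotypes.p, seed=spec.seed)
        truth = {
            "fractions": realised["fractions"],
            "beta": realised["beta"],
            "causal_index": realised["causal_index"],
        }
        return genotypes, phenos, covars, cage_df, truth
    for name, path in (
        ("genotypes_path", config.genotypes_path),
        ("phenotypes_path", config.phenotypes_path),
        ("cages_path", config.cages_path),
    ):
        if path is None:
            raise ValidationError(f"config missing {name} (and no simulate block)")
    path = str(config.genotypes_path)
    genotypes = (
        read_genotypes_hdf5(path)
        if path.endswith((".h5", ".hdf5"))
        else read_genotypes_tsv(path)
    )
    phenos = read_phenotypes(config.phenotypes_path)
    covars = (
        read_covariates(config.covariates_path)
        if config.covariates_path
        else pd.DataFrame(index=phenos.index)
    )
    cage_df = read_cage_assignments(config.cages_path)
    log.write("load", n=genotypes.n, p=genotypes.p)
    return genotypes, phenos, covars, cage_df, None


def run_pipeline(config: RunConfig) -> Path:
    """Run all configured stages; returns the run directory path.

    Halts with the failing stage recorded in the log; outputs of completed
    stages are preserved.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "scans").mkdir(exist_ok=True)
    (out / "perms").mkdir(exist_ok=True)
    log = _Log(out / "log.txt")
    config.to_yaml(out / "config.yaml")
    log.write("config", seed=config.seed, out=str(out))

    genotypes, phenos, covars, cage_df, truth = _load_inputs(config, log)
    if truth is not None:
        with open(out / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=2, default=float)

    # cage-stability filter, then alignment of all tables
    stable = filter_stable_cages(cage_df, cage_size=config.cage_size)
    cage_final = cage_df.drop_duplicates("individual_id", keep="last")
    cage_final = cage_final[cage_final["individual_id"].isin(stable)]
    cage_of = dict(zip(cage_final["individual_id"], cage_final["cage_id"]))

    geno_ids = [str(i) for i in genotypes.individual_ids]
    missing_cage = [i for i in phenos.index if str(i) not in cage_of]
    usable = [i for i, iid in enumerate(geno_ids) if iid in cage_of]
    if not usable:
        raise ValidationError("no individuals remain after the cage filter")
    if missing_cage and not config.simulate:
        raise ValidationError(
            f"phenotyped individual(s) without a stable cage: {missing_cage[:5]}"
        )
    genotypes = genotypes.subset_individuals(usable)
    geno_ids = [str(i) for i in genotypes.individual_ids]
    cages = CageStructure(
        np.array([cage_of[i] for i in geno_ids]), genotypes.individual_ids
    )
    log.write("cage_filter", retained=len(usable), cages=cages.n_cages)

    genotypes = genotypes.filter_maf(config.maf_min)
    A = compute_grm(genotypes)
    excluded = flag_related_cages(A, cages, config.sibling_threshold)
    if excluded:
        keep = np.flatnonzero(~np.isin(cages.cage_labels, list(excluded)))
        genotypes = genotypes.subset_individuals(keep)
        cages = cages.subset(keep)
        A = compute_grm(genotypes)
        geno_ids = [str(i) for i in genotypes.individual_ids]
    write_grm_tsv(A, genotypes.individual_ids, out / "grm.tsv")
    log.write("grm", n=A.shape[0], excluded_cages=len(excluded))

    comps = component_matrices(A, cages, collapsed=False)
    pheno_names = config.phenotypes or [
        c for c in phenos.columns if c != "individual_id"
    ]
    id_pos = {iid: k for k, iid in enumerate(geno_ids)}

    varcomp_rows = []
    norm_frames = {}
    ige_pvals = []
    for pheno in pheno_names:
        series = phenos[pheno]
        series = series[[str(i) in id_pos for i in series.index]]
        series = series.dropna()
        focal_ids = [str(i) for i in series.index]
        focal_idx = np.array([id_pos[i] for i in focal_ids])
        yraw = series.to_numpy(dtype=float)

        cov_cols = config.covariate_map.get(pheno, [c for c in covars.columns])
        Xcov = (
            covars.loc[series.index, cov_cols].to_numpy(dtype=float)
            if cov_cols
            else np.empty((len(yraw), 0))
        )
        if Xcov.size:  # constant columns would be collinear with the intercept
            Xcov = Xcov[:, Xcov.std(axis=0) > 1e-12]
        if config.normalize:
            res = boxcox_normalize(yraw, covariates=Xcov if Xcov.size else None)
            if not res.accepted:
                log.write("normalize", phenotype=pheno, accepted=False,
                          lmbda=res.lmbda)
                continue
            yn = res.normalized
            log.write("normalize", phenotype=pheno, lmbda=res.lmbda,
                      accepted=True)
        else:
            yn = (yraw - yraw.mean()) / yraw.std()
        norm_frames[pheno] = pd.DataFrame(
            {"individual_id": focal_ids, pheno: yn}
        )
        X = np.column_stack([np.ones(len(yn)), Xcov]) if Xcov.size else np.ones(
            (len(yn), 1)
        )
        comps_f = subset_comps(comps, focal_idx)
        analysis = analyze_phenotype(
            yn, X, A, cages,
            collapse_env=config.collapse_env,
            n_restarts=config.n_restarts, seed=config.seed, comps=comps_f,
        )
        cfit = analysis.fit
        p_ige = analysis.p_ige
        ige_pvals.append(p_ige)
        prm = cfit.params
        varcomp_rows.append(
            {
                "phenotype": pheno,
                "n": cfit.n_used,
                "sigma2_AD": prm.sigma2_AD,
                "sigma_ADS": prm.sigma_ADS,
                "sigma2_AS": prm.sigma2_AS,
                "sigma2_E": prm.sigma2_E,
                "rho_E": prm.rho_E,
                "sigma2_ED": prm.sigma2_ED,
                "sigma_EDS": prm.sigma_EDS,
                "sigma2_ES": prm.sigma2_ES,
                "sigma2_C": prm.sigma2_C,
                "prop_DGE": cfit.prop_DGE,
                "prop_IGE": cfit.prop_IGE,
                "rho": cfit.rho,
                "loglik": cfit.loglik,
                "p_ige_2df": p_ige,
                "p_rho_vs_0": analysis.p_rho_vs_0,
                "p_rho_vs_1": analysis.p_rho_vs_1,
            }
        )
        log.write("varcomp", phenotype=pheno, loglik=round(cfit.loglik, 4),
                  prop_IGE=round(cfit.prop_IGE, 4))

        for mode in config.modes:
            scans = permute_scan(
                yn, X, A, cages, genotypes, mode=mode, K=config.K,
                seed=config.seed, condition=config.condition,
                maf_min=config.maf_min, social_coding=config.social_coding,
                fit=cfit, focal_idx=focal_idx, phenotype=pheno,
            )
            scans.observed.to_tsv(out / "scans" / f"{pheno}_{mode}.tsv")
            for t in scans.permuted:
                t.to_tsv(out / "perms" / f"{pheno}_{mode}_perm{t.permutation_id}.tsv")
            loci = estimate_fdr(
                scans, clump_window_bp=config.clump_window_bp,
                fdr_threshold=config.fdr_threshold,
            )
            frame = loci_to_frame(loci)
            frame.insert(0, "phenotype", pheno)
            frame.insert(1, "mode", mode)
            frame.to_csv(
                out / f"loci_{pheno}_{mode}.tsv", sep="\t", index=False
            )
            log.write("fdr", phenotype=pheno, mode=mode,
                      loci=len(loci),
                      significant=int(frame["significant"].sum()) if len(frame) else 0)

    if varcomp_rows:
        vdf = pd.DataFrame(varcomp_rows)
        vdf["q_ige"] = qvalues(np.array(ige_pvals))
        vdf.to_csv(out / "varcomp.tsv", sep="\t", index=False)
    if norm_frames:
        pd.concat(norm_frames.values()).to_csv(
            out / "normalized_phenotypes.tsv", sep="\t", index=False
        )
    log.write("done", phenotypes=len(varcomp_rows))
    return out
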