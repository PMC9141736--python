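"""End-to-end orchestration: QC -> BLUP -> engines -> thresholds -> windows.

A RunConfig (loadable from a YAML file) names the inputs, the engines to
run and their hyperparameters; run_pipeline executes the stages, writes
per-stage TSV outputs and a JSON manifest (input checksums, seeds, stage
timings).  One root seed fans out to every stochastic stage through a
deterministic hash so reruns are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assoc_linear import bh_fdr_threshold, farmcpu_scan, fit_mlm_null, mlm_scan
from .assoc_ml import (CvScheme, RfModelSpec, SvrKernelSpec,
                       empirical_threshold, rf_importance_scan,
                       svr_importance_scan)
from .genotype_qc import (apply_snp_qc, compute_kinship, compute_snp_qc,
                          impute_markov, pca_covariates)
from .io_formats import (AssociationTable, GenotypePanel, read_gff3,
                         read_hapmap, read_phenotypes, read_vcf,
                         write_association_tsv, write_windows_bed)
from .phenotype_model import detect_outliers, estimate_heritability, fit_multi_env_blup
from .post_gwas import (DEFAULT_FLANK, annotate_candidate_genes,
                        call_significant, estimate_allele_effects,
                        export_manhattan_qq, extract_qtl_windows,
                        method_overlap_report)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]

ENGINES = ("mlm", "farmcpu", "rf", "svr")


@dataclass
class RunConfig:
    genotype: str = ""
    phenotype: str = ""
    gff3: str | None = None
    out_dir: str = "mlgwas_out"
    trait: str | None = None
    maf_min: float = 0.05
    het_max: float = 0.5
    engines: tuple[str, ...] = ENGINES
    n_pcs: int = 3
    fdr_q: float = 0.05
    alpha: float = 0.05
    threshold_reps: int = 1000
    threshold_cv: bool = False     # False: single-fit engine inside permutations
    rf_trees: int = 1000
    svr_degree: int = 2
    svr_constant: float = 1.0
    svr_cost: float = 1.0
    svr_epsilon: float = 0.1
    cv_folds: int = 5
    cv_repeats: int = 10
    flank: int = DEFAULT_FLANK
    seed: int = 0

    def __post_init__(self) -> None:
        bad = [e for e in self.engines if e not in ENGINES]
        if bad:
            raise ValueError(f"unknown method(s) {bad}; expected one of {list(ENGINES)}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "engines" in data:
            data["engines"] = tuple(data["engines"])
        return cls(**data)


def _stage_seed(root: int, stage: str) -> int:
    h = hashlib.sha256(f"{root}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _read_genotypes(path: str) -> GenotypePanel:
    if path.endswith((".hmp", ".hmp.txt", ".hapmap")):
        return read_hapmap(path)
    return read_vcf(path)


def run_pipeline(config: RunConfig) -> Path:
    """Run the full workflow; returns the output directory."""
    t_start = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "inputs": {}, "stages": {}, "outputs": [],
    }

    def stage_done(name: str, t0: float) -> None:
        manifest["stages"][name] = {"seconds": round(time.time() - t0, 3)}
        logger.info("stage %s done in %.1fs", name, time.time() - t0)

    for key in ("genotype", "phenotype", "gff3"):
        p = getattr(config, key)
        if p:
            if not Path(p).exists():
                raise FileNotFoundError(f"{key} file not found: {p}")
            manifest["inputs"][key] = {"path": str(p), "sha256": _sha256(p)}

    # --- QC -----------------------------------------------------------
    t0 = time.time()
    panel = _read_genotypes(config.genotype)
    qc = compute_snp_qc(panel, maf_min=config.maf_min, het_max=config.het_max)
    qc.to_tsv(out / "snp_qc.tsv")
    panel = impute_markov(apply_snp_qc(panel, qc))
    stage_done("qc", t0)

    # --- phenotypes / BLUP -------------------------------------------
    t0 = time.time()
    phenos = detect_outliers(read_phenotypes(config.phenotype))
    trait = config.trait or phenos.traits()[0]
    fit = fit_multi_env_blup(phenos, trait=trait)
    h2 = estimate_heritability(fit.components)
    blup_df = pd.DataFrame({
        "sample_id": fit.blups.index, "trait": trait,
        "blup": fit.blups.to_numpy(), "n_obs": fit.n_obs.to_numpy(),
    })
    blup_df.to_csv(out / "blups.tsv", sep="\t", index=False)
    pd.DataFrame([{**asdict(fit.components), "H2": h2, "trait": trait}]).to_csv(
        out / "variance_components.tsv", sep="\t", index=False)
    stage_done("blup", t0)

    # align panel samples with BLUPs
    common = [s for s in panel.sample_ids if s in set(fit.blups.index)]
    idx = [list(panel.sample_ids).index(s) for s in common]
    panel = panel.take_samples(np.array(idx))
    y = fit.blups.reindex(common).to_numpy()

    kinship = compute_kinship(panel)
    kinship.to_tsv(out / "kinship.tsv")
    covs = pca_covariates(panel, config.n_pcs) if config.n_pcs > 0 else None

    # --- association engines -----------------------------------------
    tables: dict[str, AssociationTable] = {}
    cv = CvScheme(n_folds=config.cv_folds, n_repeats=config.cv_repeats,
                  seed=_stage_seed(config.seed, "cv"))

    if "mlm" in config.engines:
        t0 = time.time()
        null = fit_mlm_null(y, covs, kinship)
        res = mlm_scan(null, panel, y)
        thr, sig = bh_fdr_threshold(res.df["p_value"].to_numpy(), q=config.fdr_q)
        tables["MLM"] = _assoc_table(res.df, "MLM", res.df["p_value"], thr, sig)
        stage_done("mlm", t0)

    if "farmcpu" in config.engines:
        t0 = time.time()
        state = farmcpu_scan(y, covs, panel)
        thr, sig = bh_fdr_threshold(state.p_values, q=config.fdr_q)
        base = pd.DataFrame({"snp_id": panel.snp_ids, "chrom": panel.chrom,
                             "pos": panel.pos})
        tables["FarmCPU"] = _assoc_table(base, "FarmCPU", state.p_values, thr, sig)
        if state.history:
            pd.DataFrame(state.history).to_csv(out / "farmcpu_iterations.tsv",
                                               sep="\t", index=False)
        stage_done("farmcpu", t0)

    thr_cv = cv if config.threshold_cv else None
    for eng, scan_fn, spec in (
        ("rf", rf_importance_scan,
         RfModelSpec(n_trees=config.rf_trees, seed=_stage_seed(config.seed, "rf"))),
        ("svr", svr_importance_scan,
         SvrKernelSpec(degree=config.svr_degree, constant=config.svr_constant,
                       cost=config.svr_cost, epsilon=config.svr_epsilon,
                       seed=_stage_seed(config.seed, "svr"))),
    ):
        if eng not in config.engines:
            continue
        t0 = time.time()
        profile = scan_fn(y, panel, spec, cv)
        null = empirical_threshold(
            y, panel, eng.upper(), spec=spec, cv=thr_cv,
            n_reps=config.threshold_reps, alpha=config.alpha,
            seed=_stage_seed(config.seed, f"{eng}-threshold"),
            reference=profile if not config.threshold_cv else None,
        )
        pd.Series(null.max_importances).to_csv(
            out / f"{eng}_null_maxima.tsv", sep="\t", index=False, header=["max_importance"])
        scaled = profile.df["scaled_importance"].to_numpy()
        tables[eng.upper()] = _assoc_table(
            profile.df, eng.upper(), scaled, null.threshold, scaled >= null.threshold)
        stage_done(eng, t0)

    for method, table in tables.items():
        write_association_tsv(table, out / f"assoc_{method.lower()}.tsv")
        manifest["outputs"].append(f"assoc_{method.lower()}.tsv")

    # --- post-GWAS ----------------------------------------------------
    t0 = time.time()
    chrom_lengths = {c: int(panel.pos[panel.chrom == c].max())
                     for c in pd.unique(panel.chrom)}
    all_windows = []
    for method, table in tables.items():
        peaks = call_significant(table, flank=config.flank)
        windows = extract_qtl_windows(peaks, flank=config.flank,
                                      chrom_lengths=chrom_lengths)
        if config.gff3:
            genes = read_gff3(config.gff3)
            windows = annotate_candidate_genes(windows, genes)
        else:
            logger.warning("no GFF3 supplied; windows not annotated with genes")
        effects = estimate_allele_effects(panel, fit.blups, peaks, trait=trait)
        if effects:
            pd.DataFrame([{
                "snp_id": e.snp_id, "trait": e.trait, "mean_ref": e.mean_ref,
                "mean_alt": e.mean_alt, "effect": e.effect,
                "n_ref": e.n_ref, "n_alt": e.n_alt,
            } for e in effects]).to_csv(out / f"allele_effects_{method.lower()}.tsv",
                                        sep="\t", index=False)
        all_windows.extend(windows)
        export_manhattan_qq(table, str(out / f"{method.lower()}"),
                            chrom_lengths=chrom_lengths)
    if all_windows:
        write_windows_bed(all_windows, out / "qtl_windows.bed",
                          chrom_lengths=chrom_lengths)
        rows = [{
            "method": w.method, "chrom": w.chrom, "start": w.start, "end": w.end,
            "peak_snp": w.peak_snp, "peak_statistic": w.peak_statistic,
            "genes": ",".join(g.gene_id for g in w.genes),
        } for w in all_windows]
        pd.DataFrame(rows).to_csv(out / "qtl_windows.tsv", sep="\t", index=False)
    if len(tables) >= 2:
        method_overlap_report(tables, flank=config.flank).to_csv(
            out / "method_overlap.tsv", sep="\t", index=False)
    stage_done("post_gwas", t0)

    manifest["wall_seconds"] = round(time.time() - t_start, 3)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out


def _assoc_table(base: pd.DataFrame, method: str, stat, threshold,
                 significant) -> AssociationTable:
    thr = np.nan_to_num(np.asarray(threshold, dtype=float),
                        nan=(0.0 if method in ("MLM", "FarmCPU") else 101.0))
    return AssociationTable(df=pd.DataFrame({
        "snp_id": base["snp_id"].to_numpy(),
        "chrom": base["chrom"].to_numpy(),
        "pos": base["pos"].to_numpy(),
        "method": method,
        "statistic": np.asarray(stat, dtype=float),
        "threshold": thr,
        "significant": np.asarray(significant, dtype=bool),
    }))
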