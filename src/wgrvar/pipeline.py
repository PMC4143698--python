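"""End-to-end orchestration: simulate -> prep -> classify -> fit -> resample.

A single YAML config (validated by a pydantic schema) drives every
stage; every random stage receives a sub-seed derived from one master
seed, so a rerun with the same config reproduces every output file.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from . import classify as vc
from . import io as wio
from .model import MCMCConfig, center_genotypes, default_prior
from .phenotype import build_covariate_matrix, prepare_cohort
from .simulate import SimSpec, simulate_dataset
from .subsets import report_tables, resample_fixed_size, run_per_set

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "SimBlock", "run_pipeline", "load_config"]


class SimBlock(BaseModel):
    n_subjects: int = 395
    n_genes: int = 31
    gene_length_bp: int = 20_000
    flank_bp: int = 50_000
    chrom_length_bp: int = 8_000_000
    n_variants: int = 49_839
    n_causal: Optional[int] = 500
    h2_markers: float = 0.3
    covariate_effects: Sequence[float] = (0.04, 0.6, 0.5, 0.4)
    resid_sd: float = 1.0
    n_visits: int = 4
    visit_missing_prob: float = 0.1

    def to_spec(self, seed: int) -> SimSpec:
        return SimSpec(seed=seed, **self.model_dump())


class MCMCBlock(BaseModel):
    n_iter: int = 40_000
    burn_in: int = 15_000
    thin: int = 1

    @field_validator("burn_in")
    @classmethod
    def _burn(cls, v, info):
        if v >= info.data.get("n_iter", np.inf):
            raise ValueError("burn_in must be < n_iter")
        return v


class ResampleBlock(BaseModel):
    size: int = 500
    reps: int = 500
    n_iter: int = 5_000
    burn_in: int = 1_000


class PipelineConfig(BaseModel):
    """Validated pipeline settings; unknown fields are rejected."""

    model_config = {"extra": "forbid"}

    outdir: Path
    master_seed: int = 0
    vcf: Optional[Path] = None
    genes: Optional[Path] = None
    phenotypes: Optional[Path] = None
    simulate: Optional[SimBlock] = None
    flank_bp: int = 50_000
    partition_r2: float = 0.5
    mcmc: MCMCBlock = Field(default_factory=MCMCBlock)
    resample: ResampleBlock = Field(default_factory=ResampleBlock)
    resample_sets: Sequence[str] = ()
    drop_monomorphic: bool = False

    def validate_inputs(self) -> None:
        if self.simulate is None:
            missing = [n for n in ("vcf", "genes", "phenotypes")
                       if getattr(self, n) is None]
            if missing:
                raise ValueError(
                    f"no simulate block and no input paths for: {missing}")


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return PipelineConfig(**raw)


def _stage(name, t0):
    logger.info("stage %-10s done in %.1fs", name, time.time() - t0)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage and populate the output directory.

    Writes: the echoed config, simulated inputs (when simulating), the
    analysis cohort, per-variant annotations, the counts cross-tab, the
    per-set R^2 table, resampling summaries and the three report grids.
    """
    config.validate_inputs()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(yaml.safe_load(config.model_dump_json()), fh)

    seed = config.master_seed
    # ---- inputs: simulate or load ------------------------------------
    t0 = time.time()
    if config.simulate is not None:
        sim = simulate_dataset(config.simulate.to_spec(seed))
        genes, variants, X = sim["genes"], sim["variants"], sim["X"]
        long_df = sim["phenotypes"]
        wio.write_bed(out / "genes.bed", genes)
        wio.write_vcf(out / "genotypes.vcf", variants, X)
        wio.write_phenotypes(out / "phenotypes.tsv", long_df)
        wio.write_json(out / "true_model.json", sim["model"].to_dict())
        samples = [f"S{i + 1:05d}" for i in range(X.shape[0])]
    else:
        variants, X, samples = wio.read_vcf(config.vcf)
        genes = wio.read_bed(config.genes)
        long_df = wio.read_phenotypes(config.phenotypes)
    _stage("inputs", t0)

    # ---- phenotype prep ----------------------------------------------
    t0 = time.time()
    cohort, transform = prepare_cohort(long_df)
    subj_order = {s: i for i, s in enumerate(samples)}
    keep_rows = [subj_order[s] for s in cohort["subject_id"]
                 if s in subj_order]
    if len(keep_rows) != len(cohort):
        raise ValueError("phenotype subjects not aligned with genotypes")
    Xa = X[keep_rows]
    y = cohort["y"].to_numpy()
    Z, _ = build_covariate_matrix(cohort)
    cohort.to_csv(out / "cohort.tsv", sep="\t", index=False)
    wio.write_json(out / "logsbp_transform.json", transform)
    _stage("prep", t0)

    # ---- classification ----------------------------------------------
    t0 = time.time()
    retained, n_excluded = vc.filter_variants(variants)
    mask = variants["qc_pass"].astype(bool) & (variants["n_alleles"] == 2)
    Xa = Xa[:, mask.to_numpy()]
    ann = vc.annotate_variants(retained, Xa, genes, config.flank_bp)
    if config.drop_monomorphic:
        poly = ann["maf"] > 0
        ann = ann.loc[poly].reset_index(drop=True)
        Xa = Xa[:, poly.to_numpy()]
    sets = vc.build_marker_sets(ann)
    counts, formatted = vc.cross_tab(ann)
    ann.to_csv(out / "annotations.tsv", sep="\t", index=False)
    formatted.to_csv(out / "crosstab.tsv", sep="\t")
    logger.info("attrition: %d in = %d retained + %d excluded",
                len(variants), len(retained), n_excluded)
    _stage("classify", t0)

    # ---- per-set fits -------------------------------------------------
    t0 = time.time()
    Xc, _ = center_genotypes(Xa)
    mcmc = MCMCConfig(n_iter=config.mcmc.n_iter, burn_in=config.mcmc.burn_in,
                      thin=config.mcmc.thin)
    per_set = run_per_set(y, Z, Xc, sets, mcmc=mcmc, seed=seed,
                          partition_r2=config.partition_r2)
    per_set.to_csv(out / "per_set_r2.tsv", sep="\t", index=False)
    _stage("fits", t0)

    # ---- resampling ---------------------------------------------------
    t0 = time.time()
    rcfg = config.resample
    rmcmc = MCMCConfig(n_iter=rcfg.n_iter, burn_in=rcfg.burn_in)
    which = list(config.resample_sets) or [
        n for n, s in sets.items() if s.size >= rcfg.size]
    resampled = {}
    rep_rows = []
    for name in which:
        if sets[name].size < rcfg.size:
            logger.warning("set %s smaller than %d; skipped", name, rcfg.size)
            continue
        res = resample_fixed_size(y, Z, Xc, sets[name], size=rcfg.size,
                                  reps=rcfg.reps, mcmc=rmcmc, seed=seed,
                                  partition_r2=config.partition_r2)
        resampled[name] = res
        for i, r2 in enumerate(res.r2_reps):
            rep_rows.append({"set_name": name, "replicate": i, "r2": r2})
    if rep_rows:
        pd.DataFrame(rep_rows).to_csv(out / "resample_replicates.tsv",
                                      sep="\t", index=False)
    _stage("resample", t0)

    # ---- reports ------------------------------------------------------
    tables = report_tables(counts=counts, per_set=per_set,
                           resampled=resampled or None)
    for key, df in tables.items():
        df.to_csv(out / f"table_{key}.tsv", sep="\t")
    return out
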