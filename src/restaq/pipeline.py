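"""End-to-end orchestration: synth -> qc -> metrics -> phenotype -> gwas -> prs.

One :class:`RunConfig` (optionally loaded from YAML) drives every stage;
all randomness flows from a single root seed through named per-stage
substreams, every artifact file is SHA-256 hashed into a run manifest,
and any stage failure aborts with the stage name while retaining partial
outputs next to a failure marker.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as rio
from .actigraphy import apply_exclusions
from .datatypes import GenotypeMatrix
from .gwas import logistic_scan, linear_scan, variant_qc
from .phenotype import assemble_table
from .prs import PRSConfig, PRSQuantileModel
from .rhythm import cohort_metrics
from .simulate import (
    ActigraphyParams,
    gen_actigraphy,
    gen_covariates,
    gen_genotypes,
    gen_phenotypes,
    make_truth,
)

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

logger = logging.getLogger(__name__)

STAGES = ("synth", "qc", "metrics", "phenotype", "gwas", "prs")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Parameters for a full synthetic-cohort analysis run."""

    out_dir: str = "restaq_run"
    seed: int = 0
    # cohort sizes
    n_participants: int = 200
    n_target: int = 200  # held-out PRS cohort
    n_variants: int = 500
    n_causal: int = 100
    h2: float = 0.3
    maf_range: tuple = (0.05, 0.5)
    outcome_corr: dict = field(
        default_factory=lambda: {"mood_instability": 0.3, "MDD": 0.2,
                                 "BD": 0.1, "GAD": 0.1, "neuroticism": 0.2}
    )
    # actigraphy
    n_days: int = 7
    epoch_s: int = 5
    noise_cv: float = 0.3
    missing_rate: float = 0.02
    # analysis settings
    bin_min: int = 5
    min_wear_h: float = 72.0
    info_min: float = 0.8
    maf_min: float = 0.01
    hwe_alpha: float = 1e-6
    prs_thresholds: tuple = (5e-8, 5e-5, 0.01, 0.05, 0.1, 0.5)
    n_quantiles: int = 4
    write_vcf: bool = False
    skip_stages: tuple = ()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        allowed = set(cls.__dataclass_fields__)
        unknown = set(data) - allowed
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("maf_range", "prs_thresholds", "skip_stages"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)

    def validate(self) -> None:
        if self.n_participants <= 0 or self.n_variants < 0:
            raise ValueError("cohort sizes must be positive")
        bad = set(self.skip_stages) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stages in skip_stages: {sorted(bad)}")
        ActigraphyParams(
            n_days=self.n_days, epoch_s=self.epoch_s,
            noise_cv=self.noise_cv, missing_rate=self.missing_rate,
        ).validate()


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _substream(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all (non-skipped) stages and return the manifest dict."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": _jsonable(asdict(config)), "seed": config.seed,
                      "stages": [], "files": {}}
    state: dict = {}
    try:
        for stage in STAGES:
            if stage in config.skip_stages:
                continue
            logger.info("running stage %s", stage)
            globals()[f"_stage_{stage}"](config, out, state)
            manifest["stages"].append(stage)
    except Exception as exc:  # noqa: BLE001 - annotate with stage and re-raise
        (out / "FAILED").write_text(f"{type(exc).__name__}: {exc}\n")
        if isinstance(exc, PipelineError):
            raise
        stage_name = stage if "stage" in dir() else "unknown"
        raise PipelineError(stage_name, str(exc)) from exc
    for f in sorted(out.glob("*")):
        if f.is_file() and f.name != "manifest.json":
            manifest["files"][f.name] = _sha256(f)
    rio.write_json(manifest, out / "manifest.json")
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


# ---------------------------------------------------------------------------
# stages


def _stage_synth(cfg: RunConfig, out: Path, state: dict) -> None:
    seed = _substream(cfg.seed, "synth")
    n_total = cfg.n_participants + cfg.n_target
    geno = gen_genotypes(
        n_total, cfg.n_variants, maf_range=cfg.maf_range, seed=seed
    )
    covar = gen_covariates(n_total, seed=seed + 1)
    truth = make_truth(
        cfg.n_variants, min(cfg.n_causal, cfg.n_variants), cfg.h2,
        seed=seed + 2, outcome_corr=cfg.outcome_corr,
    )
    pheno = gen_phenotypes(geno, truth, covar, seed=seed + 3)

    disc = np.arange(cfg.n_participants)
    targ = np.arange(cfg.n_participants, n_total)
    params = ActigraphyParams(
        n_days=cfg.n_days, epoch_s=cfg.epoch_s, noise_cv=cfg.noise_cv,
        missing_rate=cfg.missing_rate, seed=seed + 4,
    )
    series, _ = gen_actigraphy(
        params, cfg.n_participants, ra_true=pheno["mean_ra"].to_numpy()[disc]
    )
    for s, pid in zip(series, geno.sample_ids[disc]):
        s.participant_id = str(pid)

    rio.write_activity_csv(series, out / "activity.csv")
    rio.write_dosage_tsv(geno.take_samples(disc), out / "genotypes_discovery.tsv")
    rio.write_dosage_tsv(geno.take_samples(targ), out / "genotypes_target.tsv")
    if cfg.write_vcf:
        rio.write_vcf(geno.take_samples(disc), out / "genotypes_discovery.vcf")
    covar_out = covar.copy()
    covar_out.insert(0, "participant_id", geno.sample_ids)
    covar_out.to_csv(out / "covariates.tsv", sep="\t", index=False)
    pheno.to_csv(out / "phenotypes_true.tsv", sep="\t", index=False)
    rio.write_json(truth.to_json_dict(), out / "truth.json")

    state.update(
        series=series, geno=geno, covar=covar_out, pheno=pheno, truth=truth,
        disc=disc, targ=targ,
    )


def _stage_qc(cfg: RunConfig, out: Path, state: dict) -> None:
    series = state.get("series") or rio.read_activity_csv(out / "activity.csv")
    retained, report = apply_exclusions(series, min_wear_h=cfg.min_wear_h)
    report.to_frame().to_csv(out / "qc_report.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"participant_id": [s.participant_id for s in retained]}
    ).to_csv(out / "retained_ids.tsv", sep="\t", index=False)
    state["retained"] = retained
    state["qc_report"] = report


def _stage_metrics(cfg: RunConfig, out: Path, state: dict) -> None:
    retained = state["retained"]
    metrics = cohort_metrics(retained, bin_min=cfg.bin_min)
    metrics.to_csv(out / "metrics.tsv", sep="\t", index=False, float_format="%.6f")
    state["metrics"] = metrics


def _stage_phenotype(cfg: RunConfig, out: Path, state: dict) -> None:
    metrics, covar = state["metrics"], state["covar"]
    pheno = state["pheno"]
    outcome_cols = ["participant_id", "mood_instability", "MDD", "BD", "GAD",
                    "neuroticism"]
    outcomes = pheno[outcome_cols]
    table, sidecar = assemble_table(metrics, covar, outcomes)
    table.to_csv(out / "phenotype.tsv", sep="\t", index=False, float_format="%.6f")
    rio.write_json(sidecar, out / "phenotype_sidecar.json")
    state["table"] = table


def _covar_cols(covar: pd.DataFrame, with_townsend: bool) -> list[str]:
    cols = ["sex", "age", "array"] + [f"PC{i}" for i in range(1, 9)]
    if with_townsend:
        cols.append("townsend")
    return [c for c in cols if c in covar.columns]


def _stage_gwas(cfg: RunConfig, out: Path, state: dict) -> None:
    table = state["table"]
    geno: GenotypeMatrix = state["geno"].take_samples(state["disc"])
    # align genotype samples to the analysis table
    idx = {pid: i for i, pid in enumerate(geno.sample_ids)}
    rows = [idx[p] for p in table["participant_id"] if p in idx]
    sub = geno.take_samples(np.array(rows, dtype=int))
    tab = table[table["participant_id"].isin(idx)].reset_index(drop=True)

    qc_geno, qc_stats = variant_qc(
        sub, info_min=cfg.info_min, maf_min=cfg.maf_min, hwe_alpha=cfg.hwe_alpha
    )
    qc_stats.to_csv(out / "variant_qc.tsv", sep="\t", index=False)

    covars = tab[_covar_cols(tab, with_townsend=False)]
    y = tab["low_RA"].to_numpy(float)
    if np.nansum(y == 1.0) == 0 or np.nansum(y == 0.0) == 0:
        raise PipelineError("gwas", "low-RA phenotype has a single class")
    res = logistic_scan(qc_geno, y, covars)
    res.sumstats().to_csv(out / "sumstats_low_ra.tsv", sep="\t", index=False)
    res_lin = linear_scan(qc_geno, tab["mean_RA"].to_numpy(float), covars)
    res_lin.sumstats().to_csv(out / "sumstats_ra.tsv", sep="\t", index=False)
    h2, h2_se = res.h2_estimate()
    rio.write_json(
        {
            "low_ra": {"lambda_gc": res.lambda_gc, "h2": h2, "h2_se": h2_se,
                       "n_genome_wide": res.n_genome_wide},
            "continuous_ra": {"lambda_gc": res_lin.lambda_gc},
        },
        out / "scan_diagnostics.json",
    )
    state["sumstats"] = res.sumstats()


def _stage_prs(cfg: RunConfig, out: Path, state: dict) -> None:
    geno_t = state["geno"].take_samples(state["targ"])
    pheno, covar = state["pheno"], state["covar"]
    targ = state["targ"]
    outcomes = pheno.iloc[targ][
        ["mood_instability", "MDD", "BD", "GAD", "neuroticism"]
    ].reset_index(drop=True)
    covs = covar.iloc[targ][_covar_cols(covar, with_townsend=True)].reset_index(
        drop=True
    )
    model = PRSQuantileModel(
        state["sumstats"], geno_t, outcomes, covs,
        PRSConfig(thresholds=cfg.prs_thresholds, n_quantiles=cfg.n_quantiles),
    )
    res = model.fit()
    res.table.to_csv(out / "prs_associations.tsv", sep="\t", index=False)
    res.score_reports.to_csv(out / "prs_score_report.tsv", sep="\t", index=False)
    state["prs"] = res
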