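"""End-to-end pipeline stages over one synthetic study.

Each ``cmd_*`` function is one stage of the protocol, in study order:
simulate -> preprocess/fit -> permutation significance -> bootstrap
loadings -> phenome scans -> cross-cohort projection -> age
stratification.  Stages read and write plain-text artifacts inside a
working directory, never mutate their inputs, update a JSON run manifest
(config snapshot, per-stage seeds, table shapes, wall time, output
checksums), and derive their random seeds deterministically from the one
pipeline seed, so a completed run can be reproduced bit-identically from
its manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort_io import (atomic_write_text, read_cohort, read_config, sha256,
                        write_cohort, write_config, write_ground_truth, write_tsv)
from .inference import bootstrap_loadings, permutation_test
from .phenome import run_association_scan, summarize_hits
from .pls import PLSModel, fit_pls, group_ttest, latent_correlation
from .preprocess import (DEFAULT_NUISANCE, apply_exclusions, encode_chronotype,
                         prepare_cohort, preprocessing_report, residualize,
                         zscore)
from .synthetic import (GeneratorConfig, default_external_config,
                        generate_cohort, generate_external_cohort)
from .transfer import (ADULT_BRACKETS_YEARS, CHILD_BRACKETS_MONTHS,
                       age_bracket_summary, build_projection, project_cohort)

log = logging.getLogger("chronomodes")

STAGES = ("simulate", "fit", "permute", "bootstrap", "phewas", "project", "stratify")


@dataclass
class PipelineConfig:
    """Paths, sizes and thresholds for one pipeline run."""

    work_dir: str = "results/run"
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    external_n: int = 1500
    k: int = 5
    B_perm: int = 1000
    B_boot: int = 1000
    alpha_perm: float = 0.001
    alpha_assoc: float = 0.05
    min_n_assoc: int = 50
    null_scheme: str = "projection"
    subset: str = "GMV"
    seed: int = 0
    verbosity: int = 1

    def validate(self) -> None:
        for name in ("external_n", "k", "B_perm", "B_boot"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("alpha_perm", "alpha_assoc"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        self.generator.validate()

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed split from the pipeline seed."""
        idx = STAGES.index(stage)
        ss = np.random.SeedSequence([self.seed, idx])
        return int(ss.generate_state(1)[0] % (2**31))

    def path(self, name: str) -> Path:
        return Path(self.work_dir) / name

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["generator"] = self.generator.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "generator" in d and isinstance(d["generator"], dict):
            d["generator"] = GeneratorConfig.from_dict(d["generator"])
        return cls(**d)


def _update_manifest(cfg: PipelineConfig, stage: str, seconds: float,
                     artifacts: dict[str, Path], counts: dict[str, int]) -> None:
    path = cfg.path("manifest.json")
    manifest = json.loads(path.read_text()) if path.exists() else {
        "version": __version__, "config": cfg.to_dict(), "stages": {}}
    manifest["stages"][stage] = {
        "seed": cfg.stage_seed(stage),
        "wall_seconds": round(seconds, 3),
        "counts": counts,
        "artifacts": {k: {"path": str(v), "sha256": sha256(v)}
                      for k, v in artifacts.items()},
    }
    atomic_write_text(path, json.dumps(manifest, indent=1))


def _stage(stage):
    def wrap(fn):
        def run(cfg: PipelineConfig, *args, **kwargs):
            cfg.validate()
            t0 = time.perf_counter()
            artifacts, counts = fn(cfg, *args, **kwargs)
            dt = time.perf_counter() - t0
            log.info("stage=%s seed=%d wall=%.2fs %s", stage,
                     cfg.stage_seed(stage), dt,
                     " ".join(f"{k}={v}" for k, v in counts.items()))
            _update_manifest(cfg, stage, dt, artifacts, counts)
            return artifacts
        run.__name__ = f"cmd_{stage}"
        return run
    return wrap


@_stage("simulate")
def cmd_simulate(cfg: PipelineConfig):
    """Generate the source and external cohorts plus ground truth."""
    gen = cfg.generator.replace(seed=cfg.stage_seed("simulate"))
    bundle, truth = generate_cohort(gen)
    ext_cfg = default_external_config(gen, n_participants=cfg.external_n)
    ext_bundle, ext_truth = generate_external_cohort(ext_cfg, truth)

    out = Path(cfg.work_dir)
    artifacts = {}
    artifacts.update(write_cohort(bundle, out / "cohort"))
    for key, p in write_cohort(ext_bundle, out / "external").items():
        artifacts[f"external_{key}"] = p
    artifacts["ground_truth"] = write_ground_truth(truth, out / "ground_truth.json")
    artifacts["external_ground_truth"] = write_ground_truth(
        ext_truth, out / "external_ground_truth.json")
    artifacts["generator_config"] = write_config(gen, out / "generator_config.yaml")
    counts = {"n_source": bundle.n, "n_external": ext_bundle.n,
              "p_features": bundle.brain.shape[1]}
    return artifacts, counts


def prepare_training_data(cohort_dir: str | Path
                          ) -> tuple[pd.DataFrame, np.ndarray, pd.Series, pd.DataFrame]:
    """Shared preprocessing: encode, exclude, residualize, z-score.

    Returns (X ready for PLS, y in {-1,+1}, block tags, kept participant
    rows).  Deterministic, so downstream stages can re-derive the
    training data instead of shipping a second copy of the matrix.
    """
    return prepare_cohort(read_cohort(cohort_dir))


@_stage("fit")
def cmd_fit(cfg: PipelineConfig):
    """Preprocess the source cohort and fit the PLS model."""
    X, y, blocks, kept = prepare_training_data(cfg.path("cohort"))
    model = fit_pls(X, y, cfg.k, blocks=list(blocks))
    rho = latent_correlation(model, y)
    tests = [group_ttest(model.T[:, j], y) for j in range(cfg.k)]

    out = Path(cfg.work_dir)
    model.to_json(out / "model.json")
    scores = pd.DataFrame(model.T, index=X.index,
                          columns=[f"component_{j + 1}" for j in range(cfg.k)])
    scores.insert(0, "chronotype", y)
    summary = pd.DataFrame({
        "component": np.arange(1, cfg.k + 1),
        "latent_rho": rho,
        "t_morning_vs_evening": [t.t for t in tests],
        "df": [t.df for t in tests],
        "p_ttest": [t.p for t in tests],
    })
    artifacts = {
        "model": out / "model.json",
        "scores": write_tsv(scores.reset_index(), out / "scores.tsv"),
        "fit_summary": write_tsv(summary, out / "fit_summary.tsv"),
        "preprocess_report": atomic_write_text(
            out / "preprocess_report.txt", _report_text(cfg)),
    }
    return artifacts, {"n_fit": len(y), "p_features": X.shape[1], "k": cfg.k}


def _report_text(cfg: PipelineConfig) -> str:
    bundle = read_cohort(cfg.path("cohort"))
    table = bundle.participants
    target = encode_chronotype(table.set_index("participant_id")["chronotype_raw"])
    kept = apply_exclusions(table).intersection(target.kept_ids)
    return preprocessing_report(len(table), len(target.kept_ids), len(kept))


@_stage("permute")
def cmd_permute(cfg: PipelineConfig):
    """Component-wise permutation significance of the latent correlations."""
    X, y, _, _ = prepare_training_data(cfg.path("cohort"))
    result = permutation_test(X.to_numpy(), y, cfg.k, B=cfg.B_perm,
                              seed=cfg.stage_seed("permute"),
                              null_scheme=cfg.null_scheme)
    out = Path(cfg.work_dir)
    table = pd.DataFrame({
        "component": np.arange(1, cfg.k + 1),
        "observed_rho": result.observed_rho,
        "p_value": result.p_values,
        "significant": result.significant(cfg.alpha_perm),
        "B": cfg.B_perm,
        "null_scheme": cfg.null_scheme,
    })
    null_df = pd.DataFrame(result.null_rho,
                           columns=[f"component_{j + 1}" for j in range(cfg.k)])
    artifacts = {
        "perm_pvalues": write_tsv(table, out / "perm_pvalues.tsv"),
        "perm_null": write_tsv(null_df, out / "perm_null.tsv"),
    }
    return artifacts, {"B": cfg.B_perm,
                       "n_significant": int(result.significant(cfg.alpha_perm).sum())}


@_stage("bootstrap")
def cmd_bootstrap(cfg: PipelineConfig):
    """Bootstrap percentile intervals on the x-loadings."""
    X, y, blocks, _ = prepare_training_data(cfg.path("cohort"))
    result = bootstrap_loadings(X.to_numpy(), y, cfg.k, B=cfg.B_boot,
                                seed=cfg.stage_seed("bootstrap"))
    out = Path(cfg.work_dir)
    rows = []
    for j in range(cfg.k):
        for i, name in enumerate(X.columns):
            rows.append({
                "feature": name, "block": blocks.iloc[i], "component": j + 1,
                "loading": result.reference.P[i, j],
                "ci_low": result.ci_low[i, j], "ci_high": result.ci_high[i, j],
                "significant": bool(result.significant[i, j]),
            })
    artifacts = {"boot_ci": write_tsv(pd.DataFrame(rows), out / "boot_ci.tsv")}
    return artifacts, {"B": cfg.B_boot, "n_redraws": result.n_redraws,
                       "n_significant": int(result.significant.sum())}


@_stage("phewas")
def cmd_phewas(cfg: PipelineConfig):
    """Per-family association scans of the brain scores against the phenome."""
    bundle = read_cohort(cfg.path("cohort"))
    scores_df, _ = _read_scores(cfg)
    ids = scores_df.index
    out = Path(cfg.work_dir)
    artifacts = {}
    combined = []
    for family, table in bundle.phenome.items():
        scan = run_association_scan(
            scores_df.to_numpy(), table.loc[ids], family,
            alpha=cfg.alpha_assoc, min_n=cfg.min_n_assoc,
            meta=bundle.phenome_meta.get(family))
        combined.append(scan)
        artifacts[f"assoc_{family}"] = write_tsv(scan, out / f"assoc_{family}.tsv")
    if combined:
        allscan = pd.concat(combined, ignore_index=True)
        artifacts["assoc_all"] = write_tsv(allscan, out / "assoc_all.tsv")
        artifacts["assoc_hits"] = write_tsv(summarize_hits(allscan),
                                            out / "assoc_hits.tsv")
        n_hits = int(allscan["significant"].sum())
    else:
        n_hits = 0
    return artifacts, {"n_families": len(bundle.phenome), "n_hits": n_hits}


def _read_scores(cfg: PipelineConfig) -> tuple[pd.DataFrame, np.ndarray]:
    from .cohort_io import read_tsv
    df, _ = read_tsv(cfg.path("scores.tsv"), index_col="participant_id")
    y = df.pop("chronotype").to_numpy()
    return df, y


@_stage("project")
def cmd_project(cfg: PipelineConfig):
    """Project the external cohort through the subset rotation."""
    model = PLSModel.from_json(cfg.path("model.json"))
    proj = build_projection(model, cfg.subset)
    bundle = read_cohort(cfg.path("external"))
    table = bundle.participants.set_index("participant_id")
    nuisance = [c for c in DEFAULT_NUISANCE if c in table.columns]
    res = residualize(bundle.brain[proj.feature_subset], table[nuisance])
    scores = project_cohort(proj, res.matrix)
    out = Path(cfg.work_dir)
    proj.to_json(out / "projection.json")
    ext = pd.DataFrame(scores, index=res.matrix.index,
                       columns=[f"component_{j + 1}" for j in range(cfg.k)])
    artifacts = {
        "projection": out / "projection.json",
        "external_scores": write_tsv(ext.reset_index(), out / "external_scores.tsv"),
    }
    return artifacts, {"n_external": len(ext), "p_subset": len(proj.feature_subset),
                       "condition_number": int(proj.condition_number)}


@_stage("stratify")
def cmd_stratify(cfg: PipelineConfig):
    """Mean/SD of subtype expressions inside each age bracket, both cohorts."""
    from .cohort_io import read_tsv
    scores_df, _ = _read_scores(cfg)
    src = read_cohort(cfg.path("cohort")).participants.set_index("participant_id")
    ages = src.loc[scores_df.index, "age"].to_numpy()
    summary_src = age_bracket_summary(scores_df.to_numpy(), ages,
                                      ADULT_BRACKETS_YEARS, unit="years")
    summary_src.insert(0, "cohort", "source")

    ext_scores, _ = read_tsv(cfg.path("external_scores.tsv"),
                             index_col="participant_id")
    ext = read_cohort(cfg.path("external")).participants.set_index("participant_id")
    ext_ages = ext.loc[ext_scores.index, "age"].to_numpy()
    summary_ext = age_bracket_summary(ext_scores.to_numpy(), ext_ages,
                                      CHILD_BRACKETS_MONTHS, unit="months")
    summary_ext.insert(0, "cohort", "external")

    summary = pd.concat([summary_src, summary_ext], ignore_index=True)
    out = Path(cfg.work_dir)
    artifacts = {"age_summary": write_tsv(summary, out / "age_summary.tsv")}
    return artifacts, {"n_brackets": summary["bracket"].nunique()}


def cmd_run_all(cfg: PipelineConfig) -> dict[str, Path]:
    """Run every stage in protocol order; returns all artifact paths."""
    artifacts: dict[str, Path] = {}
    artifacts.update(cmd_simulate(cfg))
    artifacts.update(cmd_fit(cfg))
    artifacts.update(cmd_permute(cfg))
    artifacts.update(cmd_bootstrap(cfg))
    artifacts.update(cmd_phewas(cfg))
    artifacts.update(cmd_project(cfg))
    artifacts.update(cmd_stratify(cfg))
    return artifacts
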