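"""End-to-end orchestration: simulate/load -> audit -> select -> prune
-> impute -> fit -> predict, with plain-text artifacts and a manifest.

Every stage's output is a delimited or structured text file in the run
directory, so runs can be diffed; the manifest records a checksum per
artifact, the seeds used, and a hash of the configuration.  Reruns with
the same configuration are bit-identical for all deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bases import BasisSpec
from .harmonize import PooledDataset, audit_pooled, complete_covariate_filter
from .lmm import Covariate, ModelSpec, fit, predict_mean
from .mi import MIConfig, mi_analysis
from .selection import SelectionConfig, prune_unsupported_interactions, two_stage_select
from .synthetic import (
    MissingnessSpec,
    apply_covariate_missingness,
    default_truth,
    generate_multi_cohort,
    table1_profiles,
)
from .variance import Level1VarianceSpec

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("lifetraj.pipeline")


@dataclass
class PipelineConfig:
    """Declarative description of one analysis run.

    Exactly one of ``synthetic`` (a generation block) or ``inputs``
    (paths to measurement/child tables) must be set.  If ``selection``
    is present the trajectory and level-1 structure are selected by the
    two-stage procedure; otherwise ``model`` must describe them
    explicitly.
    """

    seed: int = 0
    synthetic: dict | None = None
    inputs: dict | None = None
    covariates: list = field(default_factory=lambda: ["sex"])
    selection: dict | None = None
    model: dict | None = None
    prune: dict | None = None
    mi: dict | None = None
    predictions: dict | None = None

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.inputs is None):
            raise ValueError("exactly one of synthetic/inputs must be given")
        if self.selection is None and self.model is None:
            raise ValueError("either selection or an explicit model is required")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _default_missingness() -> MissingnessSpec:
    # Missingness in maternal education rising with the child's observed
    # weight trajectory: the outcome-dependent (MAR) pattern MI targets.
    return MissingnessSpec(
        rates={"maternal_education": (-1.6, 0.8), "paternal_occupation": (-2.2, 0.3)}
    )


def _obtain_data(config: PipelineConfig, rundir: Path) -> PooledDataset:
    if config.inputs is not None:
        return PooledDataset.read(
            config.inputs["measurements"], config.inputs["children"]
        )
    blk = dict(config.synthetic)
    scale = float(blk.get("scale", 0.01))
    truth = default_truth()
    profiles = table1_profiles(scale)
    data = generate_multi_cohort(profiles, truth, seed=config.seed)
    if blk.get("missingness", "default") == "default":
        proxy = data.measurements.groupby("child_id")["weight_kg"].mean()
        data = PooledDataset(
            measurements=data.measurements,
            children=apply_covariate_missingness(
                data.children, _default_missingness(), proxy, seed=config.seed + 1
            ),
        )
    truth.write(rundir / "truth.yaml")
    data.write(rundir / "measurements.csv", rundir / "children.csv")
    return data


def _model_from_config(config: PipelineConfig, data: PooledDataset) -> ModelSpec:
    blk = config.model
    basis = BasisSpec.from_dict(blk["basis"])
    lv = blk.get("level1", {"kind": "segmented", "cuts": [2.0]})
    return ModelSpec(
        trajectory=basis,
        cohort_effects=blk.get("cohort_effects", "interactions"),
        level1=Level1VarianceSpec(kind=lv["kind"], cuts=tuple(lv.get("cuts", ()))),
    )


def run_pipeline(config: PipelineConfig, outdir) -> Path:
    """Execute all configured stages; returns the run directory."""
    rundir = Path(outdir)
    rundir.mkdir(parents=True, exist_ok=True)
    log.info("run directory: %s", rundir)

    data = _obtain_data(config, rundir)
    if (
        "parental_composite" in config.covariates
        and "parental_composite" not in data.children.columns
    ):
        from .harmonize import derive_parental_composite

        kids = data.children.copy()
        kids["parental_composite"] = derive_parental_composite(
            kids["maternal_education"], kids["paternal_occupation"]
        )
        data = PooledDataset(measurements=data.measurements, children=kids)
    audit = audit_pooled(data)
    audit.to_frame().to_csv(rundir / "pooling_audit.csv", index=False)
    log.info(
        "pooled %d children, %d measurements",
        audit.total_children,
        audit.total_measurements,
    )

    if config.selection is not None:
        sel_cfg = SelectionConfig(seed=config.seed, **config.selection)
        report = two_stage_select(data, sel_cfg)
        report.candidates.to_csv(rundir / "selection_candidates.csv", index=False)
        report.validation_mspe.to_csv(rundir / "selection_mspe.csv", index=False)
        report.stage2_table.to_csv(rundir / "selection_stage2.csv", index=False)
        with open(rundir / "selection_summary.yaml", "w") as fh:
            yaml.safe_dump(
                {
                    "winner": report.winner_label,
                    "trajectory": report.winner.to_dict(),
                    "level1": {
                        "kind": report.final_spec.level1.kind,
                        "cuts": list(report.final_spec.level1.cuts),
                    },
                },
                fh,
            )
        base_spec = report.final_spec
        log.info("selected trajectory: %s", report.winner_label)
    else:
        base_spec = _model_from_config(config, data)

    spec = ModelSpec(
        trajectory=base_spec.trajectory,
        covariates=tuple(Covariate(c) for c in config.covariates),
        cohort_effects=base_spec.cohort_effects,
        level1=base_spec.level1,
    )
    if config.prune is not None:
        spec, prune_log = prune_unsupported_interactions(
            spec,
            data,
            min_children=int(config.prune.get("min_children", 30)),
            min_measurements=int(config.prune.get("min_measurements", 100)),
        )
        prune_log.to_csv(rundir / "pruning_log.csv", index=False)
        log.info("pruned %d interactions", int(prune_log["dropped"].sum()))

    has_missing = (
        data.children[[c for c in config.covariates]].isna().any().any()
        if config.covariates
        else False
    )
    if has_missing and config.mi is not None:
        mi_cfg = MIConfig(seed=config.seed, **config.mi)
        pooled, fits = mi_analysis(data, spec, mi_cfg)
        pooled.ci95().to_csv(rundir / "estimates.csv")
        final_fit = pooled.as_fit(fits[0])
        meta = {
            "method": "MI+" + mi_cfg.fit_method,
            "m": mi_cfg.m,
            "n_cycles": mi_cfg.n_cycles,
            "loglik_per_imputation": [float(f.loglik) for f in fits],
        }
    else:
        if has_missing:
            data, discard = complete_covariate_filter(data, config.covariates)
            with open(rundir / "discard_report.yaml", "w") as fh:
                yaml.safe_dump(
                    {
                        "discarded_per_cohort": discard.discarded_per_cohort,
                        "total_discarded": discard.total_discarded,
                        "discarded_fraction_pct": discard.discarded_fraction_pct,
                    },
                    fh,
                )
        final_fit = fit(spec, data, method="REML")
        final_fit.summary().to_csv(rundir / "estimates.csv")
        meta = {
            "method": final_fit.method,
            "loglik": final_fit.loglik,
            "converged": bool(final_fit.converged),
            "n_obs": final_fit.n_obs,
            "n_children": final_fit.n_children,
        }
    with open(rundir / "fit_meta.yaml", "w") as fh:
        yaml.safe_dump(meta, fh)

    if config.predictions is not None:
        ages = np.asarray(config.predictions["ages"], dtype=float)
        frames = []
        for pattern in config.predictions["patterns"]:
            try:
                df = predict_mean(final_fit, pattern, ages)
            except ValueError as err:
                log.warning("prediction skipped for %s: %s", pattern, err)
                continue
            df.insert(0, "pattern", json.dumps(pattern, sort_keys=True))
            frames.append(df)
        if frames:
            pd.concat(frames, ignore_index=True).to_csv(
                rundir / "predictions.csv", index=False
            )

    manifest = {
        "lifetraj_version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "config_sha256": hashlib.sha256(
            json.dumps(asdict(config), sort_keys=True, default=str).encode()
        ).hexdigest(),
        "artifacts": {},
    }
    for f in sorted(rundir.iterdir()):
        if f.name == "manifest.json" or not f.is_file():
            continue
        manifest["artifacts"][f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
    with open(rundir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return rundir
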