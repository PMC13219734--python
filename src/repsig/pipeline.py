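"""End-to-end orchestration: simulate -> diversity -> public -> classify.

One :class:`PipelineConfig` (YAML-loadable) drives every stage; all
randomness flows from its single seed, so a rerun with the same config
reproduces every deterministic output byte-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .classify import (
    Hyperparameters,
    default_grid,
    evaluate_holdout,
    loocv_grid_search,
    split_cohort,
)
from .diversity import hill_diversity, homeostasis_occupancy, simpson_clonality
from .io import read_cohort, write_airr_tsv
from .public import build_public_table, fit_power_law, sharing_spectrum
from .repertoire import CohortSample, KeyMode
from .synth import CohortSpec, generate_cohort

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("repsig")


@dataclass
class PipelineConfig:
    """Configuration for one full analysis run."""

    outdir: str = "repsig-run"
    seed: int = 1234
    key_mode: str = KeyMode.CDR3_V_J.value
    min_individuals: int = 2
    # cohort source: either a metadata TSV (+dialect) or a simulation spec
    cohort_metadata: Optional[str] = None
    dialect: str = "airr"
    simulate: Optional[Dict] = None  # CohortSpec overrides
    # classification
    positive_labels: Sequence[str] = ("previvor", "survivor")
    validation_fraction: float = 0.2
    grid: Optional[List[Dict]] = None  # list of Hyperparameters overrides
    run_grid_search: bool = False
    hyperparameters: Dict = field(
        default_factory=lambda: {
            "key_mode": "CDR3aa",
            "presence_ratio": 0.10,
            "fisher_p": 1e-4,
            "wilcoxon_p": 1e-4,
        }
    )
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.key_mode = KeyMode.coerce(self.key_mode).value
        Hyperparameters(**self.hyperparameters)  # validate eagerly

    @classmethod
    def from_yaml(cls, path: Path | str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            log.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


@_stage("simulate")
def _run_simulate(config: PipelineConfig, outdir: Path) -> List[CohortSample]:
    overrides = dict(config.simulate or {})
    overrides.setdefault("seed", config.seed)
    spec = CohortSpec(**overrides)
    cohort, manifest = generate_cohort(spec)
    data_dir = outdir / "cohort"
    data_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in cohort:
        write_airr_tsv(s.repertoire, data_dir / f"{s.sample_id}.tsv")
        rows.append({"sample_id": s.sample_id, "group": s.group})
    pd.DataFrame(rows).to_csv(data_dir / "metadata.tsv", sep="\t", index=False)
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(
            {
                "spec": dataclasses.asdict(spec),
                "signature_keys": manifest["signature_keys"],
                "planted_carriage": manifest["planted_carriage"],
            },
            fh,
            indent=1,
        )
    return cohort


@_stage("diversity")
def _run_diversity(cohort: Sequence[CohortSample], outdir: Path) -> pd.DataFrame:
    rows = []
    for s in cohort:
        r = s.repertoire
        bins = homeostasis_occupancy(r)
        rows.append(
            {
                "sample_id": s.sample_id,
                "group": s.group,
                "D0": hill_diversity(r, 0),
                "D1": hill_diversity(r, 1),
                "D2": hill_diversity(r, 2),
                "SCI": simpson_clonality(r),
                **{f"occ_{k.lower()}": v for k, v in bins.items()},
            }
        )
    table = pd.DataFrame(rows)
    table.to_csv(outdir / "diversity.tsv", sep="\t", index=False, float_format="%.6g")
    return table


@_stage("public")
def _run_public(cohort: Sequence[CohortSample], config: PipelineConfig, outdir: Path) -> Dict:
    table = build_public_table(cohort, config.key_mode, config.min_individuals)
    spectrum = sharing_spectrum(table)
    spectrum.to_csv(outdir / "sharing_spectrum.tsv", sep="\t", index=False, float_format="%.8g")
    fit = fit_power_law(spectrum)
    record = {
        "alpha": fit.alpha,
        "k": fit.k,
        "n_points": fit.n_points,
        "rss": fit.rss,
        "n_public_keys": len(table.keys),
    }
    with open(outdir / "powerlaw.json", "w") as fh:
        json.dump(record, fh, indent=1)
    return record


@_stage("classify")
def _run_classify(cohort: Sequence[CohortSample], config: PipelineConfig, outdir: Path) -> Dict:
    positive = [l for l in config.positive_labels if any(s.group == l for s in cohort)]
    training, validation = split_cohort(
        cohort, config.validation_fraction, seed=config.seed
    )
    if config.run_grid_search:
        grid = (
            [Hyperparameters(**g) for g in config.grid]
            if config.grid
            else default_grid()
        )
        hp, grid_table = loocv_grid_search(training, grid, positive)
        grid_table.to_csv(outdir / "grid_search.tsv", sep="\t", index=False)
    else:
        hp = Hyperparameters(**config.hyperparameters)
    result, model = evaluate_holdout(training, validation, hp, positive)
    train_result, _ = evaluate_holdout(training, training, hp, positive)
    result.roc_points.to_csv(outdir / "roc.tsv", sep="\t", index=False)
    result.scores.to_csv(outdir / "validation_scores.tsv", sep="\t", index=False)
    record = {
        "hyperparameters": {
            "key_mode": hp.key_mode.value,
            "presence_ratio": hp.presence_ratio,
            "fisher_p": hp.fisher_p,
            "wilcoxon_p": hp.wilcoxon_p,
        },
        "signature_size": len(model.signature_keys),
        "signature_keys": sorted(model.signature_keys),
        "gaussians": dataclasses.asdict(model.gaussians),
        "training_auroc": train_result.auroc,
        "validation_auroc": result.auroc,
        "n_training": len(training),
        "n_validation": len(validation),
    }
    with open(outdir / "model.json", "w") as fh:
        json.dump(record, fh, indent=1)
    return record


def run_pipeline(config: PipelineConfig) -> Dict:
    """Execute all stages and return (and write) the run manifest."""
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.cohort_metadata:
        cohort = read_cohort(config.cohort_metadata, dialect=config.dialect)
    else:
        cohort = _run_simulate(config, outdir)

    _run_diversity(cohort, outdir)
    public_record = _run_public(cohort, config, outdir)
    classify_record = _run_classify(cohort, config, outdir)

    manifest = {
        "repsig_version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "n_samples": len(cohort),
        "outputs": sorted(
            {str(p.relative_to(outdir)) for p in outdir.rglob("*") if p.is_file()}
            | {"manifest.json"}
        ),
        "powerlaw": public_record,
        "classifier": {
            k: v for k, v in classify_record.items() if k != "signature_keys"
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
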