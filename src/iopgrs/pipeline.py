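"""End-to-end orchestration: simulate -> score -> associate -> cutoff.

A :class:`RunConfig` names either a generator parameterisation (synthetic
cohort) or paths to real genotype/phenotype tables, plus the stages to run.
Stage labels follow the analyses they mirror:

* ``table2`` — maximum IOP on age, sex and the nine variant dosages;
* ``table3`` / ``table4`` — maximum IOP / mean VCDR on age, sex and the GRS;
* ``fig1``  — ANOVA of the GRS across groups with Bonferroni post hoc tests;
* ``table5`` — logistic NTG-vs-control and HTG-vs-control models;
* ``fig2``  — the GRS cutoff scan with the relative-ratio statistic.

``score`` computes the unweighted GRS and is a dependency of everything
after ``table2``.  Reports are serialized at full precision; identical
config + seed produces byte-identical JSON.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Dict, List, Literal, Optional, Union

import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import __version__
from .association import (
    anova_bonferroni,
    iop_on_grs,
    iop_on_variants,
    logistic_group_on_grs,
    vcdr_on_grs,
)
from .cutoff import cutoff_scan
from .errors import ConfigError, StageOrderError
from .io import read_genotypes_csv, read_phenotypes_csv
from .panel import VariantPanel
from .scoring import unweighted_grs
from .synthetic import GeneratorParams, sample_cohort

log = logging.getLogger(__name__)

ALL_STAGES = ("score", "table2", "table3", "table4", "fig1", "table5", "fig2")
#: stages that cannot run without the GRS
SCORE_DEPENDENT = ("table3", "table4", "fig1", "table5", "fig2")


class RunConfig(BaseModel):
    """Validated pipeline configuration.

    Exactly one of ``generator`` (synthetic cohort) or the pair
    ``genotypes_csv``/``phenotypes_csv`` (real tables) must be supplied.
    """

    generator: Optional[GeneratorParams] = None
    genotypes_csv: Optional[str] = None
    phenotypes_csv: Optional[str] = None
    panel_json: Optional[str] = None  # panel for table input; default packaged
    stages: List[
        Literal["score", "table2", "table3", "table4", "fig1", "table5", "fig2"]
    ] = Field(default_factory=lambda: list(ALL_STAGES))
    cutoff_threshold: int = 12
    missing_policy: Literal["exclude", "mean_impute"] = "exclude"
    seed: int = 0
    out_dir: Optional[str] = None

    @model_validator(mode="after")
    def _exactly_one_source(self) -> "RunConfig":
        have_tables = self.genotypes_csv is not None and self.phenotypes_csv is not None
        half_tables = (self.genotypes_csv is None) != (self.phenotypes_csv is None)
        if half_tables:
            raise ValueError("genotypes_csv and phenotypes_csv must be supplied together")
        if (self.generator is None) == (not have_tables):
            raise ValueError(
                "supply exactly one of: generator params, or genotype+phenotype CSV paths"
            )
        return self

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.model_validate(json.load(fh))

    def config_hash(self) -> str:
        return hashlib.sha256(self.model_dump_json().encode()).hexdigest()


class RunReport(BaseModel):
    """Per-stage results plus a cohort summary and a provenance block."""

    cohort_summary: Dict[str, Dict[str, Union[int, float]]]
    stages: Dict[str, Any]
    provenance: Dict[str, Any]

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.model_dump(mode="json"), indent=indent, sort_keys=True)


def summarize_cohort(phenotypes: pd.DataFrame) -> Dict[str, Dict[str, float]]:
    """Per-group n, age, %male, maximum IOP and VCDR summary (demographics table)."""
    out = {}
    for group, sub in phenotypes.groupby("group"):
        out[str(group)] = {
            "n": int(len(sub)),
            "age_mean": float(sub["age_years"].mean()),
            "age_sd": float(sub["age_years"].std(ddof=1)),
            "pct_male": float(100.0 * (sub["sex"].astype(str).str.upper() == "M").mean()),
            "max_iop_mean": float(sub["max_iop_mmhg"].mean()),
            "max_iop_sd": float(sub["max_iop_mmhg"].std(ddof=1)),
            "vcdr_mean": float(sub["mean_vcdr"].mean()),
            "vcdr_sd": float(sub["mean_vcdr"].std(ddof=1)),
        }
    return out


def _load_inputs(config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame, VariantPanel]:
    if config.generator is not None:
        cohort = sample_cohort(config.generator, seed=config.seed)
        return cohort.genotypes, cohort.phenotypes, config.generator.panel
    genotypes = read_genotypes_csv(config.genotypes_csv)
    phenotypes = read_phenotypes_csv(config.phenotypes_csv)
    panel = (
        VariantPanel.from_json(config.panel_json)
        if config.panel_json
        else VariantPanel.default()
    )
    return genotypes, phenotypes, panel


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the requested stages in dependency order and assemble a report."""
    requested = list(dict.fromkeys(config.stages))  # dedupe, keep order
    for stage in requested:
        if stage in SCORE_DEPENDENT and "score" not in requested:
            raise StageOrderError(f"stage '{stage}' requires stage 'score'")
    genotypes, phenotypes, panel = _load_inputs(config)

    stages: Dict[str, Any] = {s: {"skipped": True} for s in ALL_STAGES}
    scores = None
    if "score" in requested:
        scores = unweighted_grs(genotypes, panel, missing_policy=config.missing_policy)
        stages["score"] = {
            "kind": scores.kind,
            "n_scored": int(len(scores.scores)),
            "n_missing_handled": scores.n_missing_handled,
            "mean": float(scores.scores.mean()),
            "sd": float(scores.scores.std(ddof=1)) if len(scores.scores) > 1 else 0.0,
        }
        log.info("score: n=%d, mean=%.3f", len(scores.scores), scores.scores.mean())

    if "table2" in requested:
        stages["table2"] = iop_on_variants(genotypes, phenotypes, panel).model_dump()
    if "table3" in requested:
        stages["table3"] = iop_on_grs(phenotypes, scores).model_dump()
    if "table4" in requested:
        stages["table4"] = vcdr_on_grs(phenotypes, scores).model_dump()
    if "fig1" in requested:
        merged = phenotypes.merge(scores.to_frame(), on="participant_id")
        stages["fig1"] = anova_bonferroni(merged["grs"], merged["group"]).model_dump()
    if "table5" in requested:
        stages["table5"] = {
            "NTG": logistic_group_on_grs(phenotypes, scores, "NTG").model_dump(),
            "HTG": logistic_group_on_grs(phenotypes, scores, "HTG").model_dump(),
        }
    if "fig2" in requested:
        merged = phenotypes.merge(scores.to_frame(), on="participant_id")
        from .scoring import ScoreVector

        aligned = ScoreVector(
            participant_ids=merged["participant_id"].to_numpy(),
            scores=merged["grs"].to_numpy(dtype=float),
            kind=scores.kind,
        )
        results = cutoff_scan(aligned, merged["group"].to_numpy())
        highlight = next(
            (r for r in results if r.threshold == config.cutoff_threshold), None
        )
        stages["fig2"] = {
            "scan": [r.model_dump() for r in results],
            "highlight_threshold": config.cutoff_threshold,
            "highlight": highlight.model_dump() if highlight else None,
        }

    report = RunReport(
        cohort_summary=summarize_cohort(phenotypes),
        stages=stages,
        provenance={
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "version": __version__,
        },
    )
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(report.to_json())
        if scores is not None:
            scores.to_frame().to_csv(out / "scores.csv", index=False)
    return report
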