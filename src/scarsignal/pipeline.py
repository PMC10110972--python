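"""End-to-end orchestration: read or simulate → filter → signals → summaries.

``run_pipeline`` executes the whole analysis from a single validated
configuration and writes a reproducible output directory: the culprit-drug
list, the per-(drug, scope) signal table, every summary table, and a JSON
manifest with record counts, exclusion tallies and the conventions in force.
Identical configuration and seed produce byte-identical outputs (the
manifest carries no timestamps).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, model_validator

from . import __version__
from .disproportionality import screen_positive_drugs, signal_frame, signal_matrix
from .normalize import (
    ATCMap,
    IngredientMap,
    build_culprit_list,
    culprit_counts_per_scope,
)
from .report_model import deduplicate_reports, read_reports, write_reports
from .smq import builtin_scar_smq, filter_scar_reports
from .summarize import (
    descriptive_summary,
    positive_signal_distribution,
    reporting_proportions,
    write_summary_tsv,
)
from .synthetic import SimulationConfig, generate_reports, load_simulation_config

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger("scarsignal")


class PipelineError(Exception):
    """A pipeline stage failed; the message names the stage."""


class PipelineConfig(BaseModel):
    """Validated configuration for one pipeline run.

    Exactly one of ``input`` (a report file) or ``simulate`` (a simulation
    config, inline or a YAML path) must be given.
    """

    model_config = ConfigDict(extra="forbid", arbitrary_types_allowed=True)

    input: Optional[Path] = None
    dialect: Literal["openfda_json", "flat_table"] = "openfda_json"
    simulate: Optional[SimulationConfig | Path] = None
    ingredient_map: Optional[Path] = None
    atc_map: Optional[Path] = None
    out_dir: Path
    background: Literal["faers_background", "scar_only"] = "faers_background"
    zero_cell: Literal["none", "haldane"] = "none"
    top_n: int = 10
    seed: Optional[int] = None

    @model_validator(mode="after")
    def _check(self) -> "PipelineConfig":
        if (self.input is None) == (self.simulate is None):
            raise ValueError("exactly one of input/simulate must be set")
        for label, path in [
            ("input", self.input),
            ("ingredient_map", self.ingredient_map),
            ("atc_map", self.atc_map),
        ]:
            if path is not None and not Path(path).exists():
                raise ValueError(f"{label} file does not exist: {path}")
        if isinstance(self.simulate, Path) and not self.simulate.exists():
            raise ValueError(f"simulate config file does not exist: {self.simulate}")
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        return self


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the stage name attached."""
    class _Ctx:
        def __enter__(self):
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: done", name)
            return False

    return _Ctx()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage and return the machine-readable manifest (also written
    to ``<out_dir>/manifest.json``)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    smq = builtin_scar_smq()
    manifest: dict = {
        "tool": {"name": "scarsignal", "version": __version__},
        "conventions": {
            "background": cfg.background,
            "zero_cell": cfg.zero_cell,
            "ci_z": 1.96,
            "positive_rule": "ci_low > 1 and a >= 3",
            "multiple_testing_adjustment": "none",
            "top_n": cfg.top_n,
        },
        "seed": cfg.seed,
        "counts": {},
        "outputs": [],
    }

    with _stage("ingest"):
        if cfg.simulate is not None:
            sim = (
                load_simulation_config(cfg.simulate)
                if isinstance(cfg.simulate, Path)
                else cfg.simulate
            )
            if cfg.seed is not None:
                sim = sim.model_copy(update={"seed": cfg.seed})
            manifest["seed"] = sim.seed
            raw = generate_reports(sim, smq)
        else:
            raw = read_reports(cfg.input, cfg.dialect)
        manifest["counts"]["raw_reports"] = len(raw)
        manifest["counts"]["skipped_no_reactions"] = raw.skipped_no_reactions

    with _stage("deduplicate"):
        reports = deduplicate_reports(raw)
        manifest["counts"]["after_dedup"] = len(reports)
        manifest["counts"]["duplicates_removed"] = len(raw) - len(reports)

    with _stage("scar_filter"):
        scar_set, pt_counts = filter_scar_reports(reports, smq)
        manifest["counts"]["scar_reports"] = len(scar_set)
        write_reports(scar_set, out / "scar_reports.tsv", "flat_table")
        manifest["outputs"].append("scar_reports.tsv")

    with _stage("culprit_list"):
        imap = (
            IngredientMap.from_tsv(cfg.ingredient_map)
            if cfg.ingredient_map
            else IngredientMap()
        )
        atcmap = ATCMap.from_tsv(cfg.atc_map) if cfg.atc_map else ATCMap()
        culprits, tallies = build_culprit_list(scar_set, imap, atcmap)
        manifest["counts"]["culprit_drugs"] = len(culprits)
        manifest["counts"]["exclusions"] = tallies
        scope_table = culprit_counts_per_scope(culprits, scar_set, smq)
        scope_table.to_csv(out / "culprit_counts_per_scope.tsv", sep="\t", index=False)
        manifest["outputs"].append("culprit_counts_per_scope.tsv")

    with _stage("signals"):
        matrices = signal_matrix(
            reports, culprits, smq, imap,
            zero_cell=cfg.zero_cell, background=cfg.background,
        )
        frame = signal_frame(matrices)
        frame.to_csv(out / "signals.tsv", sep="\t", index=False)
        manifest["outputs"].append("signals.tsv")
        positives, histogram = screen_positive_drugs(matrices)
        (out / "positive_drugs.txt").write_text(
            "\n".join(positives) + ("\n" if positives else ""), encoding="utf-8"
        )
        manifest["outputs"].append("positive_drugs.txt")
        manifest["counts"]["drugs_with_positive_signal"] = len(positives)

    with _stage("summaries"):
        tables = descriptive_summary(scar_set, smq)
        for key, table in tables.items():
            write_summary_tsv(table, out / f"summary_{key}.tsv")
            manifest["outputs"].append(f"summary_{key}.tsv")
        for level in ("drug", "atc2"):
            table = reporting_proportions(
                scar_set, culprits, level=level, top_n=cfg.top_n, smq=smq
            )
            write_summary_tsv(table, out / f"top_{level}.tsv")
            manifest["outputs"].append(f"top_{level}.tsv")
        dist, n_ge1 = positive_signal_distribution(matrices)
        write_summary_tsv(dist, out / "positive_signal_distribution.tsv")
        manifest["outputs"].append("positive_signal_distribution.tsv")
        manifest["counts"]["drugs_with_ge1_positive"] = n_ge1

    manifest_path = out / "manifest.json"
    manifest_path.write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return manifest
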