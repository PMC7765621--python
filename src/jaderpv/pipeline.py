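"""End-to-end study pipeline: simulate/ingest -> clean -> analyse.

One config drives every stage; all randomness flows from a single seed, so
identical config + seed reproduces byte-identical outputs. Each filtering
stage logs before/after counts into a run manifest, from which the
flowchart of the record flow can be reconstructed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .demographics import summarize_groups, summary_frame
from .errors import ConfigurationError
from .logistic import LogisticRiskModel
from .profile import EventProfiler, to_newick
from .signals import RorSignalDetector
from .simulate import (OSTEONECROSIS_SMQ_TERMS, SynthConfig, config_from_dict,
                       default_study_config, generate, write_tables)
from .tables import (clean_bmi, deduplicate, filter_suspected, merge_cases,
                     read_jader_table, write_cases_csv)

log = logging.getLogger("jaderpv")


@dataclass
class RunConfig:
    """Configuration for one full pipeline run."""

    simulate: dict | None = None          # SynthConfig kwargs, or None
    inputs: dict | None = None            # {"drug":..., "reac":..., "demo":...}
    encoding: str = "utf-8"
    event_terms: list = field(default_factory=lambda: ["osteonecrosis of the jaw"])
    profile_event_terms: list = field(default_factory=lambda: list(OSTEONECROSIS_SMQ_TERMS))
    drugs: object = "all"                 # screened drugs
    logistic_drugs: list | None = None    # None -> use detected signals
    profile_drugs: list | None = None     # None -> use detected signals
    drug_classes: dict = field(default_factory=dict)
    covariates: list = field(default_factory=lambda: ["female", "age", "height", "weight"])
    bmi_low: float = 5.0
    bmi_high: float = 100.0
    ror_threshold: float = 1.0
    alpha: float = 0.05
    min_reports: int = 20
    k_clusters: int = 2
    seed: int = 0


@dataclass
class RunManifest:
    """Counts, outputs and provenance of one run."""

    config_hash: str
    seed: int
    version: str
    input_rows: dict = field(default_factory=dict)
    stage_counts: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


class PipelineStageError(RuntimeError):
    """A stage failed; carries the stage name and the partial manifest."""

    def __init__(self, stage: str, manifest: RunManifest, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.manifest = manifest
        self.cause = cause


def load_run_config(path) -> RunConfig:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def config_hash(config: RunConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def validate_config(config: RunConfig) -> list[str]:
    """Return a list of human-readable configuration issues (never mutates)."""
    issues = []
    if config.bmi_low >= config.bmi_high:
        issues.append(f"bmi_low ({config.bmi_low}) must be < bmi_high ({config.bmi_high})")
    if config.simulate is None and config.inputs is None:
        issues.append("either 'simulate' or 'inputs' must be given")
    if config.inputs is not None:
        for kind in ("drug", "reac", "demo"):
            p = config.inputs.get(kind)
            if p is None:
                issues.append(f"inputs missing path for {kind!r} table")
            elif not Path(p).exists():
                issues.append(f"input file not found: {p}")
    if not config.event_terms:
        issues.append("event_terms is empty")
    if not 0 < config.alpha < 1:
        issues.append(f"alpha out of (0,1): {config.alpha}")
    if config.min_reports < 0:
        issues.append(f"min_reports negative: {config.min_reports}")
    if isinstance(config.drugs, list):
        screened = set(config.drugs)
        for d in config.drug_classes:
            if d not in screened:
                issues.append(f"drug_classes entry {d!r} not in screened drug list")
    if config.simulate is not None:
        try:
            _build_synth_config(config).validate()
        except (ConfigurationError, TypeError) as exc:
            issues.append(f"simulate config invalid: {exc}")
    return issues


def _build_synth_config(config: RunConfig) -> SynthConfig:
    """Build the generator config; omitting `drugs` falls back to the
    default study configuration with any given fields overridden."""
    kwargs = dict(config.simulate)
    kwargs.setdefault("seed", config.seed)
    if "drugs" not in kwargs:
        base = default_study_config(n_cases=kwargs.pop("n_cases", 50_000),
                                    seed=kwargs.pop("seed"))
        return dataclasses.replace(base, **kwargs)
    return config_from_dict(kwargs)


def run_all(config: RunConfig, out_dir) -> RunManifest:
    """Execute every stage in order, writing all declared outputs.

    Output layout under `out_dir`: tables/ (when simulating), cases.csv,
    cleaning_report.json, table1.csv, table2.csv, volcano.tsv, table3.csv,
    range_odds_ratios.csv, profile/, manifest.json.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def rel(p):
        return str(Path(p).relative_to(out))

    manifest = RunManifest(config_hash=config_hash(config), seed=config.seed,
                           version=__version__)
    stage = "setup"
    try:
        stage = "ingest"
        if config.simulate is not None:
            synth = _build_synth_config(config)
            drug_df, reac_df, demo_df, _truth = generate(synth)
            paths = write_tables((drug_df, reac_df, demo_df), out / "tables")
            manifest.outputs["tables"] = {k: rel(v) for k, v in paths.items()}
            drug_paths = {"DRUG": paths["DRUG"], "REAC": paths["REAC"],
                          "DEMO": paths["DEMO"]}
        else:
            drug_paths = {"DRUG": config.inputs["drug"],
                          "REAC": config.inputs["reac"],
                          "DEMO": config.inputs["demo"]}
        tables = {kind: read_jader_table(p, kind, encoding=config.encoding)
                  for kind, p in drug_paths.items()}
        manifest.input_rows = {k: len(v) for k, v in tables.items()}

        stage = "clean"
        drug = filter_suspected(tables["DRUG"])
        manifest.stage_counts["drug_suspected_rows"] = len(drug)
        drug = deduplicate(drug, "DRUG")
        reac = deduplicate(tables["REAC"], "REAC")
        manifest.stage_counts["drug_dedup_rows"] = len(drug)
        manifest.stage_counts["reac_dedup_rows"] = len(reac)
        cases = merge_cases(drug, reac, tables["DEMO"])
        manifest.stage_counts["cases_merged"] = len(cases)
        cases, report = clean_bmi(cases, config.bmi_low, config.bmi_high)
        manifest.stage_counts.update({
            "cases_removed_low_bmi": report.n_removed_low_bmi,
            "cases_removed_high_bmi": report.n_removed_high_bmi,
            "cases_final": report.n_output,
        })
        write_cases_csv(cases, out / "cases.csv")
        (out / "cleaning_report.json").write_text(report.to_json())
        manifest.outputs["cases"] = rel(out / "cases.csv")
        manifest.outputs["cleaning_report"] = rel(out / "cleaning_report.json")

        stage = "demographics"
        table1 = summary_frame(summarize_groups(cases, config.event_terms))
        table1.to_csv(out / "table1.csv", index=False)
        manifest.outputs["table1"] = rel(out / "table1.csv")

        stage = "signals"
        detector = RorSignalDetector(config.event_terms, drugs=config.drugs,
                                     ror_threshold=config.ror_threshold,
                                     alpha=config.alpha).fit(cases)
        table2 = detector.results_.copy()
        table2.insert(1, "drug_class",
                      table2["drug"].map(config.drug_classes).fillna(""))
        table2.to_csv(out / "table2.csv", index=False)
        detector.volcano_table().to_csv(out / "volcano.tsv", sep="\t", index=False)
        manifest.outputs["table2"] = rel(out / "table2.csv")
        manifest.outputs["volcano"] = rel(out / "volcano.tsv")
        manifest.stage_counts["signals_detected"] = int(detector.results_["is_signal"].sum())

        stage = "logistic"
        drugs_for_model = (config.logistic_drugs
                           or detector.signals_["drug"].tolist())
        model = LogisticRiskModel(config.event_terms, drugs_for_model,
                                  covariates=tuple(config.covariates)).fit(cases)
        model.summary_frame().to_csv(out / "table3.csv", index=False)
        model.range_odds_ratios().to_csv(out / "range_odds_ratios.csv", index=False)
        manifest.outputs["table3"] = rel(out / "table3.csv")
        manifest.outputs["range_odds_ratios"] = rel(out / "range_odds_ratios.csv")
        manifest.stage_counts["logistic_n_used"] = model.n_used_
        manifest.stage_counts["logistic_n_dropped_missing"] = model.n_dropped_

        stage = "profile"
        profile_drugs = (config.profile_drugs
                         or detector.signals_["drug"].tolist())
        profiler = EventProfiler(profile_drugs, config.profile_event_terms,
                                 min_reports=config.min_reports,
                                 k=config.k_clusters).fit(cases)
        pdir = out / "profile"
        pdir.mkdir(exist_ok=True)
        profiler.ror_matrix_.to_csv(pdir / "ror_matrix.csv")
        profiler.loadings_.to_csv(pdir / "loadings.csv")
        profiler.scores_.to_csv(pdir / "scores.csv")
        pd.DataFrame({"component": [f"PC{i+1}" for i in range(len(profiler.contribution_ratios_))],
                      "contribution_pct": profiler.contribution_ratios_}
                     ).to_csv(pdir / "contributions.csv", index=False)
        pd.DataFrame(profiler.cluster_result_.linkage_matrix,
                     columns=["left", "right", "height", "size"]
                     ).to_csv(pdir / "merges.csv", index=False)
        profiler.labels_.rename_axis("event").to_csv(pdir / "labels.csv")
        (pdir / "dendrogram.nwk").write_text(to_newick(profiler.cluster_result_))
        manifest.outputs["profile"] = rel(pdir)

        stage = "manifest"
        (out / "manifest.json").write_text(manifest.to_json())
        manifest.outputs["manifest"] = rel(out / "manifest.json")
    except PipelineStageError:
        raise
    except Exception as exc:
        log.error("stage %s failed: %s", stage, exc)
        raise PipelineStageError(stage, manifest, exc) from exc
    return manifest
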