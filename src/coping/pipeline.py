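"""End-to-end pipeline: simulate -> classify -> stats.

Each stage reads the previous stage's CSV outputs, so the pipeline is
the same whether a cohort was simulated or supplied externally in the
documented schema. Every output carries a provenance sidecar and the
run emits a ``manifest.json`` with versions, seeds and file hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .classify import BootstrapConfig, average_latencies, classify_cohort
from .cohort import CohortModelParams, generate_cohort
from .io import config_hash, read_latency_table, write_sidecar, write_table
from .stats import one_way_anova, pearson_r2, tukey_hsd, two_sample_t, two_way_anova

__all__ = [
    "PipelineRunConfig",
    "PipelineStageError",
    "load_config",
    "run_pipeline",
    "stage_simulate",
    "stage_classify",
    "stage_stats",
]

logger = logging.getLogger("coping")

BEHAVIOR_ENDPOINT_COLUMNS = [
    "interaction_time_s",
    "interaction_latency_s",
    "distance_cm",
    "fst_pct_immobile",
    "fst_pct_swim",
    "fst_pct_climb",
]


class PipelineStageError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineRunConfig:
    """Configuration of one end-to-end run."""

    out_dir: Path
    params: CohortModelParams = field(default_factory=CohortModelParams)
    bootstrap: BootstrapConfig = field(default_factory=BootstrapConfig)
    day_range: tuple[int, int] = (1, 7)
    seed: int = 0

    def __post_init__(self):
        self.out_dir = Path(self.out_dir)
        # one master seed drives both stages' substreams
        self.params = dataclasses.replace(self.params, seed=self.seed)
        self.bootstrap = dataclasses.replace(self.bootstrap, seed=self.seed + 1)


def load_config(path: str | Path, out_dir: str | Path, seed: int | None = None):
    """Build a PipelineRunConfig from a YAML file.

    Recognized top-level keys: ``cohort`` (CohortModelParams fields;
    ``behavior_cells`` maps endpoint -> "stress/drug" -> [mean, sd]),
    ``bootstrap`` (BootstrapConfig fields), ``day_range`` ([first,
    last]), ``seed``. All keys optional; omitted fields keep defaults.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cohort_kwargs = dict(raw.get("cohort", {}))
    if "behavior_cells" in cohort_kwargs:
        parsed: dict = {}
        for endpoint, cells in cohort_kwargs["behavior_cells"].items():
            parsed[endpoint] = {
                tuple(key.split("/")): (float(v[0]), float(v[1]))
                for key, v in cells.items()
            }
        cohort_kwargs["behavior_cells"] = parsed
    params = CohortModelParams(**cohort_kwargs)
    bootstrap = BootstrapConfig(**raw.get("bootstrap", {}))
    day_range = tuple(raw.get("day_range", (1, 7)))
    cfg_seed = seed if seed is not None else int(raw.get("seed", 0))
    return PipelineRunConfig(
        out_dir=Path(out_dir),
        params=params,
        bootstrap=bootstrap,
        day_range=day_range,  # type: ignore[arg-type]
        seed=cfg_seed,
    )


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def stage_simulate(config: PipelineRunConfig) -> dict[str, Path]:
    """Generate a cohort and write its four tables."""
    out = config.out_dir
    cohort = generate_cohort(config.params)
    paths = {}
    for name, df in [
        ("cohort_latencies", cohort.latencies),
        ("cohort_truth", cohort.truth),
        ("cohort_expression", cohort.expression),
        ("cohort_behavior", cohort.behavior),
    ]:
        p = write_table(df, out / f"{name}.csv")
        write_sidecar(p, "simulate", config.seed, config.params)
        paths[name] = p
    logger.info("[simulate] wrote %d tables to %s", len(paths), out)
    return paths


def stage_classify(config: PipelineRunConfig) -> dict[str, Path]:
    """Read cohort_latencies.csv, classify, write classification.csv."""
    out = config.out_dir
    lat_path = out / "cohort_latencies.csv"
    latencies = read_latency_table(
        lat_path, config.params.latency_floor, config.params.latency_cap
    )
    if latencies.empty:
        raise ValueError("empty cohort: no defeated animals to classify")
    avg = average_latencies(latencies, config.day_range)
    result = classify_cohort(avg, config.bootstrap)
    p = write_table(result.table, out / "classification.csv")
    write_sidecar(
        p,
        "classify",
        config.bootstrap.seed,
        config.bootstrap,
        day_range=list(config.day_range),
        n_excluded=result.n_excluded,
        exclusion_fraction=result.exclusion_fraction,
        n_degenerate_redraws=result.n_degenerate_redraws,
    )
    logger.info(
        "[classify] %d animals, %d excluded", len(result.table), result.n_excluded
    )
    return {"classification": p}


def _stats_reports(
    classification: pd.DataFrame,
    expression: pd.DataFrame,
    behavior: pd.DataFrame,
) -> list[tuple[str, pd.DataFrame]]:
    reports: list[tuple[str, pd.DataFrame]] = []
    retained = classification[classification["label"] != "excluded"]

    # passive vs active average latency
    passive = retained.loc[retained["label"] == "passive", "avg_latency_s"]
    active = retained.loc[retained["label"] == "active", "avg_latency_s"]
    if len(passive) >= 2 and len(active) >= 2:
        rep = two_sample_t(passive, active)
        reports.append(("latency_passive_vs_active", rep.to_frame()))

    # expression by stress group (control + retained phenotypes), Tukey post hoc
    expr = expression.merge(
        retained[["animal_id", "label"]], on="animal_id", how="left"
    )
    expr["stress"] = expr["label"].where(
        expr["group"] == "defeated", "control"
    )
    expr = expr.dropna(subset=["stress"])
    groups = {
        name: sub["expression"].to_numpy()
        for name, sub in expr.groupby("stress")
        if len(sub) >= 2
    }
    if len(groups) >= 2:
        reports.append(("expression_one_way_anova", one_way_anova(groups).to_frame()))
        reports.append(
            (
                "expression_tukey",
                tukey_hsd(expr["expression"], expr["stress"]).to_frame(),
            )
        )

    # latency vs expression correlation among defeated animals
    defeated_expr = expr[expr["group"] == "defeated"].dropna(subset=["avg_latency_s"])
    if len(defeated_expr) >= 3:
        rep = pearson_r2(defeated_expr["avg_latency_s"], defeated_expr["expression"])
        frame = rep.to_frame()
        frame["comparison"] = "avg_latency vs expression"
        frame["mean_diff"] = rep.extras["r2"]
        reports.append(("latency_expression_correlation", frame))

    # two-way stress-by-drug ANOVA + Tukey per behavioral endpoint
    behav = behavior.merge(
        retained[["animal_id", "label"]], on="animal_id", how="left"
    )
    behav["stress"] = behav["label"].where(behav["stress"] != "control", "control")
    behav = behav.dropna(subset=["stress"])
    for endpoint in BEHAVIOR_ENDPOINT_COLUMNS:
        if endpoint not in behav.columns:
            continue
        counts = behav.groupby(["stress", "drug"], observed=True)[endpoint].count()
        if len(counts) < 6 or (counts < 2).any():
            continue
        reports.append(
            (f"{endpoint}_two_way_anova", two_way_anova(behav, endpoint).to_frame())
        )
        cell_labels = behav["stress"] + "/" + behav["drug"]
        reports.append(
            (f"{endpoint}_tukey", tukey_hsd(behav[endpoint], cell_labels).to_frame())
        )
    return reports


def stage_stats(config: PipelineRunConfig) -> dict[str, Path]:
    """Read classified cohort tables, write stats_report.csv and report.txt."""
    out = config.out_dir
    classification = pd.read_csv(out / "classification.csv")
    expression = pd.read_csv(out / "cohort_expression.csv")
    behavior = pd.read_csv(out / "cohort_behavior.csv")
    reports = _stats_reports(classification, expression, behavior)

    frames = []
    for name, frame in reports:
        frame = frame.copy()
        frame.insert(0, "analysis", name)
        frames.append(frame)
    if frames:
        with warnings.catch_warnings():
            # frames legitimately differ in which numeric columns are all-NA
            warnings.simplefilter("ignore", FutureWarning)
            report_df = pd.concat(frames, ignore_index=True)
    else:
        report_df = pd.DataFrame()
    p = write_table(report_df, out / "stats_report.csv")
    write_sidecar(p, "stats", config.seed, config.bootstrap)

    lines = [f"coping {__version__} statistical report", ""]
    for name, frame in reports:
        lines.append(f"== {name} ==")
        lines.append(frame.to_string(index=False))
        lines.append("")
    (out / "report.txt").write_text("\n".join(lines))
    logger.info("[stats] wrote %d analyses", len(reports))
    return {"stats_report": p, "report": out / "report.txt"}


def run_pipeline(config: PipelineRunConfig) -> dict:
    """Run simulate -> classify -> stats; return the run manifest."""
    config.out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    for stage_name, stage in [
        ("simulate", stage_simulate),
        ("classify", stage_classify),
        ("stats", stage_stats),
    ]:
        try:
            outputs.update(stage(config))
        except Exception as exc:
            raise PipelineStageError(f"stage {stage_name!r} failed: {exc}") from exc
    manifest = {
        "version": __version__,
        "python": sys.version.split()[0],
        "seed": config.seed,
        "config_hash": config_hash(
            {
                "params": config.params,
                "bootstrap": config.bootstrap,
                "day_range": list(config.day_range),
            }
        ),
        "outputs": {k: {"path": str(v), "sha256": _hash_file(v)} for k, v in outputs.items()},
    }
    (config.out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
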