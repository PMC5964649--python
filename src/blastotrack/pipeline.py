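"""End-to-end orchestration: load/generate -> validate -> annotate ->
rescale -> statistics -> in silico comparison.

All outputs are plain CSV tables plus a JSON run manifest; identical
(inputs, config, seed) produce identical files.  The CLI in
:mod:`blastotrack.cli` is a thin shell over these stage functions.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import LineageValidationError
from .identity import AnnotatedLineage, annotate_lineage
from .insilico import (
    CONDITION_INNER_SYM,
    CONDITION_OBSERVED,
    CONDITION_OUTER_SYM,
    condition_comparison,
    run_conditions,
)
from .lineage_io import (
    IDENTITY_INNER,
    EmbryoLineage,
    LineageMetadata,
    read_lineage_table,
    validate_lineage,
    write_lineage_table,
)
from .stats import (
    asymmetric_division_proportion,
    attach_normalized_age,
    counts_by_type,
    counts_on_grid,
    founder_clone_summary,
    group_normalized_death_ratio,
    make_bins,
    neighborhood_composition,
    proportion_inner,
    relative_developmental_speed,
)
from .timescale import (
    TimeScale,
    common_window,
    compute_timescale,
    observation_window_na,
)

DEFAULT_CONDITIONS = [CONDITION_OBSERVED, CONDITION_OUTER_SYM, CONDITION_INNER_SYM]


@dataclass
class PipelineConfig:
    """Run configuration; defaults follow the analysis conventions
    (10% collapse threshold, 0.05 n.a. bins, 8 nearest neighbors)."""

    embryos: list[dict] = field(default_factory=list)
    drop_threshold: float = 0.10
    bin_width_na: float = 0.05
    shell_tolerance: float = 0.5
    k_neighbors: int = 8
    conditions: list[str] = field(default_factory=lambda: list(DEFAULT_CONDITIONS))
    seed: int = 0
    output_dir: str = "blastotrack_out"

    def __post_init__(self) -> None:
        if not 0 < self.drop_threshold < 1:
            raise ValueError("drop_threshold must lie in (0, 1)")
        if self.bin_width_na <= 0 or self.shell_tolerance < 0 or self.k_neighbors < 1:
            raise ValueError("invalid threshold configuration")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in data.items() if k in known})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class EmbryoResult:
    """Per-embryo products accumulated across the stages."""

    lineage: EmbryoLineage
    annotated: AnnotatedLineage | None = None
    timescale: TimeScale | None = None
    window_na: tuple[float, float] | None = None

    @property
    def embryo_id(self) -> str:
        return self.lineage.metadata.embryo_id

    @property
    def group(self) -> str:
        return self.lineage.metadata.group


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def load_cohort(config: PipelineConfig, base_dir: str | Path = ".") -> list[EmbryoResult]:
    base = Path(base_dir)
    results = []
    for entry in config.embryos:
        meta = LineageMetadata(
            embryo_id=entry["embryo_id"],
            group=entry.get("group", "wild_type"),
            time_origin=entry.get("time_origin", "fertilization"),
            fertilization_offset_h=float(entry.get("fertilization_offset_h", 8.0)),
            frame_interval_min=float(entry.get("frame_interval_min", 15.0)),
        )
        lineage = read_lineage_table(base / entry["path"], meta)
        results.append(EmbryoResult(lineage=lineage))
    return results


def stage_validate(cohort: list[EmbryoResult]) -> dict[str, str]:
    """Validate every lineage; raises on the first failing embryo."""
    summaries = {}
    for res in cohort:
        report = validate_lineage(res.lineage)
        summaries[res.embryo_id] = report.summary()
        if not report.passed:
            raise LineageValidationError(
                f"{res.embryo_id} failed validation:\n{report.summary()}")
    return summaries


def stage_annotate(cohort: list[EmbryoResult], config: PipelineConfig) -> None:
    for res in cohort:
        res.annotated = annotate_lineage(
            res.lineage, shell_tolerance=config.shell_tolerance)


def stage_rescale(cohort: list[EmbryoResult], config: PipelineConfig) -> None:
    for res in cohort:
        ts, _ = compute_timescale(res.lineage, config.drop_threshold)
        res.timescale = ts
        res.window_na = observation_window_na(res.lineage, ts)
        if res.annotated is not None:
            res.annotated = attach_normalized_age(res.annotated, ts)


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def timescale_table(cohort: list[EmbryoResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "embryo_id": r.embryo_id,
        "group": r.group,
        "t_collapse_hp": r.timescale.t_collapse_hp,
        "collapse_timestep": r.timescale.collapse_timestep,
        "window_lo_na": r.window_na[0],
        "window_hi_na": r.window_na[1],
    } for r in cohort])


def speed_table(cohort: list[EmbryoResult]) -> pd.DataFrame:
    wt = [r.timescale.t_collapse_hp for r in cohort if r.group == "wild_type"]
    rows = []
    for r in cohort:
        if r.group == "clone" and wt:
            rows.append({
                "embryo_id": r.embryo_id,
                "slowdown_percent": relative_developmental_speed(
                    r.timescale.t_collapse_hp, wt),
            })
    return pd.DataFrame(rows, columns=["embryo_id", "slowdown_percent"])


def counts_table(cohort: list[EmbryoResult], grid: np.ndarray) -> pd.DataFrame:
    rows = []
    for r in cohort:
        on_grid = counts_on_grid(counts_by_type(r.annotated, r.timescale), grid)
        on_grid.insert(0, "embryo_id", r.embryo_id)
        on_grid.insert(1, "group", r.group)
        on_grid["pic"] = proportion_inner(on_grid)
        rows.append(on_grid)
    return pd.concat(rows, ignore_index=True)


def division_proportion_table(
    cohort: list[EmbryoResult], window, config: PipelineConfig
) -> pd.DataFrame:
    edges = make_bins(window.lo_na, window.hi_na, config.bin_width_na)
    rows = []
    for group in sorted({r.group for r in cohort}):
        divisions = [d for r in cohort if r.group == group
                     for d in r.annotated.divisions]
        for label, mother in (("OAD", "outer"), ("IAD", "inner")):
            binned = asymmetric_division_proportion(divisions, mother, edges)
            frame = binned.to_frame()
            frame.insert(0, "group", group)
            frame.insert(1, "statistic", label)
            rows.append(frame)
    return pd.concat(rows, ignore_index=True)


def death_ratio_table(cohort: list[EmbryoResult], window) -> pd.DataFrame:
    rows = []
    for group in sorted({r.group for r in cohort}):
        sub = [(r.annotated, r.timescale) for r in cohort if r.group == group]
        for identity in ("inner", "outer"):
            stat, excluded = group_normalized_death_ratio(
                sub, identity, (window.lo_na, window.hi_na))
            rows.append({
                "group": group,
                "identity": identity,
                "mean": stat.mean,
                "sd": stat.sd,
                "se": stat.se,
                "n_embryos": stat.n,
                "n_excluded": len(excluded),
            })
    return pd.DataFrame(rows)


def neighborhood_table(cohort: list[EmbryoResult], config: PipelineConfig) -> pd.DataFrame:
    rows = []
    for r in cohort:
        frame = neighborhood_composition(r.annotated, k=config.k_neighbors)
        frame.insert(0, "embryo_id", r.embryo_id)
        frame.insert(1, "group", r.group)
        rows.append(frame)
    return pd.concat(rows, ignore_index=True)


def founder_table(cohort: list[EmbryoResult]) -> pd.DataFrame:
    rows = []
    for r in cohort:
        for s in founder_clone_summary(r.annotated):
            rows.append({
                "embryo_id": r.embryo_id,
                "group": r.group,
                "founder_track_id": s.founder_track_id,
                "founder_identity": s.founder_identity,
                "n_mitoses": s.n_mitoses,
                "n_final_inner": s.n_final_inner,
                "n_final_outer": s.n_final_outer,
                "n_dead": s.n_dead,
            })
    return pd.DataFrame(rows, columns=[
        "embryo_id", "group", "founder_track_id", "founder_identity",
        "n_mitoses", "n_final_inner", "n_final_outer", "n_dead"])


def insilico_table(
    cohort: list[EmbryoResult], grid: np.ndarray, config: PipelineConfig
) -> pd.DataFrame:
    rows = []
    for group in sorted({r.group for r in cohort}):
        sub = [(r.annotated, r.timescale) for r in cohort if r.group == group]
        if len(sub) < 2:
            continue
        frame = condition_comparison(sub, grid, config.conditions)
        frame.insert(0, "group", group)
        rows.append(frame)
    if not rows:
        return pd.DataFrame(
            columns=["group", "condition", "na", "cell_type", "mean_count", "cv"])
    return pd.concat(rows, ignore_index=True)


def annotated_lineage_with_identities(res: EmbryoResult) -> EmbryoLineage:
    """Copy of the lineage whose identity column carries the per-track
    annotation on every node."""
    lineage = res.lineage
    nodes = lineage.nodes.copy()
    ident = nodes["identity"].copy()
    for tid, value in res.annotated.identities.items():
        ident.loc[lineage.tracks[tid].node_ids] = value
    nodes["identity"] = ident
    return EmbryoLineage(metadata=lineage.metadata, nodes=nodes)


# ---------------------------------------------------------------------------
# Full run
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig, base_dir: str | Path = ".") -> Path:
    """Execute every stage and write the report bundle to the output dir.

    Returns the output directory.  Any stage failure propagates as the
    corresponding package exception; partial outputs carry an ``incomplete``
    marker in the manifest directory.
    """
    outdir = Path(base_dir) / config.output_dir
    outdir.mkdir(parents=True, exist_ok=True)
    marker = outdir / "INCOMPLETE"
    marker.write_text("run in progress\n")

    cohort = load_cohort(config, base_dir)
    summaries = stage_validate(cohort)
    (outdir / "validation_report.txt").write_text(
        "\n\n".join(f"{k}\n{v}" for k, v in summaries.items()) + "\n")

    stage_annotate(cohort, config)
    stage_rescale(cohort, config)

    timescale_table(cohort).to_csv(outdir / "timescales.csv", index=False)
    speed_table(cohort).to_csv(outdir / "relative_speed.csv", index=False)

    window = common_window([r.window_na for r in cohort])
    grid = window.grid(config.bin_width_na)

    counts_table(cohort, grid).to_csv(outdir / "counts.csv", index=False)
    division_proportion_table(cohort, window, config).to_csv(
        outdir / "division_proportions.csv", index=False)
    death_ratio_table(cohort, window).to_csv(
        outdir / "death_ratios.csv", index=False)
    neighborhood_table(cohort, config).to_csv(
        outdir / "neighborhood.csv", index=False)
    founder_table(cohort).to_csv(outdir / "founders.csv", index=False)
    insilico_table(cohort, grid, config).to_csv(
        outdir / "insilico_cv.csv", index=False)

    annotated_dir = outdir / "annotated"
    annotated_dir.mkdir(exist_ok=True)
    for r in cohort:
        write_lineage_table(annotated_lineage_with_identities(r),
                            annotated_dir / f"{r.embryo_id}.csv")

    manifest = {
        "package": "blastotrack",
        "version": __version__,
        "python": platform.python_version(),
        "config": config.to_dict(),
        "common_window_na": [window.lo_na, window.hi_na],
        "embryos": [r.embryo_id for r in cohort],
        "tables": sorted(p.name for p in outdir.glob("*.csv")),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    marker.unlink()
    return outdir


def write_cohort_config(
    outdir: str | Path,
    embryo_entries: list[dict],
    seed: int,
    **extra,
) -> Path:
    """Write the cohort YAML consumed by ``run-all``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    payload = {"embryos": embryo_entries, "seed": seed, **extra}
    path = outdir / "cohort.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
    return path
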