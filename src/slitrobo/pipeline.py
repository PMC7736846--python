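"""End-to-end orchestration: annotations -> sequence stage -> structure
stage -> docking stage -> graded report, with a manifest of every decision
value used so an identical analysis can be re-run from the manifest alone.
"""

from __future__ import annotations

import json
import logging
import tomllib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import docking, sequence, structure, tables
from .records import Grade, ScoredComplex

logger = logging.getLogger("slitrobo")


@dataclass
class PipelineConfig:
    annotation_table: str | None = None
    dock_table: str | None = None
    output_dir: str = "slitrobo_out"
    pooling: str = "all"                    # median pooling for the sequence stage
    grouping: tuple[str, ...] = ("gene", "dataset", "region")
    rmsd_tolerance: float = 1e-3            # neutral band for RMSD classes, A
    energy_tolerance: float = 1e-9          # neutral band for energy classes
    orbit_width: float = 0.1                # relative-ASA width of one orbit
    intra_orbit_tolerance: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("rmsd_tolerance", "energy_tolerance"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        data = tomllib.loads(Path(path).read_text())
        if "grouping" in data:
            data["grouping"] = tuple(data["grouping"])
        return cls(**data)


@dataclass
class PipelineResult:
    sequence_table: pd.DataFrame | None = None
    structure_table: pd.DataFrame | None = None
    dock_report: pd.DataFrame | None = None
    summaries: dict[str, object] = field(default_factory=dict)
    disruptor_counts: dict[tuple[str, str], int] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)
    graded: list[ScoredComplex] = field(default_factory=list)


def run_prioritisation(
    annotation_path: str | Path, config: PipelineConfig
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Sequence-stage scoring/median selection, then structure-stage
    scoring/top-two selection, over an annotation table."""
    records = tables.read_annotation_table(annotation_path)
    scored = [(v, sequence.score_sequence_outcomes(o)) for v, o, _ in records]
    selected, thresholds = sequence.select_by_median(scored, config.pooling)
    logger.info("sequence stage: median thresholds %s; %d/%d variants pass",
                thresholds, len(selected), len(scored))
    seq_rows = []
    selected_keys = {(v.gene, v.protein_change) for v, _ in selected}
    for variant, vec in scored:
        seq_rows.append({
            "gene": variant.gene, "protein_change": variant.protein_change,
            "dataset": variant.dataset.value, "region": variant.region.value,
            "cumulative": vec.cumulative,
            "missing_tools": ";".join(vec.missing_tools),
            "selected": (variant.gene, variant.protein_change) in selected_keys,
        })
    seq_table = pd.DataFrame(seq_rows)

    struct_records = [
        (v, o, s) for v, o, s in records
        if (v.gene, v.protein_change) in selected_keys]
    combined = []
    for variant, outcomes, struct_outcomes in struct_records:
        seq_vec = sequence.score_sequence_outcomes(outcomes)
        vec = structure.score_structure_outcomes(struct_outcomes, seq_vec)
        combined.append((variant, vec))
    kept = structure.select_top_two([(v, vec.combined_total) for v, vec in combined])
    kept_keys = {(v.gene, v.protein_change) for v, _ in kept}
    struct_rows = [{
        "gene": v.gene, "protein_change": v.protein_change,
        "dataset": v.dataset.value, "region": v.region.value,
        "cumulative_structure": vec.cumulative_structure,
        "combined_total": vec.combined_total,
        "selected_for_docking": (v.gene, v.protein_change) in kept_keys,
    } for v, vec in combined]
    manifest = {"median_thresholds": thresholds,
                "pooling": config.pooling,
                "grouping": list(config.grouping)}
    return seq_table, pd.DataFrame(struct_rows), manifest


def run_docking_assessment(
    dock_path: str | Path, config: PipelineConfig
) -> tuple[list[ScoredComplex], dict, dict[tuple[str, str], int], dict]:
    """Score, grade and summarise a docking-parameter table."""
    complexes = tables.read_dock_table(dock_path)
    summaries = docking.grade_all(complexes)
    counts = docking.disruptor_count_matrix(complexes)
    for summary in summaries.values():
        logger.info("category %s: n=%d mean TS=%.3f (%d more / %d less)",
                    summary.category, summary.n_complexes,
                    summary.mean_total_score, summary.n_more, summary.n_less)
    manifest = {
        "rmsd_tolerance": config.rmsd_tolerance,
        "energy_tolerance": config.energy_tolerance,
        "category_means": {c: s.mean_total_score for c, s in summaries.items()},
        "tie_rule": "ties at the category mean grade less_disrupting, flagged",
    }
    return complexes, summaries, counts, manifest


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage for which the config names an input table.

    Writes per-stage TSVs, a graded docking report, the disruptor-count
    matrix and ``manifest.json`` into the output directory.  Fails fast if
    a configured input is missing.
    """
    for path in (config.annotation_table, config.dock_table):
        if path is not None and not Path(path).exists():
            raise FileNotFoundError(path)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    result = PipelineResult()
    manifest: dict = {"config": {**asdict(config),
                                 "grouping": list(config.grouping)}}

    if config.annotation_table:
        try:
            seq_table, struct_table, stage_manifest = run_prioritisation(
                config.annotation_table, config)
        except Exception as exc:
            raise RuntimeError(f"prioritisation stage failed: {exc}") from exc
        result.sequence_table = seq_table
        result.structure_table = struct_table
        manifest["prioritisation"] = stage_manifest
        seq_table.to_csv(out_dir / "sequence_scores.tsv", sep="\t", index=False)
        struct_table.to_csv(out_dir / "structure_scores.tsv", sep="\t", index=False)

    if config.dock_table:
        try:
            graded, summaries, counts, stage_manifest = run_docking_assessment(
                config.dock_table, config)
        except Exception as exc:
            raise RuntimeError(f"docking stage failed: {exc}") from exc
        result.graded = graded
        result.summaries = summaries
        result.disruptor_counts = counts
        manifest["docking"] = stage_manifest
        report = tables.complexes_to_frame(graded)
        result.dock_report = report
        report.to_csv(out_dir / "dock_report.tsv", sep="\t", index=False)
        count_rows = [{"mutant_gene": g, "wild_type_partner": p, "n_more_disrupting": n}
                      for (g, p), n in counts.items()]
        pd.DataFrame(count_rows).to_csv(
            out_dir / "disruptor_counts.tsv", sep="\t", index=False)

    result.manifest = manifest
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return result
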