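"""End-to-end orchestration: files in, tables/tests/logs out.

`run_protein_pipeline` chains normalization -> median-reference fold changes
-> replicate averaging -> operon positioning -> median correction ->
classification, the +1 Wilcoxon tests and the distance correlation.
`run_rna_pipeline` does the RNA equivalent from WIG coverage.  Both write
every table as TSV, test results as JSON, and a structured run log with
per-stage counts so the n behind every statistic is recomputable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .annotations import load_annotations, load_operons
from .polar import (
    classify_operon_effects,
    distance_correlation,
    downstream_gene_test,
    operon_median_correction,
    position_fold_changes,
    summarize_classes,
)
from .proteomics import (
    average_replicates,
    fold_changes_vs_median,
    normalize_intensities,
    read_intensity_matrix,
    write_fold_changes,
)
from .rnaseq import (
    filter_low_density,
    gene_density_table,
    read_wig,
    rna_fold_changes,
    sum_strand_tracks,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_protein_pipeline", "run_rna_pipeline"]


@dataclass
class RunConfig:
    """Declarative configuration of one pipeline run."""

    annotations: str
    operons: str
    deletions: str
    outdir: str
    intensities: str | None = None
    sample_sheet: str | None = None
    wig_sheet: str | None = None
    normalization: str = "vsn_like"
    replicate_average_scale: str = "log"
    min_genes: int = 2
    include_p1_in_downstream_median: bool = True
    classification_threshold_log2: float = 1.0
    test_method: str = "rank_sum"
    density_threshold: float = 1.0
    exclude_mutants: list[str] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.classification_threshold_log2 <= 0:
            raise ValueError("classification threshold must be > 0")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _load_deletions(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["mutant_id"], df["gene_id"]))


def _write_run_log(outdir: Path, config: RunConfig, stage_counts: dict) -> None:
    log = {
        "package_version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "stages": stage_counts,
    }
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=1, sort_keys=True)


def _analyze_positioned(
    fc: pd.DataFrame,
    config: RunConfig,
    outdir: Path,
    datatype: str,
    stage_counts: dict,
) -> dict:
    annotations = load_annotations(config.annotations)
    operons = load_operons(config.operons)
    deletions = _load_deletions(config.deletions)
    stage_counts["genes_annotated"] = len(annotations)
    stage_counts["operons"] = len(operons)
    stage_counts["mutants"] = len(deletions)

    positioned, controls = position_fold_changes(
        fc, operons, deletions, annotations,
        exclude_mutants=set(config.exclude_mutants),
    )
    corrected = operon_median_correction(
        positioned,
        min_genes=config.min_genes,
        include_p1_in_downstream_median=config.include_p1_in_downstream_median,
    )
    classes = classify_operon_effects(
        corrected, threshold_log2=config.classification_threshold_log2
    )
    summary = summarize_classes(classes)
    stage_counts["positioned_rows"] = len(corrected)
    stage_counts["not_in_operon_rows"] = len(controls)
    stage_counts["n_per_position"] = {
        str(int(k)): int(v)
        for k, v in corrected.groupby("position").size().items()
    }
    stage_counts.update({f"class_{k}": v for k, v in summary.items()})

    tests: dict[str, dict] = {}
    for use_corrected, label in ((False, "uncorrected"), (True, "corrected")):
        try:
            res = downstream_gene_test(
                corrected, datatype=datatype,
                use_corrected=use_corrected, method=config.test_method,
            )
            tests[f"p1_test_{label}"] = res.to_dict()
        except ValueError as exc:
            logger.warning("+1 test (%s) skipped: %s", label, exc)
    if datatype == "protein":
        try:
            tests["distance_correlation"] = distance_correlation(
                corrected, datatype=datatype
            ).to_dict()
        except ValueError as exc:
            logger.warning("distance correlation skipped: %s", exc)

    corrected.to_csv(outdir / f"positioned_{datatype}.tsv", sep="\t", index=False)
    controls.to_csv(outdir / f"not_in_operon_{datatype}.tsv", sep="\t", index=False)
    classes.to_csv(outdir / f"operon_classes_{datatype}.tsv", sep="\t", index=False)
    with open(outdir / f"tests_{datatype}.json", "w") as fh:
        json.dump({"note": "p-values are unadjusted", **tests}, fh, indent=1)
    return {
        "positioned": corrected,
        "not_in_operon": controls,
        "classes": classes,
        "class_summary": summary,
        "tests": tests,
    }


def run_protein_pipeline(config: RunConfig) -> dict:
    """Run the proteomics branch; returns the bundle of result tables."""
    if not config.intensities or not config.sample_sheet:
        raise ValueError("protein pipeline needs intensities and sample_sheet paths")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage_counts: dict = {}

    matrix = read_intensity_matrix(config.intensities, config.sample_sheet)
    stage_counts["proteins_read"] = matrix.values.shape[0]
    stage_counts["samples_read"] = matrix.values.shape[1]
    try:
        normalized = normalize_intensities(matrix, method=config.normalization)
    except Exception as exc:
        raise RuntimeError(f"stage 'normalize_intensities' failed: {exc}") from exc
    per_sample = fold_changes_vs_median(normalized)
    fc = average_replicates(per_sample, scale=config.replicate_average_scale)
    stage_counts["fold_change_rows"] = len(fc)
    write_fold_changes(fc, outdir / "fold_changes_protein.tsv")

    bundle = _analyze_positioned(fc, config, outdir, "protein", stage_counts)
    bundle["fold_changes"] = fc
    _write_run_log(outdir, config, stage_counts)
    return bundle


def run_rna_pipeline(config: RunConfig) -> dict:
    """Run the transcriptomics branch; returns the bundle of result tables."""
    if not config.wig_sheet:
        raise ValueError("rna pipeline needs a wig_sheet path")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage_counts: dict = {}

    annotations = load_annotations(config.annotations)
    sheet = pd.read_csv(config.wig_sheet, sep="\t")
    tracks = {}
    for _, row in sheet.iterrows():
        try:
            fwd = read_wig(row["fwd_path"])
            rev = read_wig(row["rev_path"])
            tracks[row["mutant_id"]] = sum_strand_tracks(fwd, rev)
        except Exception as exc:
            raise RuntimeError(
                f"stage 'read_wig' failed for mutant {row['mutant_id']!r}: {exc}"
            ) from exc
    stage_counts["tracks_read"] = len(tracks)

    densities = gene_density_table(tracks, annotations)
    kept = filter_low_density(densities, threshold=config.density_threshold)
    stage_counts["density_rows"] = len(densities)
    stage_counts["density_rows_kept"] = len(kept)
    fc = rna_fold_changes(kept)
    stage_counts["fold_change_rows"] = len(fc)
    densities.to_csv(outdir / "gene_densities.tsv", sep="\t", index=False)
    write_fold_changes(fc, outdir / "fold_changes_rna.tsv")

    bundle = _analyze_positioned(fc, config, outdir, "rna", stage_counts)
    bundle["fold_changes"] = fc
    bundle["densities"] = kept
    _write_run_log(outdir, config, stage_counts)
    return bundle
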