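"""Synthetic mutant libraries with operon polar-effect structure.

The generator emulates a Keio-style single-gene deletion library measured by
multiplexed proteomics and strand-separated RNA-seq coverage:

* a bacterial chromosome of non-overlapping operons laid head-to-tail, each
  an ordered run of genes with realistic lengths and intergenic distances
  (overlapping ORFs allowed);
* one deletion mutant per multi-gene operon, plus control deletions in
  single-gene operons;
* per mutant, an operon-wide transcriptional shift (up- or downregulation of
  all downstream genes, affecting RNA and protein alike), drawn from an
  up/down/none mixture;
* an additional protein-only deficit on the gene directly downstream of the
  deletion, decaying with intergenic distance — the post-transcriptional
  signature the analysis is built to detect;
* lognormal measurement noise per protein replicate, samples packed into
  TMT-style plexes; Poisson per-position RNA coverage.

Every drawn effect is recorded in a :class:`GroundTruth` so that pipeline
estimates can be checked against the simulation truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .annotations import (
    GeneAnnotation,
    OperonStructure,
    intergenic_distance,
    relative_positions,
)
from .proteomics import IntensityMatrix
from .rnaseq import CoverageTrack, write_wig

__all__ = [
    "SimulationParams",
    "GroundTruth",
    "simulate_genome",
    "simulate_library",
    "make_rna_tracks",
    "write_library",
    "recovery_report",
]


@dataclass
class SimulationParams:
    """Full parameterization of a synthetic deletion library.

    Defaults describe a library like the one the analysis targets: 18% of
    operons at least 2-fold upregulated (shift drawn from (1, 2] log2, i.e.
    up to 4-fold) and 21% at least 2-fold downregulated (shift in [-3, -1),
    up to 8-fold); a protein-only deficit of up to -2.5 log2 on the +1 gene
    decaying with intergenic distance over a 30 nt lengthscale; duplicate
    TMT measurements with 0.2 log2 channel noise.
    """

    n_operons: int = 60
    operon_size_range: tuple[int, int] = (1, 6)
    gene_length_range: tuple[int, int] = (300, 1500)
    intergenic_distance_range: tuple[int, int] = (-20, 100)
    p_operon_up: float = 0.18
    p_operon_down: float = 0.21
    up_log2_range: tuple[float, float] = (1.0, 2.0)
    down_log2_range: tuple[float, float] = (-3.0, -1.0)
    p1_effect_max_log2: float = -2.5
    p1_effect_lengthscale: float = 30.0
    replicate_count: int = 2
    plex_size: int = 10
    noise_sd_log2: float = 0.2
    baseline_abundance_log_mean: float = 20.0
    baseline_abundance_log_sd: float = 2.0
    rna_depth: float = 5.0
    #: draw Poisson counts (True) or use exact per-position means (False);
    #: the deterministic mode supports exact-null checks
    rna_poisson: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.p_operon_up <= 1 and 0 <= self.p_operon_down <= 1):
            raise ValueError("effect probabilities must be in [0, 1]")
        if self.p_operon_up + self.p_operon_down > 1:
            raise ValueError("p_operon_up + p_operon_down must be <= 1")
        for name in ("operon_size_range", "gene_length_range",
                     "intergenic_distance_range", "up_log2_range", "down_log2_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} is not ordered: ({lo}, {hi})")
        if self.gene_length_range[0] < 1:
            raise ValueError("gene lengths must be positive")
        if self.p1_effect_max_log2 > 0:
            raise ValueError("p1_effect_max_log2 must be <= 0 (it is a deficit)")
        if min(self.replicate_count, self.n_operons) < 1:
            raise ValueError("need at least one operon and one replicate")
        if self.noise_sd_log2 < 0 or self.rna_depth < 0:
            raise ValueError("rates must be >= 0")


@dataclass
class GroundTruth:
    """Record of every effect drawn during simulation, keyed by mutant."""

    deletions: dict[str, str] = field(default_factory=dict)
    operon_of: dict[str, str] = field(default_factory=dict)
    operon_effect_log2: dict[str, float] = field(default_factory=dict)
    p1_gene: dict[str, str] = field(default_factory=dict)
    p1_extra_log2: dict[str, float] = field(default_factory=dict)
    p1_distance: dict[str, int] = field(default_factory=dict)
    baseline_abundance: dict[str, float] = field(default_factory=dict)
    #: per mutant, the transcriptional log2 shift applied to each downstream
    #: gene (what the RNA sees; protein additionally gets the +1 deficit)
    rna_shift_log2: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return asdict(self)


_OPERON_GAP = 500  # nt between consecutive operons; keeps them non-overlapping


def simulate_genome(
    params: SimulationParams, rng: np.random.Generator | None = None
) -> tuple[dict[str, GeneAnnotation], dict[str, OperonStructure]]:
    """Lay operons head-to-tail on one chromosome.

    Gene lengths and within-operon intergenic distances are drawn uniformly
    from their ranges (negative distances give overlapping ORFs).  Strand
    alternates by draw; for a minus-strand operon the transcription order
    runs right-to-left, so the operon's gene list is the reverse of the
    placement order.
    """
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    annotations: dict[str, GeneAnnotation] = {}
    operons: dict[str, OperonStructure] = {}
    cursor = 1
    for oi in range(params.n_operons):
        size = int(rng.integers(params.operon_size_range[0],
                                params.operon_size_range[1] + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        lengths = rng.integers(params.gene_length_range[0],
                               params.gene_length_range[1] + 1, size=size)
        gaps = rng.integers(params.intergenic_distance_range[0],
                            params.intergenic_distance_range[1] + 1, size=max(size - 1, 0))
        placed: list[GeneAnnotation] = []
        pos = cursor
        for gi in range(size):
            gene_id = f"op{oi:03d}_g{gi}"
            start = pos
            end = start + int(lengths[gi]) - 1
            placed.append(GeneAnnotation(gene_id, "chr", start, end, strand))
            if gi < size - 1:
                pos = end + int(gaps[gi]) + 1
        for g in placed:
            annotations[g.gene_id] = g
        order = placed if strand == "+" else list(reversed(placed))
        operons[f"op{oi:03d}"] = OperonStructure(
            f"op{oi:03d}", tuple(g.gene_id for g in order)
        )
        cursor = max(g.end for g in placed) + _OPERON_GAP + 1
    return annotations, operons


def _draw_operon_effect(params: SimulationParams, rng: np.random.Generator) -> float:
    u = rng.random()
    if u < params.p_operon_up:
        lo, hi = params.up_log2_range
        return float(lo) if lo == hi else float(rng.uniform(lo, hi))
    if u < params.p_operon_up + params.p_operon_down:
        lo, hi = params.down_log2_range
        return float(lo) if lo == hi else float(rng.uniform(lo, hi))
    return 0.0


def _p1_effect(params: SimulationParams, distance: int) -> float:
    # overlapping ORFs (negative distance) saturate at the maximum deficit
    return params.p1_effect_max_log2 * float(
        np.exp(-max(distance, 0) / params.p1_effect_lengthscale)
    )


def simulate_library(
    params: SimulationParams,
    condition: str = "cassette",
    annotations: dict[str, GeneAnnotation] | None = None,
    operons: dict[str, OperonStructure] | None = None,
) -> tuple[IntensityMatrix, dict[str, str], GroundTruth]:
    """Simulate the protein side of a deletion library.

    One mutant per multi-gene operon (deleted gene drawn uniformly within
    the operon) plus one control mutant per single-gene operon.  Per mutant,
    all genes downstream of the deletion receive a common transcriptional
    log2 shift; the +1 gene receives an additional protein-only deficit
    ``p1_effect_max_log2 * exp(-d / lengthscale)`` at intergenic distance d.
    Protein intensities are ``baseline * 2**effect * 2**N(0, noise_sd)`` per
    replicate, and the deleted gene's own protein is absent from its mutant.
    Samples are packed into plexes round-robin by mutant index.

    ``condition="excised"`` simulates removal of the resistance cassette and
    its promoter: upregulating shifts are zeroed while downregulation and
    the +1 deficit persist.

    Returns ``(intensity_matrix, deletions, ground_truth)``.  RNA tracks for
    the same library come from :func:`make_rna_tracks` with the same truth.
    """
    if params.plex_size < 3:
        raise ValueError("plex_size must be >= 3 for a meaningful median reference")
    rng = np.random.default_rng(params.seed)
    if annotations is None or operons is None:
        annotations, operons = simulate_genome(params, rng)
    truth = GroundTruth()
    gene_ids = list(annotations)
    baselines = 2.0 ** rng.normal(
        params.baseline_abundance_log_mean,
        params.baseline_abundance_log_sd,
        size=len(gene_ids),
    )
    truth.baseline_abundance = dict(zip(gene_ids, map(float, baselines)))

    mutants: list[str] = []
    effect_log2: dict[str, dict[str, float]] = {}  # mutant -> gene -> protein log2 shift
    rna_shift: dict[str, dict[str, float]] = {}    # mutant -> gene -> RNA log2 shift
    for operon in operons.values():
        deleted = operon.genes[int(rng.integers(len(operon.genes)))]
        mutant_id = f"d_{deleted}"
        mutants.append(mutant_id)
        truth.deletions[mutant_id] = deleted
        truth.operon_of[mutant_id] = operon.operon_id
        op_effect = _draw_operon_effect(params, rng)
        if condition == "excised" and op_effect > 0:
            op_effect = 0.0
        truth.operon_effect_log2[mutant_id] = op_effect
        shifts: dict[str, float] = {}
        rshifts: dict[str, float] = {}
        for rp in relative_positions(operon, deleted, mutant_id):
            if rp.position > 0:
                shifts[rp.gene_id] = op_effect
                rshifts[rp.gene_id] = op_effect
            if rp.position == 1:
                d = intergenic_distance(
                    annotations[deleted], annotations[rp.gene_id]
                )
                extra = _p1_effect(params, d)
                shifts[rp.gene_id] = shifts.get(rp.gene_id, 0.0) + extra
                truth.p1_gene[mutant_id] = rp.gene_id
                truth.p1_extra_log2[mutant_id] = extra
                truth.p1_distance[mutant_id] = int(d)
        effect_log2[mutant_id] = shifts
        rna_shift[mutant_id] = rshifts
        truth.rna_shift_log2[mutant_id] = rshifts

    # pack samples: one plex set per replicate, mutants dealt round-robin by index
    sample_rows = []
    columns = {}
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    n_plexes = -(-len(mutants) // params.plex_size)
    for rep in range(1, params.replicate_count + 1):
        for mi, mutant_id in enumerate(mutants):
            sample_id = f"{mutant_id}_r{rep}"
            plex_id = f"plex{rep}_{mi % n_plexes}"
            sample_rows.append((sample_id, mutant_id, rep, plex_id, condition))
            shifts = effect_log2[mutant_id]
            deleted = truth.deletions[mutant_id]
            noise = rng.normal(0.0, params.noise_sd_log2, size=len(gene_ids))
            vals = baselines * 2.0 ** (
                np.array([shifts.get(g, 0.0) for g in gene_ids]) + noise
            )
            vals[gene_index[deleted]] = np.nan  # the deleted gene is gone
            columns[sample_id] = vals
    values = pd.DataFrame(columns, index=gene_ids)
    samples = pd.DataFrame(
        sample_rows,
        columns=["sample_id", "mutant_id", "replicate", "plex_id", "condition"],
    ).set_index("sample_id")
    matrix = IntensityMatrix(values=values, samples=samples)
    return matrix, dict(truth.deletions), truth


def make_rna_tracks(
    params: SimulationParams,
    annotations: dict[str, GeneAnnotation],
    truth: GroundTruth,
) -> dict[str, tuple[CoverageTrack, CoverageTrack]]:
    """Strand-separated Poisson coverage tracks for every mutant.

    Per-position counts within each gene body are Poisson with mean
    ``rna_depth * 2**shift`` where the shift is the mutant's operon-wide
    transcriptional effect on that gene (downstream genes only).  The +1
    protein-only deficit deliberately leaves the RNA untouched.  The deleted
    gene's locus is still transcribed in its own mutant (the resistance
    cassette replacing the ORF is expressed), so its region keeps baseline
    coverage; this also keeps overlapping neighbors' windows comparable
    across mutants.  Positions outside genes are uncovered.  Seeding is
    derived per mutant from ``params.seed`` so tracks are reproducible
    independently of generation order.
    """
    genome_end = max(g.end for g in annotations.values())
    tracks: dict[str, tuple[CoverageTrack, CoverageTrack]] = {}
    for mi, (mutant_id, deleted) in enumerate(sorted(truth.deletions.items())):
        rng = np.random.default_rng((params.seed, 7, mi))
        shifts = truth.rna_shift_log2.get(mutant_id, {})
        fwd = np.zeros(genome_end)
        rev = np.zeros(genome_end)
        for g in annotations.values():
            mean = params.rna_depth * 2.0 ** shifts.get(g.gene_id, 0.0)
            if params.rna_poisson:
                counts = rng.poisson(mean, size=g.length)
            else:
                counts = np.full(g.length, mean)
            target = fwd if g.strand == "+" else rev
            target[g.start - 1:g.end] += counts
        tracks[mutant_id] = (
            CoverageTrack("chr", fwd, start=1),
            CoverageTrack("chr", rev, start=1),
        )
    return tracks


def write_library(
    outdir: str | Path,
    params: SimulationParams,
    condition: str = "cassette",
    write_rna: bool = True,
) -> Path:
    """Simulate a library and write every pipeline input format to ``outdir``.

    Emits: ``annotations.tsv``, ``operons.tsv``, ``intensities.tsv``,
    ``samples.tsv``, ``deletions.tsv``, per-mutant WIG pairs with a
    ``wig_samples.tsv`` sheet, and ``ground_truth.json``.
    """
    import json

    from .annotations import write_annotations, write_operons

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(params.seed)
    annotations, operons = simulate_genome(params, rng)
    matrix, deletions, truth = simulate_library(
        params, condition=condition, annotations=annotations, operons=operons
    )
    write_annotations(annotations, outdir / "annotations.tsv")
    write_operons(operons, outdir / "operons.tsv")
    matrix.values.to_csv(outdir / "intensities.tsv", sep="\t",
                         index_label="gene_id")
    matrix.samples.to_csv(outdir / "samples.tsv", sep="\t",
                          index_label="sample_id")
    with open(outdir / "deletions.tsv", "w") as fh:
        fh.write("mutant_id\tgene_id\n")
        for m, g in deletions.items():
            fh.write(f"{m}\t{g}\n")
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(truth.to_json_dict(), fh, indent=1, sort_keys=True)
    if write_rna:
        tracks = make_rna_tracks(params, annotations, truth)
        wigdir = outdir / "wig"
        wigdir.mkdir(exist_ok=True)
        with open(outdir / "wig_samples.tsv", "w") as fh:
            fh.write("mutant_id\tfwd_path\trev_path\n")
            for mutant_id, (fwd, rev) in tracks.items():
                fp = wigdir / f"{mutant_id}_fwd.wig"
                rp = wigdir / f"{mutant_id}_rev.wig"
                write_wig(fwd, fp)
                write_wig(rev, rp)
                fh.write(f"{mutant_id}\t{fp}\t{rp}\n")
    return outdir


def recovery_report(
    truth: GroundTruth,
    classifications: pd.DataFrame,
    positioned: pd.DataFrame | None = None,
    threshold_log2: float = 1.0,
) -> pd.DataFrame:
    """Compare pipeline estimates against the simulation truth.

    Rows: fraction of operons with a >= 2-fold (|log2| > threshold) up or
    down transcriptional shift, and — when a corrected positioned table is
    given — the median +1 linear fold change.  True fractions are computed
    over the mutants the pipeline could evaluate, so the comparison is
    like-for-like.
    """
    from .polar import summarize_classes

    ev = classifications[classifications["class"] != "not_evaluable"]
    effects = pd.Series({
        m: truth.operon_effect_log2[m]
        for m in ev["mutant_id"].unique()
        if m in truth.operon_effect_log2
    })
    true_up = float((effects > threshold_log2).mean())
    true_down = float((effects < -threshold_log2).mean())
    class_summary = summarize_classes(classifications)
    rows = [
        ("fraction_up", true_up, class_summary["fraction_up"]),
        ("fraction_down", true_down, class_summary["fraction_down"]),
    ]
    if positioned is not None:
        p1 = positioned[(positioned["position"] == 1)
                        & (positioned["datatype"] == "protein")]
        est = p1.dropna(subset=["corrected_log2fc"])
        if len(est):
            est_fc = float(2.0 ** est["corrected_log2fc"].median())
            mutants = est["mutant_id"].unique()
            true_fc = float(2.0 ** np.median(
                [truth.p1_extra_log2[m] for m in mutants if m in truth.p1_extra_log2]
            ))
            rows.append(("median_p1_linear_fc", true_fc, est_fc))
    out = pd.DataFrame(rows, columns=["parameter", "true", "estimated"])
    out["error"] = out["estimated"] - out["true"]
    return out
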