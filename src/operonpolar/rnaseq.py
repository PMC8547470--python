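"""Per-gene transcript densities from strand-separated WIG coverage tracks.

Each mutant's RNA-seq signal arrives as two UCSC WIG tracks (forward and
reverse strand coverage).  The tracks are summed positionwise, counts within
each gene body are summed and divided by gene length, low-coverage
(gene, mutant) pairs are dropped, and the surviving densities are turned into
log2 fold changes against the across-mutant median — the same median-reference
logic as the protein side.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotations import GeneAnnotation

logger = logging.getLogger(__name__)

__all__ = [
    "CoverageTrack",
    "read_wig",
    "write_wig",
    "sum_strand_tracks",
    "gene_density",
    "gene_density_table",
    "filter_low_density",
    "rna_fold_changes",
]


@dataclass
class CoverageTrack:
    """Dense per-position coverage: ``values[i]`` is the count at ``start + i`` (1-based)."""

    chrom: str
    values: np.ndarray
    start: int = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.start < 1:
            raise ValueError("positions are 1-based; start must be >= 1")
        if (self.values < 0).any():
            raise ValueError("coverage counts must be non-negative")

    @property
    def end(self) -> int:
        """Last covered position (inclusive); ``start - 1`` for an empty track."""
        return self.start + len(self.values) - 1

    def count_at(self, pos: int) -> float:
        """Count at a 1-based position; positions outside the track are 0."""
        i = pos - self.start
        if 0 <= i < len(self.values):
            return float(self.values[i])
        return 0.0

    def window_sum(self, start: int, end: int) -> float:
        """Sum of counts over the closed interval [start, end]."""
        lo = max(start, self.start) - self.start
        hi = min(end, self.end) - self.start
        if hi < lo:
            return 0.0
        return float(self.values[lo:hi + 1].sum())


def read_wig(path) -> CoverageTrack:
    """Parse a UCSC WIG file (fixedStep and/or variableStep blocks).

    Span/step semantics follow the UCSC specification: a value in a block
    with ``span=n`` covers n consecutive positions.  Positions never written
    are 0.  Mixing chromosomes in one file is not supported.
    """
    counts: dict[int, float] = {}
    chrom: str | None = None
    mode: str | None = None
    pos = step = span = 1
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith(("fixedStep", "variableStep")):
                fields = dict(
                    kv.split("=", 1) for kv in line.split()[1:] if "=" in kv
                )
                if "chrom" not in fields:
                    raise ValueError(f"{path}:{lineno}: block declaration lacks chrom=")
                if chrom is not None and fields["chrom"] != chrom:
                    raise ValueError(
                        f"{path}:{lineno}: multiple chromosomes in one WIG file"
                    )
                chrom = fields["chrom"]
                span = int(fields.get("span", 1))
                if line.startswith("fixedStep"):
                    mode = "fixed"
                    if "start" not in fields:
                        raise ValueError(f"{path}:{lineno}: fixedStep lacks start=")
                    pos = int(fields["start"])
                    step = int(fields.get("step", 1))
                else:
                    mode = "variable"
                continue
            if mode is None:
                raise ValueError(f"{path}:{lineno}: data before any block declaration")
            parts = line.split()
            try:
                if mode == "fixed":
                    if len(parts) != 1:
                        raise ValueError("fixedStep lines carry one value")
                    value = float(parts[0])
                    here = pos
                    pos += step
                else:
                    if len(parts) != 2:
                        raise ValueError("variableStep lines carry position and value")
                    here, value = int(parts[0]), float(parts[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            for p in range(here, here + span):
                counts[p] = counts.get(p, 0.0) + value
    if not counts:
        return CoverageTrack(chrom=chrom or "", values=np.zeros(0), start=1)
    lo, hi = min(counts), max(counts)
    values = np.zeros(hi - lo + 1)
    for p, v in counts.items():
        values[p - lo] = v
    return CoverageTrack(chrom=chrom or "", values=values, start=lo)


def write_wig(track: CoverageTrack, path, name: str | None = None) -> None:
    """Write a track as fixedStep WIG, one block per contiguous nonzero run."""
    with open(path, "w") as fh:
        if name:
            fh.write(f'track type=wiggle_0 name="{name}"\n')
        vals = track.values
        nonzero = np.flatnonzero(vals)
        if len(nonzero) == 0:
            return
        # split into runs of consecutive indices
        breaks = np.flatnonzero(np.diff(nonzero) > 1)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [len(nonzero) - 1]])
        for s, e in zip(starts, ends):
            i0, i1 = nonzero[s], nonzero[e]
            fh.write(f"fixedStep chrom={track.chrom} start={track.start + i0} step=1\n")
            block = vals[i0:i1 + 1]
            fh.write("\n".join(format(v, "g") for v in block))
            fh.write("\n")


def sum_strand_tracks(fwd: CoverageTrack, rev: CoverageTrack) -> CoverageTrack:
    """Positionwise sum of forward and reverse strand coverage."""
    if fwd.chrom and rev.chrom and fwd.chrom != rev.chrom:
        raise ValueError(
            f"chromosome mismatch: {fwd.chrom!r} vs {rev.chrom!r}"
        )
    if len(fwd.values) == 0:
        return CoverageTrack(rev.chrom or fwd.chrom, rev.values.copy(), rev.start)
    if len(rev.values) == 0:
        return CoverageTrack(fwd.chrom or rev.chrom, fwd.values.copy(), fwd.start)
    lo = min(fwd.start, rev.start)
    hi = max(fwd.end, rev.end)
    values = np.zeros(hi - lo + 1)
    values[fwd.start - lo:fwd.end - lo + 1] += fwd.values
    values[rev.start - lo:rev.end - lo + 1] += rev.values
    return CoverageTrack(fwd.chrom or rev.chrom, values, lo)


def gene_density(track: CoverageTrack, gene: GeneAnnotation) -> float:
    """Summed counts over the gene body divided by gene length.

    Strand is ignored: the track is expected to be the strand-summed
    coverage.  Zero coverage gives 0.
    """
    return track.window_sum(gene.start, gene.end) / gene.length


def gene_density_table(tracks: dict[str, CoverageTrack],
                       annotations: dict[str, GeneAnnotation]) -> pd.DataFrame:
    """Per-(gene, mutant) densities from per-mutant strand-summed tracks.

    Equivalent to calling :func:`gene_density` per (gene, mutant) but uses a
    cumulative sum per track so whole-library quantification stays fast.
    """
    genes = list(annotations.values())
    gene_ids = [g.gene_id for g in genes]
    starts = np.array([g.start for g in genes])
    ends = np.array([g.end for g in genes])
    lengths = ends - starts + 1
    frames = []
    for mutant_id, track in tracks.items():
        cs = np.concatenate([[0.0], np.cumsum(track.values)])
        lo = np.clip(starts - track.start, 0, len(track.values))
        hi = np.clip(ends - track.start + 1, 0, len(track.values))
        sums = cs[np.maximum(hi, lo)] - cs[lo]
        frames.append(pd.DataFrame({
            "gene_id": gene_ids,
            "mutant_id": mutant_id,
            "density": sums / lengths,
        }))
    if not frames:
        return pd.DataFrame(columns=["gene_id", "mutant_id", "density"])
    return pd.concat(frames, ignore_index=True)


def filter_low_density(table: pd.DataFrame, threshold: float = 1.0) -> pd.DataFrame:
    """Drop (gene, mutant) rows with density strictly below the threshold.

    The cut is per (gene, mutant), not per gene globally: a gene can survive
    in well-covered mutants while being dropped where coverage is poor.
    """
    return table[table["density"] >= threshold].reset_index(drop=True)


def rna_fold_changes(table: pd.DataFrame, condition: str = "cassette") -> pd.DataFrame:
    """Log2 fold change of each mutant's density against the across-mutant median.

    The median runs over the mutants with a retained row for that gene (the
    low-density filter is applied first); genes retained in fewer than 2
    mutants are skipped with a warning.  Returns a fold-change table with
    ``datatype="rna"`` and ``n_replicates=1``.
    """
    if table["mutant_id"].nunique() < 3:
        raise ValueError("need densities from at least 3 mutants for a median reference")
    frames = []
    for gene_id, grp in table.groupby("gene_id", sort=False):
        if len(grp) < 2:
            logger.warning(
                "gene %s retained in only %d mutant(s); skipped", gene_id, len(grp)
            )
            continue
        med = grp["density"].median()
        if med <= 0:
            logger.warning("gene %s has non-positive median density; skipped", gene_id)
            continue
        sub = grp.copy()
        sub["log2fc"] = np.log2(sub["density"] / med)
        frames.append(sub)
    if not frames:
        return pd.DataFrame(
            columns=["gene_id", "mutant_id", "condition", "datatype", "log2fc", "n_replicates"]
        )
    out = pd.concat(frames, ignore_index=True)
    out["condition"] = condition
    out["datatype"] = "rna"
    out["n_replicates"] = 1
    return out[["gene_id", "mutant_id", "condition", "datatype", "log2fc", "n_replicates"]]
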