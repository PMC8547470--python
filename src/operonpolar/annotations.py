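"""Gene annotations, operon structures, relative positions and intergenic distances.

Coordinates are 1-based inclusive throughout (GenBank convention).  Operon
tables list genes in transcription order (5'->3' of the transcript), as
EcoCyc-style exports do; that order, not the strand, defines upstream and
downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

logger = logging.getLogger(__name__)

__all__ = [
    "GeneAnnotation",
    "OperonStructure",
    "RelativePosition",
    "load_annotations",
    "load_operons",
    "write_annotations",
    "write_operons",
    "relative_positions",
    "intergenic_distance",
    "gene_to_operon_map",
    "check_operon_strand_consistency",
]


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene's genomic location: 1-based inclusive [start, end] and strand."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(
                f"gene {self.gene_id!r}: start must be >= 1, got {self.start}"
            )
        if self.end < self.start:
            raise ValueError(
                f"gene {self.gene_id!r}: end ({self.end}) < start ({self.start})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"gene {self.gene_id!r}: strand must be '+' or '-', got {self.strand!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class OperonStructure:
    """An operon as an ordered tuple of gene ids in transcription direction."""

    operon_id: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.genes) == 0:
            raise ValueError(f"operon {self.operon_id!r} has no genes")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"operon {self.operon_id!r} lists a gene more than once")


@dataclass(frozen=True)
class RelativePosition:
    """Operon-relative position of a gene in a deletion mutant (0 = deleted gene)."""

    gene_id: str
    mutant_id: str
    position: int


def _parse_tsv_annotations(path: Path) -> dict[str, GeneAnnotation]:
    genes: dict[str, GeneAnnotation] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0].lower() in ("gene_id", "gene"):
                continue  # header
            if len(fields) != 5:
                raise ValueError(
                    f"{path}:{lineno}: expected 5 tab-separated fields "
                    f"(gene_id, chrom, start, end, strand), got {len(fields)}"
                )
            gene_id, chrom, start_s, end_s, strand = fields
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            if gene_id in genes:
                raise ValueError(f"{path}:{lineno}: duplicate gene_id {gene_id!r}")
            try:
                genes[gene_id] = GeneAnnotation(gene_id, chrom, start, end, strand)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return genes


def _parse_gff_annotations(path: Path) -> dict[str, GeneAnnotation]:
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        merge_strategy="error",
        keep_order=True,
    )
    genes: dict[str, GeneAnnotation] = {}
    for featuretype in ("gene", "CDS"):
        for feat in db.features_of_type(featuretype):
            gene_id = feat.attributes.get("ID", [feat.id])[0]
            if gene_id in genes:
                if featuretype == "CDS":
                    continue  # gene feature already seen; CDS of same ID is redundant
                raise ValueError(f"{path}: duplicate gene id {gene_id!r}")
            genes[gene_id] = GeneAnnotation(
                gene_id, feat.seqid, feat.start, feat.end, feat.strand
            )
    return genes


def load_annotations(path: str | Path, format: str | None = None) -> dict[str, GeneAnnotation]:
    """Load gene annotations from GFF3 or 5-column TSV.

    Parameters
    ----------
    path
        Annotation file.  TSV columns: gene_id, chrom, start, end, strand
        (1-based inclusive coordinates).  GFF3: features of type ``gene`` or
        ``CDS``; the ``ID`` attribute names the gene.
    format
        ``"gff"`` or ``"tsv"``; inferred from the suffix when omitted.

    Returns
    -------
    dict mapping gene_id to :class:`GeneAnnotation`.  Duplicate ids are an
    error.
    """
    path = Path(path)
    if format is None:
        format = "gff" if path.suffix.lower() in (".gff", ".gff3") else "tsv"
    if format == "gff":
        return _parse_gff_annotations(path)
    if format == "tsv":
        return _parse_tsv_annotations(path)
    raise ValueError(f"unknown annotation format {format!r}")


def load_operons(path: str | Path) -> dict[str, OperonStructure]:
    """Load operon structures from a 2-column TSV (operon_id, comma-separated gene ids).

    Gene order in the file is transcription order.  A gene appearing in two
    operons is an error; gene ids are not required to exist in any annotation
    set at load time (checked lazily when joining).
    """
    path = Path(path)
    operons: dict[str, OperonStructure] = {}
    seen_genes: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0].lower() in ("operon_id", "operon"):
                continue
            if len(fields) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 tab-separated fields, got {len(fields)}"
                )
            operon_id, genes_s = fields
            genes = tuple(g.strip() for g in genes_s.split(",") if g.strip())
            if operon_id in operons:
                raise ValueError(f"{path}:{lineno}: duplicate operon_id {operon_id!r}")
            try:
                op = OperonStructure(operon_id, genes)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            for g in genes:
                if g in seen_genes:
                    raise ValueError(
                        f"{path}:{lineno}: gene {g!r} already in operon "
                        f"{seen_genes[g]!r}; a gene belongs to at most one operon"
                    )
                seen_genes[g] = operon_id
            operons[operon_id] = op
    return operons


def write_annotations(genes: Mapping[str, GeneAnnotation] | Iterable[GeneAnnotation],
                      path: str | Path) -> None:
    """Write annotations as the 5-column TSV that :func:`load_annotations` reads."""
    if isinstance(genes, Mapping):
        genes = genes.values()
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstart\tend\tstrand\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.start}\t{g.end}\t{g.strand}\n")


def write_operons(operons: Mapping[str, OperonStructure] | Iterable[OperonStructure],
                  path: str | Path) -> None:
    """Write operons as the 2-column TSV that :func:`load_operons` reads."""
    if isinstance(operons, Mapping):
        operons = operons.values()
    with open(path, "w") as fh:
        fh.write("operon_id\tgenes\n")
        for op in operons:
            fh.write(f"{op.operon_id}\t{','.join(op.genes)}\n")


def gene_to_operon_map(operons: Mapping[str, OperonStructure]) -> dict[str, str]:
    """Invert a set of operons into a gene_id -> operon_id map."""
    out: dict[str, str] = {}
    for op in operons.values():
        for g in op.genes:
            if g in out:
                raise ValueError(
                    f"gene {g!r} appears in operons {out[g]!r} and {op.operon_id!r}"
                )
            out[g] = op.operon_id
    return out


def relative_positions(operon: OperonStructure, deleted_gene: str,
                       mutant_id: str | None = None) -> list[RelativePosition]:
    """Positions of every operon gene relative to the deleted gene.

    Position 0 is the deleted gene itself; downstream (later in transcription
    order) is positive.  The positions form a contiguous integer range.
    """
    if deleted_gene not in operon.genes:
        raise ValueError(
            f"deleted gene {deleted_gene!r} is not in operon {operon.operon_id!r}"
        )
    mid = mutant_id if mutant_id is not None else deleted_gene
    i0 = operon.genes.index(deleted_gene)
    return [
        RelativePosition(gene_id=g, mutant_id=mid, position=i - i0)
        for i, g in enumerate(operon.genes)
    ]


def intergenic_distance(deleted: GeneAnnotation, downstream: GeneAnnotation) -> int:
    """Nucleotides between the deleted gene's stop codon and the downstream start codon.

    Abutting ORFs give 0; overlapping coding sequences give a negative value.
    On the + strand ``d = downstream.start - deleted.end - 1``; on the -
    strand the mirror image.  Distances are computed on wild-type coordinates
    (the resistance cassette preserves the last 21 nt of the deleted gene, so
    the wild-type stop position is the relevant anchor).
    """
    if deleted.strand != downstream.strand:
        raise ValueError(
            f"genes {deleted.gene_id!r} and {downstream.gene_id!r} are on "
            "different strands; intergenic distance is defined within one operon"
        )
    if deleted.strand == "+":
        return downstream.start - deleted.end - 1
    return deleted.start - downstream.end - 1


def check_operon_strand_consistency(
    operons: Mapping[str, OperonStructure],
    annotations: Mapping[str, GeneAnnotation],
) -> list[str]:
    """Warn when an operon's listed order contradicts its genes' strand.

    For + strand operons, coordinates should increase along the listed order;
    for - strand, decrease.  The listed order wins in either case (EcoCyc-style
    tables are already in transcription order); mismatches are reported as
    warning strings and logged.
    """
    warnings: list[str] = []
    for op in operons.values():
        annotated = [annotations[g] for g in op.genes if g in annotations]
        if len(annotated) < 2:
            continue
        strands = {a.strand for a in annotated}
        if len(strands) > 1:
            msg = f"operon {op.operon_id!r}: genes on both strands"
            warnings.append(msg)
            logger.warning(msg)
            continue
        starts = [a.start for a in annotated]
        increasing = all(b > a for a, b in zip(starts, starts[1:]))
        decreasing = all(b < a for a, b in zip(starts, starts[1:]))
        ok = increasing if strands == {"+"} else decreasing
        if not ok and (increasing or decreasing):
            msg = (
                f"operon {op.operon_id!r}: listed order contradicts strand "
                f"{strands.pop()!r}; keeping the listed order"
            )
            warnings.append(msg)
            logger.warning(msg)
        elif not (increasing or decreasing):
            msg = f"operon {op.operon_id!r}: gene coordinates are not monotone"
            warnings.append(msg)
            logger.warning(msg)
    return warnings
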