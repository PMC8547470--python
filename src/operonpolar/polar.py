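"""Operon-relative positioning, median correction, classification and tests.

This is the analytical core: fold-change tables (protein or RNA) are joined
with operon structures to give every measured operon mate a signed position
relative to the deleted gene (downstream positive, the deleted gene itself
excluded), the per-side median is subtracted to isolate gene-specific
deviations from the operon-wide transcriptional shift, operon-level effects
are classified against a 2-fold threshold, and the position +1 gene — the one
directly downstream of the deletion — is tested for an additional deficit
with a Wilcoxon rank-sum test and correlated with its intergenic distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .annotations import (
    GeneAnnotation,
    OperonStructure,
    check_operon_strand_consistency,
    gene_to_operon_map,
    intergenic_distance,
    relative_positions,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TestResult",
    "position_fold_changes",
    "operon_median_correction",
    "classify_operon_effects",
    "summarize_classes",
    "downstream_gene_test",
    "distance_correlation",
    "concordance",
]

POSITIONED_COLUMNS = [
    "gene_id", "mutant_id", "condition", "datatype", "operon_id",
    "position", "log2fc", "corrected_log2fc", "intergenic_distance",
]


@dataclass
class TestResult:
    """Outcome of a two-sample or correlation test."""

    statistic: float
    p_value: float
    n1: int
    n2: int
    method: str
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of [0, 1]: {self.p_value}")

    def to_dict(self) -> dict:
        out = {
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n1": self.n1,
            "n2": self.n2,
            "method": self.method,
        }
        out.update(self.extra)
        return out


def position_fold_changes(
    fc: pd.DataFrame,
    operons: Mapping[str, OperonStructure],
    deletions: Mapping[str, str],
    annotations: Mapping[str, GeneAnnotation],
    exclude_mutants: set[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Annotate fold-change rows with operon-relative positions.

    For every mutant whose deleted gene sits in a multi-gene operon, each
    measured operon mate gets a signed position (downstream positive); the
    deleted gene's own row (position 0) is dropped from the positioned table.
    The +1 gene additionally gets the intergenic distance from the deleted
    gene's stop codon to its start codon, from wild-type coordinates.

    Mutants whose gene is not in an operon with others are routed to the
    second returned table unchanged — they serve as the negative control set.
    Operon genes absent from the annotation set keep their position but have
    no intergenic distance; an optional ``exclude_mutants`` set removes
    mutants whose deleted gene may regulate its own operon.

    Returns ``(positioned, not_in_operon)``.
    """
    exclude_mutants = exclude_mutants or set()
    check_operon_strand_consistency(operons, annotations)
    g2o = gene_to_operon_map(operons)

    positioned_frames = []
    control_frames = []
    for mutant_id, grp in fc.groupby("mutant_id", sort=False):
        if mutant_id in exclude_mutants:
            continue
        if mutant_id not in deletions:
            raise ValueError(f"mutant {mutant_id!r} has no deletion entry")
        deleted = deletions[mutant_id]
        if deleted not in annotations:
            raise ValueError(
                f"mutant {mutant_id!r}: deleted gene {deleted!r} not in annotation set"
            )
        operon_id = g2o.get(deleted)
        operon = operons[operon_id] if operon_id is not None else None
        if operon is None or len(operon.genes) < 2:
            control_frames.append(grp)
            continue
        pos = {
            rp.gene_id: rp.position
            for rp in relative_positions(operon, deleted, mutant_id)
        }
        sub = grp[grp["gene_id"].isin(pos)].copy()
        sub["position"] = sub["gene_id"].map(pos)
        sub = sub[sub["position"] != 0]
        sub["operon_id"] = operon_id
        sub["intergenic_distance"] = np.nan
        p1 = [g for g, p in pos.items() if p == 1]
        if p1:
            p1_gene = p1[0]
            if p1_gene in annotations:
                try:
                    d = intergenic_distance(annotations[deleted], annotations[p1_gene])
                    sub.loc[sub["position"] == 1, "intergenic_distance"] = d
                except ValueError as exc:
                    logger.warning("mutant %s: %s", mutant_id, exc)
            else:
                logger.warning(
                    "mutant %s: +1 gene %s not annotated; no intergenic distance",
                    mutant_id, p1_gene,
                )
        positioned_frames.append(sub)

    empty = pd.DataFrame(columns=list(fc.columns) + [
        "position", "operon_id", "intergenic_distance"])
    positioned = (
        pd.concat(positioned_frames, ignore_index=True) if positioned_frames else empty
    )
    if not positioned.empty:
        positioned["corrected_log2fc"] = np.nan
    else:
        positioned["corrected_log2fc"] = pd.Series(dtype=float)
    control = (
        pd.concat(control_frames, ignore_index=True)
        if control_frames
        else pd.DataFrame(columns=fc.columns)
    )
    return positioned, control


def operon_median_correction(
    table: pd.DataFrame,
    min_genes: int = 2,
    include_p1_in_downstream_median: bool = True,
) -> pd.DataFrame:
    """Subtract the per-side median fold change within each mutant's operon.

    For each (mutant, condition, datatype): the median log2 fold change of
    all upstream genes is subtracted from every upstream gene, and likewise
    downstream.  The downstream median includes the +1 gene by default;
    ``include_p1_in_downstream_median=False`` computes it over positions
    >= +2 only (while still correcting the +1 gene), which avoids absorbing
    the +1 gene's own deficit into its reference.

    Corrected values are emitted only when at least ``min_genes`` genes are
    quantified on that side; elsewhere ``corrected_log2fc`` stays NaN.  The
    per-side median of emitted corrected values is exactly 0 whenever the
    median set equals the corrected set (the default).
    """
    out = table.copy()
    out["corrected_log2fc"] = np.nan
    for _, idx in out.groupby(
        ["mutant_id", "condition", "datatype"], sort=False
    ).groups.items():
        sub = out.loc[idx]
        up = sub.index[sub["position"] < 0]
        down = sub.index[sub["position"] > 0]
        if len(up) >= min_genes:
            med = sub.loc[up, "log2fc"].median()
            out.loc[up, "corrected_log2fc"] = sub.loc[up, "log2fc"] - med
        if len(down) >= min_genes:
            if include_p1_in_downstream_median:
                ref = down
            else:
                ref = sub.index[sub["position"] >= 2]
            if len(ref) > 0:
                med = sub.loc[ref, "log2fc"].median()
                out.loc[down, "corrected_log2fc"] = sub.loc[down, "log2fc"] - med
    return out


def classify_operon_effects(
    table: pd.DataFrame, threshold_log2: float = 1.0
) -> pd.DataFrame:
    """Classify each mutant's operon-level transcriptional effect.

    The median uncorrected log2 fold change is taken over downstream genes at
    positions >= +2 — the gene directly downstream is excluded because it
    carries an additional gene-specific effect.  Class is ``up`` if the
    median exceeds ``threshold_log2`` (strictly), ``down`` if below its
    negative, ``none`` otherwise and ``not_evaluable`` when no such genes
    were measured.
    """
    rows = []
    for (mutant_id, condition, datatype), grp in table.groupby(
        ["mutant_id", "condition", "datatype"], sort=False
    ):
        vals = grp.loc[grp["position"] >= 2, "log2fc"]
        n = len(vals)
        if n == 0:
            med, cls = np.nan, "not_evaluable"
        else:
            med = float(vals.median())
            if med > threshold_log2:
                cls = "up"
            elif med < -threshold_log2:
                cls = "down"
            else:
                cls = "none"
            if abs(abs(med) - threshold_log2) < 1e-12:
                logger.info(
                    "mutant %s: median %.3f exactly at threshold; classified %s",
                    mutant_id, med, cls,
                )
        rows.append((mutant_id, condition, datatype, med, cls, n))
    return pd.DataFrame(
        rows,
        columns=["mutant_id", "condition", "datatype",
                 "median_downstream_excl_p1", "class", "n_downstream_excl_p1"],
    )


def summarize_classes(summary: pd.DataFrame) -> dict:
    """Fractions of evaluable mutants classified up/down."""
    ev = summary[summary["class"] != "not_evaluable"]
    n = len(ev)
    n_up = int((ev["class"] == "up").sum())
    n_down = int((ev["class"] == "down").sum())
    return {
        "n_evaluable": n,
        "n_up": n_up,
        "n_down": n_down,
        "fraction_up": n_up / n if n else np.nan,
        "fraction_down": n_down / n if n else np.nan,
    }


def _rank_sum(x: np.ndarray, y: np.ndarray, alternative: str) -> TestResult:
    """Wilcoxon rank-sum via the Mann-Whitney U statistic.

    Exact null enumeration when n1 + n2 <= 12 and the data are tie-free;
    otherwise the normal approximation with tie and continuity correction.
    """
    n1, n2 = len(x), len(y)
    ties = len(np.unique(np.concatenate([x, y]))) < n1 + n2
    if n1 + n2 <= 12 and not ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method,
                             use_continuity=True)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n1=n1,
        n2=n2,
        method=f"wilcoxon_rank_sum_{method}",
    )


def downstream_gene_test(
    table: pd.DataFrame,
    datatype: str = "protein",
    use_corrected: bool = False,
    method: str = "rank_sum",
    alternative: str = "two-sided",
) -> TestResult:
    """Test the gene directly downstream of the deletion for an extra deficit.

    ``rank_sum`` (default) compares the position +1 values (one per mutant)
    against the pooled values at other downstream positions (>= +2) with a
    two-sample Wilcoxon rank-sum test.  ``signed_rank`` instead tests the +1
    values against zero with a one-sample Wilcoxon signed-rank test.  Values
    are uncorrected or median-corrected per ``use_corrected``; corrected mode
    drops rows where no correction was emitted.

    The result's ``extra`` carries ``median_linear_fc_p1``, the median linear
    fold change of the +1 gene (e.g. 0.62 means a 1.6-fold deficit).
    """
    col = "corrected_log2fc" if use_corrected else "log2fc"
    sub = table[table["datatype"] == datatype].dropna(subset=[col])
    p1 = sub.loc[sub["position"] == 1, col].to_numpy(dtype=float)
    rest = sub.loc[sub["position"] >= 2, col].to_numpy(dtype=float)
    if len(p1) == 0:
        raise ValueError("no values at position +1")
    median_fc = float(2.0 ** np.median(p1))
    if method == "rank_sum":
        if len(rest) == 0:
            raise ValueError("no values at positions >= +2 to compare against")
        result = _rank_sum(p1, rest, alternative)
    elif method == "signed_rank":
        res = stats.wilcoxon(p1, alternative=alternative)
        result = TestResult(
            statistic=float(res.statistic),
            p_value=float(res.pvalue),
            n1=len(p1),
            n2=0,
            method="wilcoxon_signed_rank",
        )
    else:
        raise ValueError(f"unknown test method {method!r}")
    result.extra["median_linear_fc_p1"] = median_fc
    return result


def distance_correlation(table: pd.DataFrame, datatype: str = "protein") -> TestResult:
    """Spearman correlation of the corrected +1 deficit with intergenic distance.

    Uses position +1 rows that carry both a median-corrected fold change and
    an intergenic distance.  A positive rho means genes closer to the deleted
    gene's stop codon are downregulated more.  Ties get average ranks; the
    p-value uses the t approximation.
    """
    sub = table[(table["datatype"] == datatype) & (table["position"] == 1)]
    sub = sub.dropna(subset=["corrected_log2fc", "intergenic_distance"])
    n = len(sub)
    if n < 4:
        raise ValueError(f"need at least 4 (+1, distance) pairs, got {n}")
    x = sub["corrected_log2fc"].to_numpy(dtype=float)
    y = sub["intergenic_distance"].to_numpy(dtype=float)
    if len(np.unique(x)) < 2 or len(np.unique(y)) < 2:
        raise ValueError("constant input; rank correlation undefined")
    rho, p = stats.spearmanr(x, y)
    return TestResult(
        statistic=float(rho), p_value=float(p), n1=n, n2=n, method="spearman"
    )


def concordance(fc_a: pd.DataFrame, fc_b: pd.DataFrame,
                value_b: str = "log2fc") -> TestResult:
    """Pearson correlation between two fold-change tables joined on (gene, mutant).

    Typically protein vs RNA fold changes for the mutants measured with both;
    ``value_b`` can name a different column (e.g. an abundance measure) for
    abundance-vs-effect correlations.
    """
    joined = fc_a.merge(
        fc_b, on=["gene_id", "mutant_id"], suffixes=("_a", "_b")
    )
    col_b = value_b if value_b in joined.columns else f"{value_b}_b"
    joined = joined.dropna(subset=["log2fc_a", col_b])
    n = len(joined)
    if n < 3:
        raise ValueError(f"need at least 3 joined (gene, mutant) pairs, got {n}")
    r, p = stats.pearsonr(
        joined["log2fc_a"].to_numpy(dtype=float),
        joined[col_b].to_numpy(dtype=float),
    )
    return TestResult(
        statistic=float(r), p_value=float(p), n1=n, n2=n, method="pearson"
    )
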