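"""Per-channel protein intensities to per-mutant log2 fold changes.

The quantification follows the standard isobaric-labeling (TMT) workflow for
mutant libraries: channel intensities are calibrated within each multiplex
experiment (plex), each protein's intensity in each mutant is divided by the
median intensity of that protein across all mutants of the same plex, and
replicate fold changes are averaged.  The across-mutant median stands in for
the wild type: as long as most mutants leave a given protein unchanged, the
median is a robust wild-type proxy.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "IntensityMatrix",
    "normalize_intensities",
    "fold_changes_vs_median",
    "average_replicates",
    "read_intensity_matrix",
    "write_fold_changes",
    "read_fold_changes",
]

#: Column order of a fold-change table.
FC_COLUMNS = ["gene_id", "mutant_id", "condition", "datatype", "log2fc", "n_replicates"]

SAMPLE_SHEET_COLUMNS = ["mutant_id", "replicate", "plex_id", "condition"]


@dataclass
class IntensityMatrix:
    """Protein signal-sum intensities (rows = proteins, columns = samples).

    ``values`` is indexed by gene_id with one column per sample; ``samples``
    is indexed by sample_id with columns mutant_id, replicate, plex_id and
    condition.  Missing measurements are NaN.  ``calibration`` records the
    per-sample (scale, offset) of the last normalization, if any.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    calibration: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in self.values.columns if c not in self.samples.index]
        if missing:
            raise ValueError(f"samples missing from sample sheet: {missing}")
        for col in SAMPLE_SHEET_COLUMNS:
            if col not in self.samples.columns:
                raise ValueError(f"sample sheet lacks required column {col!r}")
        # raw matrices must be non-negative; a calibrated matrix may dip below
        # zero near the detection floor (affine offset), those values simply
        # yield no fold-change rows downstream
        if not self.calibration:
            with np.errstate(invalid="ignore"):
                if (self.values.to_numpy(dtype=float) < 0).any():
                    raise ValueError("negative intensities are not allowed")

    def plexes(self):
        """Yield (plex_id, sample_ids) for each plex, in sheet order."""
        order = self.samples.loc[list(self.values.columns)]
        for plex_id, grp in order.groupby("plex_id", sort=False):
            yield plex_id, list(grp.index)


def read_intensity_matrix(values_path, sample_sheet_path) -> IntensityMatrix:
    """Read an intensity TSV/CSV (first column gene_id) plus its sample sheet TSV."""
    sep = "," if str(values_path).endswith(".csv") else "\t"
    values = pd.read_csv(values_path, sep=sep, index_col=0)
    samples = pd.read_csv(sample_sheet_path, sep="\t", index_col=0)
    samples["replicate"] = samples["replicate"].astype(int)
    return IntensityMatrix(values=values, samples=samples)


def _median_log_calibration(block: pd.DataFrame) -> dict[str, tuple[float, float]]:
    """Per-column scale equalizing median log-intensity within a plex.

    The first column anchors the scale, mirroring the vsn_like convention.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        med = np.log2(block.where(block > 0)).median(axis=0)
    target = med.iloc[0]
    return {c: (float(2.0 ** (target - med[c])), 0.0) for c in block.columns}


def _vsn_like_calibration(block: pd.DataFrame, n_iter: int = 10) -> dict[str, tuple[float, float]]:
    """Robust affine calibration on the generalized-log (asinh) scale.

    Model: h_c(x) = asinh(a_c * x + b_c) per column, with a_c > 0 so rank
    order is preserved.  Columns are fitted so h_c(x_ic) agrees with the
    per-protein consensus across the plex; a soft-L1 loss downweights the
    minority of truly changing proteins.  The first column anchors the scale
    (a=1, b=0), which fixes the affine indeterminacy of the model.
    """
    from scipy.optimize import least_squares

    X = block.to_numpy(dtype=float)
    n_prot, n_col = X.shape
    # warm start from the median-log scales: keeps the robust fit away from
    # the degenerate zero-scale optimum of the asinh model
    start = _median_log_calibration(block)
    log_a = np.log([start[c][0] for c in block.columns])
    log_a0 = log_a.copy()
    b = np.zeros(n_col)

    def transformed():
        return np.arcsinh(np.exp(log_a)[None, :] * X + b[None, :])

    scale_guess = np.nanmedian(X)
    for _ in range(n_iter):
        H = transformed()
        consensus = np.nanmean(H, axis=1)
        new_log_a, new_b = log_a.copy(), b.copy()
        for c in range(1, n_col):
            x = X[:, c]
            mask = np.isfinite(x) & np.isfinite(consensus)
            if mask.sum() < 2:
                raise ValueError(
                    f"sample {block.columns[c]!r}: not enough finite values to calibrate"
                )

            def resid(theta, x=x[mask], m=consensus[mask]):
                return np.arcsinh(np.exp(theta[0]) * x + theta[1]) - m

            # scale stays within e^±3 of the median-log warm start: rules out
            # the degenerate zero-scale optimum on pathological input
            lo = [log_a0[c] - 3.0, -10.0 * scale_guess]
            hi = [log_a0[c] + 3.0, 10.0 * scale_guess]
            sol = least_squares(
                resid,
                x0=[np.clip(new_log_a[c], lo[0], hi[0]),
                    np.clip(new_b[c], lo[1], hi[1])],
                bounds=(lo, hi),
                loss="soft_l1",
                f_scale=0.1,
                x_scale=[1.0, max(scale_guess, 1.0)],
            )
            new_log_a[c], new_b[c] = sol.x
        if np.allclose(new_log_a, log_a, atol=1e-10) and np.allclose(new_b, b, atol=1e-8):
            log_a, b = new_log_a, new_b
            break
        log_a, b = new_log_a, new_b
    return {
        col: (float(np.exp(log_a[c])), float(b[c]))
        for c, col in enumerate(block.columns)
    }


def normalize_intensities(matrix: IntensityMatrix, method: str = "vsn_like") -> IntensityMatrix:
    """Calibrate channel intensities within each plex.

    ``vsn_like`` fits a per-column affine calibration (scale, offset) by
    robust iterative minimization of between-column spread on the
    generalized-log (asinh) scale, then returns values on the calibrated
    intensity scale ``a_c * x + b_c``.  ``median_log`` simply rescales each
    column so per-column median log-intensity is equal within a plex.  Both
    leave within-column rank order unchanged.
    """
    if method not in ("vsn_like", "median_log"):
        raise ValueError(f"unknown normalization method {method!r}")
    values = matrix.values.copy()
    calibration: dict[str, tuple[float, float]] = {}
    for plex_id, cols in matrix.plexes():
        if len(cols) < 2:
            raise ValueError(f"plex {plex_id!r} has fewer than 2 samples")
        block = values[cols]
        for c in cols:
            if not np.isfinite(block[c].to_numpy(dtype=float)).any():
                raise ValueError(f"sample {c!r} has no finite intensities")
        if method == "median_log":
            cal = _median_log_calibration(block)
        else:
            cal = _vsn_like_calibration(block)
        for c, (a, off) in cal.items():
            values[c] = values[c] * a + off
        calibration.update(cal)
    return IntensityMatrix(values=values, samples=matrix.samples,
                           calibration=calibration)


def fold_changes_vs_median(matrix: IntensityMatrix) -> pd.DataFrame:
    """Log2 fold change of each sample against the across-sample plex median.

    For every protein and sample, ``log2fc = log2(intensity / median over all
    samples of the same plex)``; the median includes the focal sample, so the
    per-(protein, plex) median log2fc is exactly 0.  Proteins missing in a
    sample yield no row; a zero (or missing) plex median skips that
    (protein, plex) with a warning.

    Returns a long-format table with one row per (gene, sample), carrying the
    sample's mutant, replicate, plex and condition.
    """
    frames = []
    for plex_id, cols in matrix.plexes():
        mutants = matrix.samples.loc[cols, "mutant_id"].nunique()
        if mutants < 3:
            warnings.warn(
                f"plex {plex_id!r} has only {mutants} mutants; the median "
                "reference is dominated by each sample itself",
                stacklevel=2,
            )
        block = matrix.values[cols].astype(float)
        med = block.median(axis=1, skipna=True)
        bad = (med <= 0) | ~np.isfinite(med)
        if bad.any():
            logger.warning(
                "plex %s: skipping %d protein(s) with non-positive median",
                plex_id, int(bad.sum()),
            )
        ok = block.loc[~bad]
        with np.errstate(divide="ignore", invalid="ignore"):
            lfc = np.log2(ok.div(med.loc[~bad], axis=0))
        long = lfc.stack().rename("log2fc").reset_index()
        long.columns = ["gene_id", "sample_id", "log2fc"]
        long = long[np.isfinite(long["log2fc"])]
        long["plex_id"] = plex_id
        frames.append(long)
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["gene_id", "sample_id", "log2fc", "plex_id"]
    )
    meta = matrix.samples[["mutant_id", "replicate", "condition"]]
    out = out.join(meta, on="sample_id")
    out["datatype"] = "protein"
    return out[["gene_id", "mutant_id", "condition", "datatype",
                "replicate", "plex_id", "sample_id", "log2fc"]]


def average_replicates(table: pd.DataFrame, scale: str = "log") -> pd.DataFrame:
    """Average replicate fold changes per (gene, mutant, condition, datatype).

    ``scale="log"`` (default) takes the arithmetic mean of log2 fold changes,
    which treats up- and downregulation symmetrically; ``scale="linear"``
    averages linear ratios and re-logs.  ``n_replicates`` records how many
    replicate values contributed to each row.
    """
    keys = ["gene_id", "mutant_id", "condition", "datatype"]
    grouped = table.groupby(keys, sort=False)["log2fc"]
    if scale == "log":
        mean = grouped.mean()
    elif scale == "linear":
        mean = np.log2(grouped.apply(lambda s: np.mean(2.0 ** s.to_numpy())))
    else:
        raise ValueError(f"unknown averaging scale {scale!r}")
    out = mean.rename("log2fc").reset_index()
    out["n_replicates"] = grouped.size().to_numpy()
    return out[FC_COLUMNS]


def write_fold_changes(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_fold_changes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
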