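"""Optional figures: fold change by operon position, and +1 deficit vs distance."""

from __future__ import annotations

import pandas as pd

__all__ = ["position_boxplot", "distance_scatter"]


def position_boxplot(table: pd.DataFrame, value: str = "log2fc", ax=None,
                     datatype: str | None = None):
    """Box-whisker of fold changes per operon-relative position.

    Boxes show median and IQR, whiskers the most extreme values within
    1.5 x IQR.  Position 0 (the deleted gene) never appears.
    """
    import matplotlib.pyplot as plt

    if datatype is not None:
        table = table[table["datatype"] == datatype]
    table = table.dropna(subset=[value])
    positions = sorted(table["position"].unique())
    data = [table.loc[table["position"] == p, value].to_numpy() for p in positions]
    if ax is None:
        _, ax = plt.subplots()
    ax.boxplot(data, tick_labels=[f"{p:+d}" for p in positions], whis=1.5)
    ax.axhline(0.0, color="grey", lw=0.8, ls="--")
    ax.set_xlabel("position in operon relative to deleted gene")
    ax.set_ylabel(f"{value} (log2)")
    return ax


def distance_scatter(table: pd.DataFrame, ax=None):
    """Corrected +1 protein fold change against intergenic distance."""
    import matplotlib.pyplot as plt

    sub = table[(table["position"] == 1) & (table["datatype"] == "protein")]
    sub = sub.dropna(subset=["corrected_log2fc", "intergenic_distance"])
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(sub["intergenic_distance"], sub["corrected_log2fc"], s=18)
    ax.axhline(0.0, color="grey", lw=0.8, ls="--")
    ax.set_xlabel("intergenic distance (nt)")
    ax.set_ylabel("corrected log2 fold change of +1 gene")
    return ax
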