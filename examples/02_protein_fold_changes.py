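"""From TMT channel intensities to median-reference log2 fold changes.

Three mutants in one plex; protein p1 is twice as abundant in mutant m2 as
in the others.  The fold change of each mutant is taken against the
across-mutant median of the same protein, so unchanged proteins land at 0.
"""

import numpy as np
import pandas as pd

from operonpolar import IntensityMatrix, average_replicates, fold_changes_vs_median

values = pd.DataFrame(
    {
        "m0_r1": [100.0, 5000.0, 800.0],
        "m1_r1": [100.0, 5000.0, 820.0],
        "m2_r1": [200.0, 5000.0, 790.0],
    },
    index=["p1", "p2", "p3"],
)
samples = pd.DataFrame(
    {
        "mutant_id": ["m0", "m1", "m2"],
        "replicate": [1, 1, 1],
        "plex_id": ["plexA"] * 3,
        "condition": ["cassette"] * 3,
    },
    index=values.columns,
)

matrix = IntensityMatrix(values=values, samples=samples)
fc = average_replicates(fold_changes_vs_median(matrix))
print(fc.to_string(index=False))
print()
print("p1 in m2 is log2(200/100) = +1 (2-fold up vs the plex median);")
print("p2 is identical everywhere, so its fold changes are exactly 0.")
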