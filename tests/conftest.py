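import numpy as np
import pandas as pd
import pytest

from operonpolar import GeneAnnotation, IntensityMatrix, OperonStructure


@pytest.fixture
def abc_annotations():
    """Three-gene + strand operon plus a lone gene, hand-placed coordinates."""
    genes = [
        GeneAnnotation("geneA", "chr", 100, 1099, "+"),
        GeneAnnotation("geneB", "chr", 1150, 2149, "+"),
        GeneAnnotation("geneC", "chr", 2200, 3199, "+"),
        GeneAnnotation("geneX", "chr", 5000, 5999, "-"),
    ]
    return {g.gene_id: g for g in genes}


@pytest.fixture
def abc_operons():
    return {
        "op1": OperonStructure("op1", ("geneA", "geneB", "geneC")),
        "op2": OperonStructure("op2", ("geneX",)),
    }


def make_matrix(values: np.ndarray, gene_ids, sample_ids, plex_ids=None,
                mutant_ids=None, replicates=None) -> IntensityMatrix:
    """Assemble an IntensityMatrix from a raw array with a one-plex default sheet."""
    values = pd.DataFrame(values, index=gene_ids, columns=sample_ids)
    n = len(sample_ids)
    samples = pd.DataFrame(
        {
            "mutant_id": mutant_ids or [f"m{i}" for i in range(n)],
            "replicate": replicates or [1] * n,
            "plex_id": plex_ids or ["p1"] * n,
            "condition": ["cassette"] * n,
        },
        index=list(sample_ids),
    )
    return IntensityMatrix(values=values, samples=samples)


@pytest.fixture
def small_matrix():
    """3 proteins x 3 mutants, one plex; protein g1 has intensities (2, 4, 8)."""
    return make_matrix(
        np.array([[2.0, 4.0, 8.0], [5.0, 5.0, 5.0], [1.0, 3.0, 9.0]]),
        ["g1", "g2", "g3"],
        ["s1", "s2", "s3"],
    )
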