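"""Simulate a Keio-style deletion library and write every pipeline input.

The generator lays operons on a chromosome, deletes one gene per operon,
applies operon-wide transcriptional shifts plus the distance-dependent
protein-only deficit on the +1 gene, and emits annotations, operon table,
TMT-style intensities, WIG coverage and the ground truth.
"""

from pathlib import Path

from operonpolar import SimulationParams, write_library

outdir = Path("scratch/example_library")
params = SimulationParams(n_operons=20, seed=42)
write_library(outdir, params)

print(f"library written to {outdir}/")
for f in sorted(outdir.iterdir()):
    if f.is_file():
        print(" ", f.name)
print("wig/ holds one forward + one reverse coverage file per mutant;")
print("ground_truth.json records every simulated effect for recovery checks.")
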