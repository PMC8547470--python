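"""End-to-end polar-effect analysis on a simulated library.

Simulates a 40-operon library with the default effect structure, runs the
protein branch (fold changes -> operon positions -> median correction),
classifies operon-level effects and tests the gene directly downstream of
each deletion for its extra protein deficit.
"""

import operonpolar as op

params = op.SimulationParams(n_operons=40, seed=7)
ann, ops = op.simulate_genome(params)
matrix, deletions, truth = op.simulate_library(params, annotations=ann, operons=ops)

fc = op.average_replicates(op.fold_changes_vs_median(
    op.normalize_intensities(matrix, "median_log")))
positioned, not_in_operon = op.position_fold_changes(fc, ops, deletions, ann)
corrected = op.operon_median_correction(positioned)

classes = op.classify_operon_effects(positioned)
summary = op.summarize_classes(classes)
print(f"evaluable mutants (>=1 gene beyond +1): {summary['n_evaluable']}")
print(f"operons >2-fold up: {summary['n_up']} ({100*summary['fraction_up']:.0f}%), "
      f"down: {summary['n_down']} ({100*summary['fraction_down']:.0f}%)")

test = op.downstream_gene_test(corrected, "protein", use_corrected=True)
print(f"+1 gene vs other downstream genes (corrected): "
      f"p = {test.p_value:.2e}, median linear FC at +1 = "
      f"{test.extra['median_linear_fc_p1']:.2f}")

dist = op.distance_correlation(corrected)
print(f"corrected +1 deficit vs intergenic distance: Spearman rho = "
      f"{dist.statistic:.2f} (p = {dist.p_value:.1e}, n = {dist.n1})")
print()
print("a median FC below 1 at +1 means the gene directly downstream of the")
print("deletion loses protein beyond the operon-wide transcriptional shift,")
print("and the positive rho says the loss grows as the intergenic gap shrinks.")
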