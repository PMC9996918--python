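"""Compositional preprocessing: filter, impute, ALR-transform, autoscale.

Metabolites with >20% missing values in either population are dropped;
remaining gaps are filled with half the minimum observed intensity of the
metabolite's acquisition method; abundances become additive log-ratios
(ALR) against the lowest-CV reference metabolite; a Procrustes correlation
against the centered log-ratio geometry checks that this reference choice
barely distorts the sample configuration; columns are autoscaled so later
effect sizes are in per-metabolite SD units.
"""

import metabodisc as md

cfg = md.SimulationConfig(seed=1)
table, _ = md.generate_dataset(cfg)
table = md.inject_missingness(table, cfg)

result = md.preprocess_table(table, missing_threshold=0.20)
r = result.report
print(f"metabolites in: {r['n_metabolites_in']}")
print(f"removed (>20% missing in a population): {r['n_removed_missing']}")
print(f"ALR columns: {r['n_alr_columns']} (= {r['n_retained']} retained - 1)")
print(f"ALR reference (lowest CV): {r['reference_id']}")
print(f"Procrustes correlation vs CLR geometry: {r['procrustes_correlation']:.4f}")
# A Procrustes correlation near 1 means the ALR coordinates preserve the
# compositional sample geometry almost isometrically.
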