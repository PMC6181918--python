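"""Simulate one clustered ROI and run the full analysis pipeline on it.

Generates a 20 µm² region with the BT-474-like preset (360 localizations/µm²,
~3 molecules per cluster), then applies the quality filters, binarization,
blinking-corrected density quantification, pair-correlation fitting and
cluster-occupancy analysis.
"""

import qsmlm

params = qsmlm.preset("bt474")
table, truth = qsmlm.simulate_roi(params, seed=42)
print(f"simulated {len(table)} localizations from {truth.n_molecules} molecules "
      f"in {len(truth.cluster_radius)} clusters")

result = qsmlm.analyze_roi(table)

print(f"binning loss fraction      : {result.loss_fraction:.4f}")
print(f"detected density           : {result.density.density:.1f} molecules/um^2")
print(f"cluster amplitude A        : {result.fit.A:.2f}")
print(f"correlation length xi      : {result.fit.xi:.1f} nm")
print(f"molecules per cluster      : {result.fit.n_per_cluster:.2f}")
print(f"verdict                    : {qsmlm.classify_clustered(result.fit)}")
print(f"fraction clustered (>2)    : {result.occupancy.fraction_clustered:.2f}")

# The detected density is the localization count / (alpha * area): with the
# preset's 360 locs/um^2 and alpha = 3 it sits near 120 molecules/um^2 (less
# the ~2% precision-percentile cut and ~0.5% binning loss).  The verdict is
# 'clustered' because the fitted amplitude is significantly above zero.
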