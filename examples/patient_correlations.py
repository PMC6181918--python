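"""Correlate the embedded patient summary with FISH copy numbers.

Reproduces the study-level statistics from the packaged patient table:
Pearson correlation of detected HER2 density (and of receptors per cluster)
against FISH copy number, and the density threshold equivalent to the
clinical copy-number-6 positivity cutoff.
"""

import qsmlm
from qsmlm.stats_report import (patient_density_correlation,
                                patient_per_cluster_correlation)

table = qsmlm.load_table1()
print(table[["id", "fish_copy_number", "density_per_um2", "per_cluster"]].to_string(index=False))

dens = patient_density_correlation()
print(f"\ndensity vs copy number (n={dens.n}): r = {dens.r:.3f} "
      f"[{dens.ci_low:.3f}, {dens.ci_high:.3f}], p = {dens.p_value:.4f}")
print(f"least-squares line: copy = {dens.slope:.2f} * density + {dens.intercept:.2f} "
      f"(R^2 = {dens.r_squared:.3f})")

thr = qsmlm.density_threshold_from_fit(dens, copy_number=6.0)
print(f"copy number 6 corresponds to {thr:.1f} molecules/um^2")

per = patient_per_cluster_correlation()
print(f"\nreceptors/cluster vs copy number (n={per.n}): r = {per.r:.3f} "
      f"[{per.ci_low:.3f}, {per.ci_high:.3f}], p = {per.p_value:.3f}")

# r ~ 0.98 confirms that the blinking-corrected density tracks gene
# amplification; the threshold (~22 molecules/um^2) converts the clinical
# FISH cutoff into an imaging-domain quantity.
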