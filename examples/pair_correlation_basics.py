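"""Pair correlation of a random vs a clustered localization pattern.

Shows the two regimes the amplitude test distinguishes: complete spatial
randomness (g flattens to 1 once the blinking peak decays) versus
nanoclusters (excess correlation at short range, fitted by the exponential
cluster model).
"""

import numpy as np

import qsmlm

for name, simulate in [("random", qsmlm.simulate_random_roi),
                       ("bt474", qsmlm.simulate_roi)]:
    table, _ = simulate(qsmlm.preset(name), seed=3)
    image = qsmlm.binarize(table)
    corr = qsmlm.autocorrelate(image)
    sigma = float(np.mean(table.precision))
    fit = qsmlm.fit_protein_correlation(corr, sigma_bar=sigma, alpha=3.0)
    print(f"{name:>7}: {len(table):>5} locs | "
          f"g(0-25 nm) = {corr.g[corr.r < 25].mean():6.1f} | "
          f"g(tail) = {corr.g[corr.r > 300].mean():5.2f} | "
          f"A = {fit.A:5.2f}, xi = {fit.xi:5.1f} nm -> {qsmlm.classify_clustered(fit)}")

# Both patterns show a large short-range peak from repeated appearances of
# single labels (blinking); only the clustered preset keeps excess
# correlation after the blinking term is accounted for, so only it gets a
# positive amplitude A and the 'clustered' verdict.
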