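"""Simulate a small synthetic cohort and look at its trait structure.

The generator draws NEO PI-R-style facet T-scores (mean 50, SD 10, facets
within a domain correlated 0.4), sums them into domain scores, and derives
1-7 attachment prototype ratings from the domain z-scores.  With the
default loadings, secure attachment is negatively related to neuroticism
and positively to extraversion.
"""

import painsig as ps
from painsig.stats_core import spearman

config = ps.GeneratorConfig(n_participants=500, seed=1, sample_rate_hz=10.0,
                            n_discrepant=0)
profiles = ps.sample_traits(config)
traits = ps.traits_table(profiles)

print(traits[["N1", "N6", "C5", "N", "E", "secure", "preoccupied"]].head())
for pair in [("secure", "N"), ("secure", "E"), ("preoccupied", "N")]:
    rho, p = spearman(traits[pair[0]], traits[pair[1]])
    print(f"Spearman rho({pair[0]}, {pair[1]}) = {rho:+.2f}  (p = {p:.2g})")

# The printed correlations estimate the calibrated population structure
# (about -0.30, +0.41 and +0.40); at n = 500 they fluctuate by ~0.04.
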