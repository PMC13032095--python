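"""Trait-behavior correlation screen with per-family FDR control.

Runs the full study-size cohort (n = 534 after no exclusions here) and
screens all 35 NEO predictors and 4 attachment prototypes against the
modulation indexes with Spearman correlations; q values are
Benjamini-Hochberg adjusted within each (index x instrument) family.
"""

import painsig as ps

config = ps.GeneratorConfig(n_participants=534, seed=3, sample_rate_hz=10.0,
                            n_discrepant=0)
traits, indexes = ps.simulate_indexes(config)
battery = ps.correlation_battery(traits, indexes,
                                 ["tai_46", "contrast_magnitude"])

focus = battery[battery.predictor.isin(["N6", "C5", "N", "secure"])]
cols = ["predictor", "index", "n", "rho", "p", "q", "significance"]
print(focus[cols].round(3).to_string(index=False))

# The generator couples vulnerability (N6) positively to the contrast
# effect (population Spearman rho = 0.15) and self-discipline (C5)
# negatively to the 46 degC TAI (rho = -0.14); the broad neuroticism
# domain dilutes the facet signal, as the q column shows.
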