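"""Causal-steps mediation on known generative ground truth.

Two scenario generators encode the two candidate psychological pathways:

* stabilization -- self-discipline (C5) raises secure attachment, and
  secure attachment lowers contrast susceptibility; no direct path.
  The causal-steps classifier should call this "full" mediation.
* instability -- vulnerability (N6) raises contrast susceptibility
  directly; preoccupied attachment correlates with N6 but has no effect
  of its own, so the direct effect c' must survive adjustment.
"""

import painsig as ps

for name, cfg, x, m in [
    ("stabilization", ps.stabilization_scenario(534, seed=11), "C5", "secure"),
    ("instability", ps.instability_scenario(534, seed=11), "N6", "preoccupied"),
]:
    traits, indexes = ps.simulate_indexes(cfg)
    df = traits.merge(indexes, on="participant_id")
    model = ps.baron_kenny(df[x], df[m], df["contrast_magnitude"],
                           x_label=x, m_label=m, y_label="contrast_magnitude")
    print(f"--- {name} path: {x} -> {m} -> contrast magnitude ---")
    print(f"  c (total)  = {model.c_total.coef:+.3f}  p = {model.c_total.p:.3g}")
    print(f"  a          = {model.a.coef:+.3f}  p = {model.a.p:.3g}")
    print(f"  b          = {model.b.coef:+.3f}  p = {model.b.p:.3g}")
    print(f"  c' (direct)= {model.c_prime.coef:+.3f}  p = {model.c_prime.p:.3g}")
    print(f"  Sobel z = {model.sobel_z:+.2f} (p = {model.sobel_p:.2g})")
    print(f"  classification: {model.classification}")

# Coefficients are standardized; c = c' + a*b holds exactly for each model.
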