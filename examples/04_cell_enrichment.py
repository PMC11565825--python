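"""Score a gene community against labeled single-cell expression and test
whether a subtype's frequency shifts across pathology conditions.
"""

from abtau_modnet import SynthConfig, combined_score, composition_test, gen_cells, module_score

cfg = SynthConfig(seed=0)
cells = gen_cells(cfg)
markers = cfg.marker_sets()

score = module_score(cells, markers["S2"], seed=0)
tab = combined_score(cells, score)
print("signature score of the S2 marker community, per subtype:")
print(tab.to_string(float_format=lambda v: f"{v:.3f}"))
print("combined = mean score x positive proportion; normalized so max = 1.")
print()

res = composition_test(cells, "S1")
print(f"S1 frequency ANOVA across conditions: F = {res['anova']['F']:.2f}, "
      f"p = {res['anova']['p']:.2g}")
if res["tukey"] is not None:
    print(res["tukey"].to_string(index=False))
    print("(S1 is planted to rise Control < Abeta < AbetaTau)")
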