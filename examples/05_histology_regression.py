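"""Validate moderation on the histopathology table: per-stratum interaction
regression Tau2 ~ Abeta x GFAP, and CERAD x Braak severity cross-tabs for
high vs low GPNMB expression.
"""

from abtau_modnet import SynthConfig, fit_interaction, gen_histo, severity_crosstab

cfg = SynthConfig(seed=0)  # interaction planted only in (TCx, dementia) stratum
histo = gen_histo(cfg)

fits = fit_interaction(histo, "tau2_pct", "abeta_pct", "gfap_pct")
inter = fits[fits["term"] == "abeta_pct:gfap_pct"]
print("interaction term (Abeta x GFAP) per stratum:")
print(inter[["region", "dementia", "beta", "se", "t", "p"]].to_string(
    index=False, float_format=lambda v: f"{v:.3f}"))
print(f"(planted beta3 = {cfg.histo_beta_interaction} in {cfg.interaction_strata})")
print()

donor = histo.drop_duplicates("donor").set_index("donor")
top, bottom = severity_crosstab(donor["gpnmb_fpkm"], donor["cerad"], donor["braak"])
print("Braak distribution, GPNMB-high stratum (columns = Braak stage):")
print(top.sum(axis=0).to_string())
print("Braak distribution, GPNMB-low stratum:")
print(bottom.sum(axis=0).to_string())
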