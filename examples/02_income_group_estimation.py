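"""Estimate price elasticities separately by income group.

Countries are binned by final-year GNI per capita into six groups (the
US$1000/2000/3000/4000/6000 thresholds) and the demand equation is fitted
within each group, mirroring how elasticities differ with income level.
"""

from cigtaxsim import PanelDGPParams, estimate_by_group, generate_panel

# a larger synthetic region so every income bin is populated
panel = generate_panel(PanelDGPParams(n_countries=40, seed=7))
fits = estimate_by_group(panel)

print("group  elasticity (se)    income el.   n_obs  countries  weak-ID F")
for f in fits:
    print(f"  {f.group_id}    {f.beta_price:+.3f} ({f.se[0]:.3f})   "
          f"{f.beta_gni:+.3f}      {f.n_obs:5d}  {f.n_countries:9d}  {f.weak_id_F:9.1f}")
print("\nEvery group shares the same data-generating elasticity (-1.304);")
print("differences across rows reflect sampling noise at small group sizes.")
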