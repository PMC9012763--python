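# Moy demo catchment record.
# discharge and speciation ratios are the published monitoring-derived values;
# total exports, pasture fractions and fixed attributes are SYNTHETIC
# plausible demo values (synthetic: true).
name: Moy
synthetic: true
discharge_m3_per_year: 1.8e9
total_n_t_per_year: 5500.0     # synthetic demo value
total_p_t_per_year: 180.0      # synthetic demo value
frac_n_inorganic: 0.324
frac_inorg_as_nitrate: 0.9286
frac_p_ortho: 0.264
pasture_fraction_n: 0.70       # synthetic demo value
pasture_fraction_p: 0.55       # synthetic demo value
sediment_load_t_per_km_per_year: 8.0
bod_mg_per_l: 1.2
fixed_states:
  Alkalinity: High
  FlowVariability: Non-spatey
  Light: Open canopy
  RiverReach: Lower reaches
  CoarseFish: Present
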