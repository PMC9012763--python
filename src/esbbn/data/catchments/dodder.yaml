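# Dodder demo catchment record (small, steep, partly urbanised).
# discharge and speciation ratios are the published monitoring-derived values;
# total exports, pasture fractions and fixed attributes are SYNTHETIC
# plausible demo values (synthetic: true).
name: Dodder
synthetic: true
discharge_m3_per_year: 8.6e7
total_n_t_per_year: 190.0      # synthetic demo value
total_p_t_per_year: 6.0        # synthetic demo value
frac_n_inorganic: 0.811
frac_inorg_as_nitrate: 0.924
frac_p_ortho: 0.378
pasture_fraction_n: 0.18       # synthetic demo value
pasture_fraction_p: 0.10       # synthetic demo value
sediment_load_t_per_km_per_year: 6.0
bod_mg_per_l: 1.45
fixed_states:
  Alkalinity: Medium
  FlowVariability: Spatey
  Light: Medium canopy
  RiverReach: Headwaters
  CoarseFish: Absent
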