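# Suir (upper, non-tidal) demo catchment record.
# discharge and speciation ratios are the published monitoring-derived values;
# total exports, pasture fractions and fixed attributes are SYNTHETIC
# plausible demo values (synthetic: true) - the source-apportionment totals
# were only ever charted, not tabulated.
name: Suir
synthetic: true
discharge_m3_per_year: 1.1e9
total_n_t_per_year: 2800.0     # synthetic demo value
total_p_t_per_year: 120.0      # synthetic demo value
frac_n_inorganic: 0.807
frac_inorg_as_nitrate: 0.9808
frac_p_ortho: 0.329
pasture_fraction_n: 0.75       # synthetic demo value
pasture_fraction_p: 0.50       # synthetic demo value
sediment_load_t_per_km_per_year: 12.0
bod_mg_per_l: 1.4
fixed_states:
  Alkalinity: High
  FlowVariability: Non-spatey
  Light: Medium canopy
  RiverReach: Lower reaches
  CoarseFish: Present
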