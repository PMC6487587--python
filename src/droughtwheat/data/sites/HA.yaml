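# 2050 scenario climate normals and generator knobs for Halle
site_id: HA
name: Halle
country: Germany
latitude: 51.51
longitude: 11.95
mean_annual_temp: 12.7      # deg C, scenario annual mean
annual_precip: 509         # mm / year, scenario annual total
cultivar: Claire
sowing_date: "10-20"       # MM-DD, local sowing date
summer_dryness: 0.55      # warm-season precipitation-deficit knob
temp_amplitude: 9.4      # deg C, seasonal half-range (latitude band default)
co2_ppm: 541.0
scenario: intermediate
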