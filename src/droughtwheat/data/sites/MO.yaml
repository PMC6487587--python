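# 2050 scenario climate normals and generator knobs for Montagnano
site_id: MO
name: Montagnano
country: Italy
latitude: 43.3
longitude: 11.8
mean_annual_temp: 16.0      # deg C, scenario annual mean
annual_precip: 686         # mm / year, scenario annual total
cultivar: Creso
sowing_date: "11-25"       # MM-DD, local sowing date
summer_dryness: 1.0      # warm-season precipitation-deficit knob
temp_amplitude: 8.6      # deg C, seasonal half-range (latitude band default)
co2_ppm: 541.0
scenario: intermediate
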