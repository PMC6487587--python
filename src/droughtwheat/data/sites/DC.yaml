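# 2050 scenario climate normals and generator knobs for Debrecen
site_id: DC
name: Debrecen
country: Hungary
latitude: 47.6
longitude: 21.6
mean_annual_temp: 14.2      # deg C, scenario annual mean
annual_precip: 441         # mm / year, scenario annual total
cultivar: Thesee
sowing_date: "10-18"       # MM-DD, local sowing date
summer_dryness: 1.0      # warm-season precipitation-deficit knob
temp_amplitude: 9.0      # deg C, seasonal half-range (latitude band default)
co2_ppm: 541.0
scenario: intermediate
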