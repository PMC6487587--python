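# 2050 scenario climate normals and generator knobs for Seville
site_id: SL
name: Seville
country: Spain
latitude: 37.42
longitude: -5.88
mean_annual_temp: 22.1      # deg C, scenario annual mean
annual_precip: 434         # mm / year, scenario annual total
cultivar: Cartaya
sowing_date: "12-30"       # MM-DD, local sowing date
summer_dryness: 4.0      # warm-season precipitation-deficit knob
temp_amplitude: 8.0      # deg C, seasonal half-range (latitude band default)
co2_ppm: 541.0
scenario: dry-south
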