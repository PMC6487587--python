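# 2050 scenario climate normals and generator knobs for Tylstrup
site_id: TR
name: Tylstrup
country: Denmark
latitude: 57.2
longitude: 9.9
mean_annual_temp: 10.6      # deg C, scenario annual mean
annual_precip: 721         # mm / year, scenario annual total
cultivar: Avalon
sowing_date: "10-18"       # MM-DD, local sowing date
summer_dryness: 0.55      # warm-season precipitation-deficit knob
temp_amplitude: 10.0      # deg C, seasonal half-range (latitude band default)
co2_ppm: 541.0
scenario: intermediate
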