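# 2050 scenario climate normals and generator knobs for Vienna
site_id: VI
name: Vienna
country: Austria
latitude: 48.23
longitude: 16.35
mean_annual_temp: 14.5      # deg C, scenario annual mean
annual_precip: 643         # mm / year, scenario annual total
cultivar: Thesee
sowing_date: "10-20"       # MM-DD, local sowing date
summer_dryness: 0.0      # warm-season precipitation-deficit knob
temp_amplitude: 9.1      # deg C, seasonal half-range (latitude band default)
co2_ppm: 541.0
scenario: wet-northwest
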