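# 2050 scenario climate normals and generator knobs for Toulouse
site_id: TU
name: Toulouse
country: France
latitude: 43.62
longitude: 1.38
mean_annual_temp: 16.7      # deg C, scenario annual mean
annual_precip: 595         # mm / year, scenario annual total
cultivar: Thesee
sowing_date: "11-20"       # MM-DD, local sowing date
summer_dryness: 0.0      # warm-season precipitation-deficit knob
temp_amplitude: 8.6      # deg C, seasonal half-range (latitude band default)
co2_ppm: 541.0
scenario: wet-northwest
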