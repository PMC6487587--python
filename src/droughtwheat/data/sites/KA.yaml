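# 2050 scenario climate normals and generator knobs for Kaunas
site_id: KA
name: Kaunas
country: Lithuania
latitude: 54.88
longitude: 23.83
mean_annual_temp: 10.5      # deg C, scenario annual mean
annual_precip: 605         # mm / year, scenario annual total
cultivar: Avalon
sowing_date: "10-25"       # MM-DD, local sowing date
summer_dryness: 0.3      # warm-season precipitation-deficit knob
temp_amplitude: 9.8      # deg C, seasonal half-range (latitude band default)
co2_ppm: 541.0
scenario: intermediate
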