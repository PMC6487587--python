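# 2050 scenario climate normals and generator knobs for Clermont-Ferrand
site_id: CF
name: Clermont-Ferrand
country: France
latitude: 45.8
longitude: 3.1
mean_annual_temp: 14.7      # deg C, scenario annual mean
annual_precip: 536         # mm / year, scenario annual total
cultivar: Thesee
sowing_date: "11-15"       # MM-DD, local sowing date
summer_dryness: 1.0      # warm-season precipitation-deficit knob
temp_amplitude: 8.8      # deg C, seasonal half-range (latitude band default)
co2_ppm: 541.0
scenario: intermediate
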