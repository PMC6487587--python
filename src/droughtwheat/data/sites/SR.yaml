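# 2050 scenario climate normals and generator knobs for Sremska
site_id: SR
name: Sremska
country: Serbia
latitude: 45.0
longitude: 19.51
mean_annual_temp: 15.2      # deg C, scenario annual mean
annual_precip: 649         # mm / year, scenario annual total
cultivar: Thesee
sowing_date: "11-15"       # MM-DD, local sowing date
summer_dryness: 1.0      # warm-season precipitation-deficit knob
temp_amplitude: 8.8      # deg C, seasonal half-range (latitude band default)
co2_ppm: 541.0
scenario: intermediate
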