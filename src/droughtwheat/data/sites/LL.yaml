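# 2050 scenario climate normals and generator knobs for Lleida
site_id: LL
name: Lleida
country: Spain
latitude: 41.63
longitude: 0.6
mean_annual_temp: 18.0      # deg C, scenario annual mean
annual_precip: 311         # mm / year, scenario annual total
cultivar: Creso
sowing_date: "11-25"       # MM-DD, local sowing date
summer_dryness: 4.0      # warm-season precipitation-deficit knob
temp_amplitude: 8.4      # deg C, seasonal half-range (latitude band default)
co2_ppm: 541.0
scenario: dry-south
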