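# Initial (current local variety) cultivar parameter set for site WA
Ph: 110.0     # phyllochron, deg C day per leaf
Pp: 0.5     # daylength response, leaf h^-1
Gf: 650.0     # grain-filling duration, deg C day
A: 0.007       # maximum flag-leaf area, m^2 leaf m^-2 soil
SG: 0.5     # stay-green factor
Ru: 3.0     # rate of root water uptake, % day^-1
Wsa: 0.5   # response of photosynthesis to water stress (exponent)
Wss: 1.27   # maximum acceleration of leaf senescence
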