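name,latitude,longitude,nonag_population
City-A,31.76699766698142,108.22371896537274,8355268.363617226
City-B,24.61692423863544,107.06284410986976,1591966.3569197995
City-C,24.41766293252785,107.0521446468623,8698265.65949836
City-D,24.636498042750937,109.37911631901672,5722914.7991490625
City-E,30.636212965699606,117.41139574471711,6269003.032137439
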