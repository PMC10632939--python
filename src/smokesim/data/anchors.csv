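sex,year,prevalence_pct
male,2022,35.3
male,2025,34.0
male,2030,32.2
male,2035,30.7
male,2040,29.4
male,2045,28.3
male,2050,27.6
female,2022,3.6
female,2025,3.5
female,2030,3.3
female,2035,3.3
female,2040,3.2
female,2045,3.1
female,2050,3.1
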