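mutant,survival_years
G37R,17
G85R,6
I113T,4.3
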