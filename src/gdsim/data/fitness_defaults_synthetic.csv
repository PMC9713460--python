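line,fecundity_mean,fertility,larval_viability,larva_to_pupa_days,longevity_f,longevity_m,viability_significant
HWE,75.0,0.88,0.80,6.0,30.0,25.0,0
AeaNosC109,70.0,0.85,0.70,6.5,29.0,24.0,1
AeaZpgC109,74.0,0.87,0.81,6.2,30.0,25.0,0
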