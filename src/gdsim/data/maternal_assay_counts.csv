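line,rep,embryos_injected,n_larvae,larvae_pct,ecfp_n,ecfp_pct,mcherry_n,mcherry_pct
AeaNosC109,1,1056,26,2.4,14,53.8,12,46.1
AeaNosC109,2,1017,33,3.2,18,54.5,15,45.5
AeaNosC109,3,1170,24,2.0,14,58.3,10,41.7
AeaZpgC109,1,1007,23,2.3,13,56.5,10,43.5
AeaZpgC109,2,1015,26,2.6,12,46.1,14,53.8
AeaZpgC109,3,1004,46,4.6,22,47.8,24,52.2
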