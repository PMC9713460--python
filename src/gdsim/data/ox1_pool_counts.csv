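line,parent_sex,pool,marker_pct,n_assessed,gdbi_positive,gdbi_tested,gdbi_pct
AeaNosT4,M,low,45.9,290,0,40,0.0
AeaNosT4,M,high,58.1,136,0,40,0.0
AeaNosT4,F,low,42.9,163,0,40,0.0
AeaNosT4,F,high,51.3,117,0,40,0.0
AeaNosC109,M,low,55.3,228,9,54,16.7
AeaNosC109,M,high,86.4,214,7,27,25.9
AeaNosC109,F,low,61.5,148,7,46,15.2
AeaNosC109,F,high,89.7,136,7,12,58.3
AeaZpgC109,M,low,56.5,232,0,41,0.0
AeaZpgC109,M,high,59.2,228,0,51,0.0
AeaZpgC109,F,low,57.1,98,2,27,7.4
AeaZpgC109,F,high,73.7,118,1,23,4.3
Aeab2tC109,M,none,50.7,138,0,10,0.0
Aeab2tC109,F,none,52.5,40,0,10,0.0
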