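line,marker,embryos_injected,survivors_f,survivors_m,survivors_total,survivors_pct,pct_one_decimal
Aeab2tT4,mCherry,1115,31,41,72,6.5,1
AeaNosT4,mCherry,959,66,88,154,16,0
Aeab2tC109,mCherry,882,64,58,122,13,0
AeaNosC109,mCherry,912,90,116,206,23,0
AeaZpgC109,mCherry,568,17,28,45,7.9,1
AeaeCFPC109,eCFP,1142,24,20,44,3.9,1
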