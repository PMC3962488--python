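chromosome,n_reactions,average_pct,sem_pct
B,11,112.3,2.4
ROMA,11,83.1,1.7
10B,,100.0,
465,11,83.4,1.5
183,11,76.2,2.2
484,5,55.3,4.2
503,8,52.0,5.8
473,5,46.0,11.3
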