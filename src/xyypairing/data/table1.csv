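y_chromosome,female_normal,female_exceptional,male_exceptional,male_normal
B,2228,9,10,1944
ROMA,942,0,4,1005
10B,3035,17,18,3020
473,969,3,13,958
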