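sample_id	condition	replicate
cond1_r1	cond1	r1
cond1_r2	cond1	r2
cond2_r1	cond2	r1
cond2_r2	cond2	r2
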