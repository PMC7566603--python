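gene_id	cond1_r1	cond1_r2	cond2_r1	cond2_r2
g01	100	100	100	100
g02	250	250	250	250
g03	700	700	700	700
g04	1800	1800	1800	1800
g05	5000	5000	5000	5000
g06	12000	12000	12000	12000
g07	23000	23000	23000	23000
g08	30000	30000	30000	30000
g09	1000	1000	2000	2000
g10	2000	2000	4000	4000
g11	4800	4800	300	300
g12	500	500	2000	2000
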