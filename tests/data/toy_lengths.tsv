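gene_id	length_bp
g01	1000
g02	1000
g03	1000
g04	1000
g05	1000
g06	1000
g07	1000
g08	1000
g09	1000
g10	1000
g11	1000
g12	1000
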