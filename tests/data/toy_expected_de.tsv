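gene_id	de
g01	False
g02	False
g03	False
g04	False
g05	False
g06	False
g07	False
g08	False
g09	True
g10	True
g11	True
g12	True
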