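# Source priors for the example network: published overall similarity of
# each reference protein to the p42.3 query.
# Columns: node<TAB>score
S100A11	0.8102
RASEF	0.8068
GCN4	0.7624
FKBP	0.7334
CENP-B	0.7312
S100A2	0.7046
PAK1	0.6716
S100A12	0.6058
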