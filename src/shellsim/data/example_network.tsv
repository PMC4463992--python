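# Illustrative reconstruction of a curated signed regulatory network for the
# p42.3 reference-protein set (synthetic edge list; the published figure's
# exact topology is not printed anywhere, so this file is a user-editable
# approximation containing the reported winning chain plus competing chains).
# Columns: source<TAB>target<TAB>sign
S100A11	RAGE	+
RAGE	P38	+
P38	MAPK	+
MAPK	Microtubule-associated protein	+
Microtubule-associated protein	Spindle protein	+
Spindle protein	Centromere protein	+
Centromere protein	Cell proliferation	+
RASEF	MAPK	+
S100A2	P38	-
CENP-B	Centromere protein	+
PAK1	MAPK	+
GCN4	Transcription activation	+
Transcription activation	Cell proliferation	+
FKBP	Calcineurin signalling	+
Calcineurin signalling	Cell proliferation	+
S100A12	RAGE	+
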