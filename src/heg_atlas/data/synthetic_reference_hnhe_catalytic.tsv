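family	position	residue
IHMU	74	D
IHMU	75	H
IHMU	96	N
IHMU	117	H
PACI	63	D
PACI	64	H
PACI	85	N
PACI	106	N
GVE2	80	D
GVE2	81	H
GVE2	102	N
GVE2	123	H
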