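protein_id
OGN
BGN
LUM
CMA1
DCN
NDUFB2
NDUFB4
CPA3
NUMA1
SERPINA1
PAFAH1B3
SYNC13A
SYNC13B
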