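protein_id	gene_symbol	term_id	term_label	source
OGN	OGN	GO:0031012	Extracellular matrix	GO
BGN	BGN	GO:0031012	Extracellular matrix	GO
LUM	LUM	GO:0031012	Extracellular matrix	GO
CMA1	CMA1	GO:0031012	Extracellular matrix	GO
DCN	DCN	GO:0031012	Extracellular matrix	GO
NDUFB2	NDUFB2	GO:0005739	Mitochondrion	GO
NDUFB4	NDUFB4	GO:0005739	Mitochondrion	GO
COX5A	COX5A	GO:0005739	Mitochondrion	GO
MT-CO2	MT-CO2	GO:0005739	Mitochondrion	GO
COX6C	COX6C	GO:0005739	Mitochondrion	GO
HNRNPA1	HNRNPA1	GO:0003723	RNA binding	GO
HNRNPK	HNRNPK	GO:0003723	RNA binding	GO
RBMX	RBMX	GO:0003723	RNA binding	GO
SERPINA1	SERPINA1	GO:0070062	Extracellular exosome	GO
DCN	DCN	GO:0070062	Extracellular exosome	GO
LUM	LUM	GO:0070062	Extracellular exosome	GO
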