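# ADT antibody name -> HGNC gene symbol, for pathway (GMT) lookups.
# Editable: extend with panel-specific entries as needed.
CD3	CD3E
CD4	CD4
CD8a	CD8A
CD8	CD8A
CD11b	ITGAM
CD11c	ITGAX
CD14	CD14
CD15	FUT4
CD16	FCGR3A
CD19	CD19
CD20	MS4A1
CD25	IL2RA
CD27	CD27
CD28	CD28
CD34	CD34
CD38	CD38
CD39	ENTPD1
CD40	CD40
CD45RA	PTPRC
CD45RO	PTPRC
CD56	NCAM1
CD62L	SELL
CD69	CD69
CD80	CD80
CD86	CD86
CD95	FAS
CD103	ITGAE
CD117	KIT
CD123	IL3RA
CD127	IL7R
CD134	TNFRSF4
CD137	TNFRSF9
CD141	THBD
CD152	CTLA4
CTLA-4	CTLA4
CD161	KLRB1
CD185	CXCR5
CD194	CCR4
CD195	CCR5
CD197	CCR7
CD223	LAG3
LAG-3	LAG3
CD254	TNFSF11
CD273	PDCD1LG2
CD274	CD274
CD278	ICOS
ICOS	ICOS
CD279	PDCD1
PD-1	PDCD1
PD1	PDCD1
CD314	KLRK1
CD335	NCR1
CD357	TNFRSF18
CD366	HAVCR2
TIM3	HAVCR2
TIGIT	TIGIT
KLRG1	KLRG1
HLA-DR	HLA-DRA
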