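gene_name	description	main_localisation	kidney_mrna_fpkm	ts_score	hpa_available
UMOD	Uromodulin	Membrane	1421	647	Yes
SLC22A8	Solute carrier family 22, member 8	Membrane	269	633	Yes
SLC12A1	Solute carrier family 12, member 1	Membrane	406	460	Yes
TMEM174	Transmembrane protein 174	Membrane	97	443	Yes
MCCD1	Mitochondrial coiled-coil domain 1	Membrane	27	271	Yes
SLC34A1	Solute carrier family 34, member 1	Membrane	176	219	Yes
AQP2	Aquaporin 2 (collecting duct)	Membrane	315	177	Yes
SLC22A12	Solute carrier family 22, member 12	Membrane	108	162	Yes
SLC22A2	Solute carrier family 22, member 2	Membrane	97	154	Yes
SLC22A6	Solute carrier family 22, member 6	Membrane	198	144	No
KCNJ1	Potassium inwardly-rectifying channel	Membrane	132	140	Yes
SLC7A13	Solute carrier family 7, membrane 13	Membrane	19	118	No
NPHS2	Nephrosis 2, idiopathic, (podocin)	Membrane	68	116	Yes
SLC6A18	Solute carrier family 6, member 18	Membrane	11	106	Yes
SLC36A2	Solute carrier family 36, member 2	Membrane	64	97	Yes
SLC12A3	Solute carrier family 12, member 3	Membrane	129	84	Yes
SLC22A13	Solute carrier family 22, member 13	Membrane	12	74	Yes
ATP6V1G3	ATPase, H+ transporting, lysosomal	Membrane	38	73	Yes
MIOX	Myo-inositol oxygenase	Cytoplasm	625	73	Yes
TMEM207	Transmembrane protein 207	Membrane	10	59	Yes
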