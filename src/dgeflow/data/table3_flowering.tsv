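mirna_id	mirna_direction	gene_id	gene_direction	description
osa-miR156l	up	LOC_Os01g06550.1	down	NF-X1-type zinc finger protein, putative
osa-miR156l	up	LOC_Os02g34860.1	down	Regulator of chromosome condensation domain containing protein
osa-miR160f	down	LOC_Os04g43910.1	up	Auxin response factor, putative
osa-miR160f	down	LOC_Os06g49840.1	up	OsMADS16 - MADS-box family gene with MIKCc type-box
osa-miR164a,b	down	LOC_Os01g62660.1	up	MYB family transcription factor, putative
osa-miR172a,b	down	LOC_Os03g60430.2	up	AP2 domain containing protein
osa-miR172a,b	down	LOC_Os04g55560.4	up	AP2 domain containing protein
osa-miR390	down	LOC_Os02g10100.1	up	Leucine-rich repeat receptor protein kinase EXS precursor, putative
osa-miR390	down	LOC_Os06g03970.1	up	Receptor-like protein kinase 5 precursor, putative
osa-miR390	down	LOC_Os01g33110.1	up	Receptor-like protein kinase 5 precursor, putative
osa-miR408	down	LOC_Os08g37670.1	up	Plastocyanin-like domain containing protein, putative
osa-miR408	down	LOC_Os01g54430.1	up	Plastocyanin-like domain containing protein, putative
oru-miR135	up	LOC_Os05g27930.1	down	AP2 domain containing protein
oru-miR135	up	LOC_Os01g67240.1	down	Formin-like protein 1 precursor, putative
oru-miR135	up	LOC_Os07g38800.1	down	Lectin-like receptor kinase, putative
oru-miR135	up	LOC_Os08g23180.1	down	Fasciclin-like arabinogalactan protein 8 precursor, putative
oru-miR135	up	LOC_Os11g45740.1	down	MYB family transcription factor, putative
oru-miR139	up	LOC_Os01g10580.1	down	B-box zinc finger family protein, putative
oru-miR180	up	LOC_Os06g24070.1	down	myb-like DNA-binding domain containing protein
oru-miR4	down	LOC_Os09g39410.1	up	Male sterility protein, putative
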