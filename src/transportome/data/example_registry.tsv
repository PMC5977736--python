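family_id	name	class	is_energizer
3.A.1	ATP-binding cassette (ABC) superfamily	ATP_DEPENDENT	false
3.A.3	P-type ATPase superfamily	ATP_DEPENDENT	false
3.A.4	Arsenite-antimonite (ArsAB) efflux family	ATP_DEPENDENT	false
3.A.6	Type III secretory pathway family	ATP_DEPENDENT	false
3.A.8	Mitochondrial protein translocase family	ATP_DEPENDENT	false
3.A.9	Chloroplast envelope protein translocase family	ATP_DEPENDENT	false
3.A.2.F	F-type ATPase / ATP synthase family	ATP_DEPENDENT	true
3.A.2.V	V/A-type ATPase family	ATP_DEPENDENT	true
2.A.1	Major facilitator superfamily (MFS)	SECONDARY	false
2.A.3	Amino acid-polyamine-organocation (APC) family	SECONDARY	false
2.A.4	Cation diffusion facilitator (CDF) family	SECONDARY	false
2.A.5	Zinc-iron permease (ZIP) family	SECONDARY	false
2.A.6	Resistance-nodulation-cell division (RND) superfamily	SECONDARY	false
2.A.19	Ca2+:cation antiporter (CaCA) family	SECONDARY	false
2.A.20	Inorganic phosphate transporter (PiT) family	SECONDARY	false
2.A.23	Dicarboxylate/amino acid:cation symporter (DAACS) family	SECONDARY	false
2.A.36	Monovalent cation:proton antiporter-1 (CPA1) family	SECONDARY	false
2.A.37	Monovalent cation:proton antiporter-2 (CPA2) family	SECONDARY	false
2.A.55	Metal ion (Mn2+-iron) transporter (Nramp) family	SECONDARY	false
2.A.24	2-hydroxycarboxylate transporter (2-HCT) family	SECONDARY	false
2.A.26	Branched chain amino acid:cation symporter (LIVCS) family	SECONDARY	false
2.A.34	NhaB Na+:H+ antiporter family	SECONDARY	false
2.A.63	Monovalent cation (K+ or Na+):proton antiporter-3 (CPA3) family	SECONDARY	false
2.A.68	p-Aminobenzoyl-glutamate transporter (AbgT) family	SECONDARY	false
2.A.73	Short chain fatty acid uptake (AtoE) family	SECONDARY	false
2.A.83	Na+-dependent bicarbonate transporter (SBT) family	SECONDARY	false
2.A.87	Prokaryotic riboflavin transporter (RFT) family	SECONDARY	false
2.A.28	Bile acid:Na+ symporter (BASS) family	SECONDARY	false
2.A.74	4 TMS multidrug endosomal transporter (MET) family	SECONDARY	false
2.A.84	Chloroplast maltose exporter (MEX) family	SECONDARY	false
2.A.92	Choline transporter-like (CTL) family	SECONDARY	false
2.A.101	Silicon transporter (Sit) family	SECONDARY	false
9.A.55	Vitamin A receptor/transporter (STRA6) family	SECONDARY	false
2.A.29	Mitochondrial carrier (MC / SLC25) family	SECONDARY	false
1.A.1	Voltage-gated ion channel (VIC) superfamily	ION_CHANNEL	false
1.A.8	Major intrinsic protein (MIP / aquaporin) family	ION_CHANNEL	false
1.A.11	Chloride carrier/channel (ClC) family	ION_CHANNEL	false
1.A.35	CorA metal ion transporter family	ION_CHANNEL	false
1.A.22	Large conductance mechanosensitive channel (MscL) family	ION_CHANNEL	false
1.A.23	Small conductance mechanosensitive channel (MscS) family	ION_CHANNEL	false
1.A.26	MgtE Mg2+ channel family	ION_CHANNEL	false
1.A.30	MotAB/ExbBD proton channel family	ION_CHANNEL	false
1.A.43	CorB/CorC CBS-pair Mg2+ channel family	ION_CHANNEL	false
1.B.1	General bacterial porin (GBP) family	ION_CHANNEL	false
1.E.1	Holin functional superfamily	ION_CHANNEL	false
1.A.3	Ryanodine-inositol 1,4,5-trisphosphate receptor Ca2+ channel family	ION_CHANNEL	false
1.A.4	Transient receptor potential (TRP) Ca2+ channel family	ION_CHANNEL	false
1.A.5	Polycystin cation channel (PCC) family	ION_CHANNEL	false
1.A.6	Epithelial Na+ channel (ENaC/DEG) family	ION_CHANNEL	false
1.A.7	ATP-gated P2X receptor cation channel family	ION_CHANNEL	false
1.A.9	Neurotransmitter receptor Cys-loop ligand-gated ion channel family	ION_CHANNEL	false
1.A.10	Glutamate-gated ion channel (iGluR) family	ION_CHANNEL	false
1.A.17	Calcium-dependent chloride channel (anoctamin) family	ION_CHANNEL	false
1.A.24	Gap junction-forming connexin family	ION_CHANNEL	false
1.A.25	Gap junction-forming innexin/pannexin family	ION_CHANNEL	false
1.A.46	Anion channel-forming bestrophin family	ION_CHANNEL	false
1.A.51	Voltage-gated proton channel (Hv1) family	ION_CHANNEL	false
1.A.52	Ca2+ release-activated Ca2+ channel (Orai) family	ION_CHANNEL	false
1.A.75	Mechanosensitive Piezo channel family	ION_CHANNEL	false
1.A.77	Mitochondrial Ca2+ uniporter (MCU) family	ION_CHANNEL	false
1.A.84	Calcium homeostasis modulator (CALHM) family	ION_CHANNEL	false
1.A.94	Endolysosomal K+ channel (TMEM175) family	ION_CHANNEL	false
1.A.96	Two-pore segment Ca2+ channel (TPC) family	ION_CHANNEL	false
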