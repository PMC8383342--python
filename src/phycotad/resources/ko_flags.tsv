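ko_id	flags	note
K02025	transport	ABC transporter permease, oligosaccharide
K02026	transport	ABC transporter permease, oligosaccharide
K02057	transport	simple sugar ABC transporter substrate-binding
K10111	transport	maltose/monosaccharide ABC transporter ATPase
K10439	transport	ribose/xylose ABC transporter substrate-binding
K10227	transport	sorbitol/mannitol ABC transporter ATPase
K11069	transport	putrescine/spermidine ABC transporter substrate-binding
K11070	transport	putrescine/spermidine ABC transporter permease
K02016	transport	iron-complex ABC transporter substrate-binding
K02073	transport	thiamine ABC transporter substrate-binding
K03454	transport	TRAP transporter large permease
K11688	transport	TRAP dicarboxylate transporter DctP
K16092	cobalamin_transport	vitamin B12 TonB-dependent receptor BtuB
K06858	cobalamin_transport	vitamin B12 ABC transporter substrate-binding BtuF
K00798	cobalamin_biosynthesis	cob(I)alamin adenosyltransferase MMAB/pduO
K02234	cobalamin_biosynthesis	cobalamin biosynthesis protein CobW
K02406	flagellar	flagellin FliC
K02556	flagellar	chemotaxis/motility protein MotA
K02557	flagellar	chemotaxis/motility protein MotB
K02396	flagellar	flagellar hook-associated protein FlgK
K02283	flp_pilus	pilus assembly ATPase CpaF/TadA
K02279	flp_pilus	pilus assembly protein CpaC/RcpA
K12510	flp_pilus	tight adherence protein TadB
K12511	flp_pilus	tight adherence protein TadC
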