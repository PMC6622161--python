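family	subfamily	type_protein_name	accession	function	motif	source_publication
I	1		D50587	True lipase		original-1999
I	2		X70354	True lipase		original-1999
I	3		D11455	True lipase		original-1999
I	4		M74010	True lipase		original-1999
I	5		U78785	True lipase		original-1999
I	6		M12715	True lipase / Phospholipase		family-I-revision
I	7		X99255	True lipase		family-I-revision
I	8	Lip1	Q3IF07	True lipase		this-revision
I	9	LipG	DQ458963	True lipase	GHSLG	this-revision
I	10	RlipE1	FJ529693	-	GLSMG	this-revision
I	11	MPlaG	EU285670	True lipase / Phospholipase	GHSLG	this-revision
II			P10480	Secreted acyltranferase		original-1999
III			M86351	Extracellular lipase		original-1999
IV			X62835	Esterase		original-1999
V			M58445	PHA-depolymerase		original-1999
VI			D90904	Carboxylesterases		original-1999
VII			Q01470	Carbamate hydrolase		original-1999
VIII			AAA99492	Stereoselective esterase		original-1999
IX		phaZ7	AY026355	Poly(3-hydroxylbutyrate) depolymerase		kovacic-update
X		EstD	NP_228147	Carboxylesterase	GHSLG	this-revision
XI		EstA	ABY60416	Esterase	GHSMG	this-revision
XII		LipEH166	EU515239	Lipase		
XIII		Est30	AY186197	Carboxylesterase	GxSLG	this-revision
XIV		EstA3	NP_623858	Carboxylesterase		kovacic-update
XV		EstGtA2	AEN92268	Carboxylesterase		kovacic-update
XVI		LipSM54	AGF29555	Lipase		kovacic-update
XVII		LipJ2	KX096709	Lipase		kovacic-update
XVIII		plaB	EF408871	Phosphatidylcholine-specific phospholipase	THSTG	this-revision
XIX		LipSM	KX353755	Lipase	GHSQG	kovacic-update
XX		FLS18D	ACL67852	Esterase	GHSMG	this-revision
XXI		FnL	ABS61180	Lipase	AxSxG	this-revision
XXII		EstD2	GQ866023	Secreted esterase	GHSQG	this-revision
XXIII		LipA	ACJ13070	Lipase	AHSMG	this-revision
XXIV		Rv0045c	NP_214559	Esterase	GMSLG	this-revision
XXV		EM3L4	GQ340926	Lipase		this-revision
XXVI		EstGS	HQ156900	Secreted esterase	GHSFG	this-revision
XXVII		EstGH	HQ156914	Esterase	GHSLG	this-revision
XXVIII		LipR	YP_345621	Lipase	GYSGG	this-revision
XXIX		EstGX1	HQ262952	Lipase	GPSGG	this-revision
XXX		EstP2K	JN001203	Esterase	AHSLG	this-revision
XXXI		Est12	KF313138	Esterase	GHSAG	this-revision
XXXII		Est9x	AFR79233	Lipase	GHSAG	this-revision
XXXIII		EstDZ2	KX301277	Secreted carboxylesterase	GHSAG	this-revision
XXXIV		Est22	GAC12013	Homoserine transacetylase	GPSMG	this-revision
XXXV		AcXE2	ACM59679	Acetyl xylan esterase	GDSIT	this-revision
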