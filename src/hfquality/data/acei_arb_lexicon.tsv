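# ACEI/ARB medication lexicon.
# Columns: generic <TAB> class <TAB> comma-separated surface variants
# (brands, misspellings, abbreviations). Matching is case-insensitive on
# word boundaries; each variant must map to exactly one generic.
lisinopril	ACEI	prinivil,zestril
enalapril	ACEI	vasotec,enalaprilat
captopril	ACEI	capoten
ramipril	ACEI	altace
benazepril	ACEI	lotensin
fosinopril	ACEI	monopril
quinapril	ACEI	accupril
trandolapril	ACEI	mavik
moexipril	ACEI	univasc
perindopril	ACEI	aceon,coversyl
losartan	ARB	cozaar
valsartan	ARB	diovan
candesartan	ARB	atacand
irbesartan	ARB	avapro
olmesartan	ARB	benicar
telmisartan	ARB	micardis
eprosartan	ARB	teveten
azilsartan	ARB	edarbi
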