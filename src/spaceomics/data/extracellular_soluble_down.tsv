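tair_id	description	symbol	location
AT2G04690	Pyridoxamine 5-phosphate oxidase family protein	-	extracellular
AT3G28200	Peroxidase superfamily protein	-	extracellular
AT5G63180	Pectin lyase-like superfamily protein	-	extracellular
AT5G56870	Beta-galactosidase 4	BGAL4	extracellular
AT4G34180	Cyclase-family protein, negative regulator of cell death	CYCLASE1	extracellular
AT4G08950	Phosphate-responsive 1 family protein	EXO	extracellular
AT1G14540	Peroxidase superfamily protein	PER4	extracellular
AT5G59090	Subtilase 4.12	SBT4.12	extracellular
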