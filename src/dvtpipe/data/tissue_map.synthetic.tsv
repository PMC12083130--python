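sample	tissue
BLD01	Whole Blood
BLD02	Whole Blood
BLD03	Whole Blood
BLD04	Whole Blood
BLD05	Whole Blood
BLD06	Whole Blood
BLD07	Whole Blood
BLD08	Whole Blood
LIV01	Liver
LIV02	Liver
LIV03	Liver
LIV04	Liver
LIV05	Liver
LIV06	Liver
LIV07	Liver
LIV08	Liver
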