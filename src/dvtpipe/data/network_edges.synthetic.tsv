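# Synthetic reconstruction of the gene-disease/phenotype edge list around
# deep vein thrombosis. Exactly five of the fifteen coagulation genes carry a
# direct edge to a DVT or thrombophilia concept.
gene	concept_id	concept_label	source
F2	DOID:DVT	Deep vein thrombosis	disease
F5	DOID:DVT	Deep vein thrombosis	disease
F9	DOID:DVT	Deep vein thrombosis	disease
PROC	DOID:DVT	Deep vein thrombosis	disease
THBD	DOID:DVT	Deep vein thrombosis	disease
F2	DOID:THPH	Thrombophilia	disease
F5	DOID:THPH	Thrombophilia	disease
PROC	DOID:THPH	Thrombophilia	disease
F5	HP:0004418	Thrombophilia	phenotype
F11	HP:0001892	Abnormal bleeding	phenotype
KLKB1	HP:0001892	Abnormal bleeding	phenotype
FGB	HP:0001892	Abnormal bleeding	phenotype
FGA	HP:0011889	Bleeding with minor trauma	phenotype
VWF	DOID:VWD	Von Willebrand disease	disease
ADAMTS13	DOID:TTP	Thrombotic thrombocytopenic purpura	disease
SH2B3	HP:0001873	Thrombocytopenia	phenotype
PLCG2	HP:0002960	Autoimmunity	phenotype
ST3GAL4	HP:0001892	Abnormal bleeding	phenotype
PLEK	HP:0001873	Thrombocytopenia	phenotype
F8	DOID:HEMA	Hemophilia A	disease
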