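# Synthetic excerpt of a primary-immunodeficiency (IUIS-style) gene list.
IL6R
IL1RN
PLCG2
BTK
WAS
ADA
RAG1
RAG2
STAT3
STAT1
NFKB1
CTLA4
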