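# Exemplar assay-interference substructure motifs (id <TAB> SMARTS).
# A small, documented default used for testing the flagging mechanism;
# production runs should supply a curated filter collection instead.
quinone	O=C1C=CC(=O)C=C1
catechol	c1cc(O)c(O)cc1
rhodanine	O=C1CSC(=S)N1
ene_rhodanine	O=C1C(=*)SC(=S)N1
azo	[#6]N=N[#6]
michael_acceptor	C=CC(=O)[#6]
nitroaromatic	c[N+](=O)[O-]
hydrazone	[#6]C=NN([#1,#6])[#6]
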