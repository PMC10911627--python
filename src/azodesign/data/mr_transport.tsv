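# Methyl red (MR) uptake block: azoreductase, transport, exchange, and
# secretion of the reduced by-product N,N-dimethyl-4-phenylenediamine (dmppd).
# Columns: id <TAB> equation <TAB> lb <TAB> ub <TAB> gpr
# AzoR_MR consumes exactly 2 NADH per MR, cleaving the azo bond into
# dmppd + anthranilate (published model-edit stoichiometry).
AzoR_MR	mr[c] + 2 h[c] + 2.0 nadh[c] --> dmppd[c] + anth[c] + 2.0 nad[c]	0	1000	azoR
MRt1	mr[e] <=> mr[p]	-1000	1000
MRt2	mr[p] + h[p] <=> mr[c] + h[c]	-1000	1000
EX_mr_e	mr[e] -->	0	1000
DMPPDt	dmppd[c] --> dmppd[e]	0	1000
EX_dmppd_e	dmppd[e] -->	0	1000
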