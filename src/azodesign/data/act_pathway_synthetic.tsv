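# SYNTHETIC stand-in for the heterologous actinorhodin (ACT) pathway block.
# AnthDO carries the literature stoichiometry of anthranilate 1,2-dioxygenase
# (antABC, Acinetobacter sp.): anthranilate + O2 + NADH -> catechol + CO2 + NH4.
# ACTSYN lumps the S. coelicolor type-II PKS and tailoring steps into one
# reaction: 2 acetyl-CoA starters + 14 malonyl-CoA extenders per ACT (C32
# dimeric octaketide). The NADH regeneration term lumps the oxidative
# tailoring and dimerization steps and is sized so that the pathway is a net
# redox/energy source — the structural property that makes the product
# couplable to growth. Per-step stoichiometries of the full 22-reaction
# block are not reproduced here.
# Columns: id <TAB> equation <TAB> lb <TAB> ub <TAB> gpr
AnthDO	anth[c] + o2[c] + nadh[c] + 2 h[c] --> catechol[c] + co2[c] + nh4[c] + nad[c]	0	1000	antA and antB and antC
ACTSYN	2 accoa[c] + 14 malcoa[c] + 8 nad[c] --> act[c] + 14 co2[c] + 8 nadh[c]	0	1000	actPKS
ACTt	act[c] --> act[e]	0	1000
EX_act_e	act[e] -->	0	1000
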