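# Default class adaptor table (synthetic stand-in sequences).
# One row per functional class: class, forward adaptor, reverse adaptor.
# All adaptors are 12 nt, pairwise distinct, free of type IIS (BsaI) sites,
# and absent from the default backbone template.
class	fwd	rev
CP	ACGTTGACCAGT	TGGTCATCGTCA
APC	CATTGGACGTTC	AGTCCTGAACGT
MFS	GTTCACCTGGAA	CCATGTTGAGCA
DMT	TGAACGGTCCAT	GATCCAATGCGT
MATE	CCTGATTGGCAA	TTGCAGTCCGAT
ABC	GAATCGTGGTCA	CAGTTGCATCCG
PA	TCGGATAACCTG	GTCAACTGGATC
UF	AACCGTTCTGGA	CGATTGGTACTC
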