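# RNA/RNA nearest-neighbor stacking free energies, delta-G at 37 C (kcal/mol).
# Keys are dinucleotide steps read 5'->3' on the guide strand, DNA alphabet
# (T stands for U). Watson-Crick stacks from the standard published RNA set;
# INIT is the duplex initiation term; MISMATCH and GU are flat per-position
# penalties applied to unpaired / wobble positions.
AA	-0.93
AC	-2.24
AG	-2.08
AT	-1.10
CA	-2.11
CC	-3.26
CG	-2.36
CT	-2.08
GA	-2.35
GC	-3.42
GG	-3.26
GT	-2.24
TA	-1.33
TC	-2.35
TG	-2.11
TT	-0.93
INIT	4.09
MISMATCH	0.50
GU	0.25
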