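# B-Z transition free energies per dinucleotide unit, kcal/mol.
# AS = 5'-anti 3'-syn, SA = 5'-syn 3'-anti, ZZ = Z-Z junction penalty for the
# doublet spanning two out-of-phase dinucleotide units.
# Rows list the ten distinct dinucleotide classes; X=Y marks reverse-complement
# pairs that share energies.
# version: 1
dinucleotide	AS	SA	ZZ
CG	0.7	4.0	4.0
GC	4.0	0.7	4.0
CA=TG	1.3	4.6	4.5
AC=GT	4.6	1.3	4.5
CC=GG	2.4	2.4	4.0
CT=AG	3.4	3.4	6.3
TC=GA	3.4	3.4	6.3
AA=TT	3.9	3.9	7.4
TA	2.5	5.9	5.6
AT	5.9	2.5	5.6
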