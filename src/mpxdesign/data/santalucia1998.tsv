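# Unified nearest-neighbor parameters for DNA/DNA duplexes (SantaLucia 1998).
# Columns: key, dH (kcal/mol), dS (cal/mol/K).
# Dinucleotide keys are the 5'->3' top strand of one stack; the bottom strand
# is its Watson-Crick complement. init_AT / init_GC are per-terminal-pair
# duplex initiation terms; symmetry applies once to self-complementary duplexes.
AA	-7.9	-22.2
AT	-7.2	-20.4
AC	-8.4	-22.4
AG	-7.8	-21.0
TA	-7.2	-21.3
TT	-7.9	-22.2
TC	-8.2	-22.2
TG	-8.5	-22.7
CA	-8.5	-22.7
CT	-7.8	-21.0
CC	-8.0	-19.9
CG	-10.6	-27.2
GA	-8.2	-22.2
GT	-8.4	-22.4
GC	-9.8	-24.4
GG	-8.0	-19.9
init_AT	2.3	4.1
init_GC	0.1	-2.8
symmetry	0.0	-1.4
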