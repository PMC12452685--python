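name	pattern
M1	[V/I]-[I/V]-G-A-G-x-[V/I]-G-x-x-x-A
M2	G-x-x-V-x-x-[I/V]-[D/E]
M3	S-x-G-N-x-[G/A]
M4	P-W-x-x-x-[F/Y]
M5	L-[E/D]-x-x-R-G-Y
M6	[L/I]-R-x-x-G-x-x-E-x-[A/G]
M7	W-[M/L]-G-x-R-P-x-x-x-D
M8	A-x-G-H-x-H-x-G-L
rossmann_extended	[V/I]-x-G-x(1,2)-G-x-x-G-x-x-x-[G/A]
rossmann_core	G-x(1,2)-G-x-x-G
gxxxa	G-x-x-x-A
peroxisomal_like	W-x-x-x-[F/Y]
prm_composite	P-x-x-x-P-(x)6-P-(x)5-P-x-x-P-(x)8-P-x-x-x-P
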