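phylum	class	count
Pseudomonadota	a-proteobacteria	1644
Pseudomonadota	b-proteobacteria	293
Pseudomonadota	g-proteobacteria	195
Pseudomonadota	d-proteobacteria	9
Pseudomonadota	Undefined Proteobacteriota	58
Undefined	Undefined Bacteria	10
Actinomycetota	Actinobacteria	3
Acidobacteriota	Acidobacteriota	3
Planctomycetota	Planctomycetota	2
Chloroflexota	Chloroflexota	1
Verrucomicrobiota	Verrucomicrobia	1
Deinococcota	Deinococcota	1
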