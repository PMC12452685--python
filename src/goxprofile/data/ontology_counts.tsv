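label	count
FAD-dependent/binding oxidoreductase	2121
amino acid dehydrogenase	40
D-amino acid dehydrogenase	28
D-amino acid dehydrogenase 1	8
dependent oxidoreductase	4
dependent oxidoreductase family protein	3
D-amino acid dehydrogenase small subunit	3
putative D-amino acid dehydrogenase protein	3
Dehydrogenase	2
amino acid oxidase	1
cytochrome C4	1
dadA1	1
FAD-dependent glyphosate oxidase	1
Glycine/D-amino acid oxidase _deaminating_	1
Gox	1
ketopantoate reductase PanE/ApbA family protein	1
pyridine nucleotide-disulfide oxidoreductase family protein	1
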