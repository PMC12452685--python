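# Default protein-name ("ontology") normalization rules.
#
# Keys are matched case-insensitively with runs of spaces/underscores/hyphens
# collapsed, so "oxidoreductase_ FAD-binding" and "oxidoreductase FAD binding"
# hit the same entry.  synonym_map unifies alternative spellings of the same
# label; group_map then collapses labels that describe the same activity into
# one subtype, keeping the most widespread term.
synonym_map:
  "FAD-binding oxidoreductase": "FAD-binding oxidoreductase"
  "oxidoreductase FAD-binding": "FAD-binding oxidoreductase"
  "oxidoreductase FAD-binding protein": "FAD-binding oxidoreductase"
  "FAD-dependent oxidoreductase": "FAD-binding oxidoreductase"
  "FAD-dependent/binding oxidoreductase": "FAD-binding oxidoreductase"
  "FAD-binding/dependent oxidoreductase": "FAD-binding oxidoreductase"
group_map:
  "amino acid dehydrogenase": "(D-) amino acid dehydrogenase"
  "D-amino acid dehydrogenase": "(D-) amino acid dehydrogenase"
  "D-amino acid dehydrogenase 1": "(D-) amino acid dehydrogenase"
  "D-amino acid dehydrogenase small subunit": "(D-) amino acid dehydrogenase"
  "putative D-amino acid dehydrogenase protein": "(D-) amino acid dehydrogenase"
  "(D-) amino acid dehydrogenase": "(D-) amino acid dehydrogenase"
  "dependent oxidoreductase": "dependent oxidoreductase"
  "dependent oxidoreductase family protein": "dependent oxidoreductase"
  "Gox": "Gox"
  "Gox (Glyphosate oxidoreductase)": "Gox"
  "Gox (FAD-dependent glyphosate oxidase)": "Gox"
  "FAD-dependent glyphosate oxidase": "Gox"
  "glyphosate oxidase": "Gox"
  "glyphosate oxidoreductase": "Gox"
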