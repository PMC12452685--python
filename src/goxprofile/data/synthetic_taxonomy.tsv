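# Synthetic stand-in taxonomy table (no live NCBI lookups): organism name -> deepest
# annotated rank and lineage (domain;phylum;class;order;family;genus;species prefix).
organism	rank	lineage
Ochrobactrum sp. G-1	genus	Bacteria;Pseudomonadota;a-proteobacteria;Hyphomicrobiales;Brucellaceae;Ochrobactrum
uncultured bacterium	domain	Bacteria
Pseudomonadota bacterium	phylum	Bacteria;Pseudomonadota
alpha proteobacterium	class	Bacteria;Pseudomonadota;a-proteobacteria
beta proteobacterium	class	Bacteria;Pseudomonadota;b-proteobacteria
gamma proteobacterium	class	Bacteria;Pseudomonadota;g-proteobacteria
delta proteobacterium	class	Bacteria;Pseudomonadota;d-proteobacteria
Rhodospirillales bacterium	order	Bacteria;Pseudomonadota;a-proteobacteria;Rhodospirillales
Burkholderiales bacterium	order	Bacteria;Pseudomonadota;b-proteobacteria;Burkholderiales
Rhizobiaceae bacterium	family	Bacteria;Pseudomonadota;a-proteobacteria;Hyphomicrobiales;Rhizobiaceae
Comamonadaceae bacterium	family	Bacteria;Pseudomonadota;b-proteobacteria;Burkholderiales;Comamonadaceae
Rhizobium sp. SYN-1	genus	Bacteria;Pseudomonadota;a-proteobacteria;Hyphomicrobiales;Rhizobiaceae;Rhizobium
Variovorax sp. SYN-2	genus	Bacteria;Pseudomonadota;b-proteobacteria;Burkholderiales;Comamonadaceae;Variovorax
Pseudomonas sp. SYN-3	genus	Bacteria;Pseudomonadota;g-proteobacteria;Pseudomonadales;Pseudomonadaceae;Pseudomonas
Rhizobium leguminosarum	species	Bacteria;Pseudomonadota;a-proteobacteria;Hyphomicrobiales;Rhizobiaceae;Rhizobium;Rhizobium leguminosarum
Variovorax paradoxus	species	Bacteria;Pseudomonadota;b-proteobacteria;Burkholderiales;Comamonadaceae;Variovorax;Variovorax paradoxus
Variovorax boronicumulans	species	Bacteria;Pseudomonadota;b-proteobacteria;Burkholderiales;Comamonadaceae;Variovorax;Variovorax boronicumulans
Agrobacterium tumefaciens	species	Bacteria;Pseudomonadota;a-proteobacteria;Hyphomicrobiales;Rhizobiaceae;Agrobacterium;Agrobacterium tumefaciens
Pseudomonas fluorescens	species	Bacteria;Pseudomonadota;g-proteobacteria;Pseudomonadales;Pseudomonadaceae;Pseudomonas;Pseudomonas fluorescens
Actinomycetota bacterium	phylum	Bacteria;Actinomycetota
Streptomyces sp. SYN-4	genus	Bacteria;Actinomycetota;Actinobacteria;Streptomycetales;Streptomycetaceae;Streptomyces
Acidobacteriota bacterium	phylum	Bacteria;Acidobacteriota
Planctomycetota bacterium	phylum	Bacteria;Planctomycetota
Chloroflexota bacterium	phylum	Bacteria;Chloroflexota
Deinococcus sp. SYN-5	genus	Bacteria;Deinococcota;Deinococci;Deinococcales;Deinococcaceae;Deinococcus
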