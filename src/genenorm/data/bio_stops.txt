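# Common biological terms excluded when indexing lexicon synonyms
# (27 manually curated entries).
activate
anti
antibody
cdna
complex
domain
domains
dominant
enzymes
family
families
gene
genes
linked
homolog
homology
human
humans
like
mrna
negative
promoter
promoters
receptor
subfamily
subunit
superfamily
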