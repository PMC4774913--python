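# Hypernym headwords for gene/protein entities.
gene
genes
protein
proteins
factor
factors
cytokine
cytokines
molecule
molecules
receptor
receptors
element
elements
family
families
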