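name: panel300
genes_file: panel300_genes.txt
size_mb: 0.6
include_synonymous: true
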