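# Breast-cancer risk-SNP screen list (one rsID per line).
# The published 24-SNP risk panel is not redistributed here; supply your own
# list via --snp-list.  This default covers the CASP8 risk allele.
rs1045485
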