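# Secretase cleavage annotation for human APP770 (example input).
# Columns: taxon, beta, alpha, gamma — each the 1-based position of the
# FIRST residue following the cut, on the taxon's own (ungapped) sequence.
# beta..gamma-1 spans Abeta42 (residues 672-713 of APP770); the alpha site
# falls after Abeta residue K16 (APP770 position 687).
APP_HUMAN_770	672	688	714
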