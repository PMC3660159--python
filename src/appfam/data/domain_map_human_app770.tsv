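#reference=APP_HUMAN_770
# Example domain map for the 770-residue human amyloid precursor protein
# isoform (APP770). Boundaries are approximate, intended as a worked
# example of the format; supply your own map for real analyses.
# Coordinates are 1-based inclusive. The amyloid-forming bA4 region
# (Abeta42 = residues 672-713) overlaps the C-terminal E3 region and is
# flagged accordingly.
#name	start	end	overlap
NTS	1	17
E1	18	189
E2	366	575
bA4	672	713	1
E3	700	770
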